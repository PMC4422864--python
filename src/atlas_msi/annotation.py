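"""Mass annotation: theoretical monoisotopic/adduct masses, PTM/adduct
delta-pair detection with spatial-correlation support, and ppm matching
against a compound table.

Charge-carrier convention: singly charged ion m/z is the neutral
monoisotopic mass plus/minus proton or cation masses with the electron mass
absorbed (proton 1.007276 Da, K+ 38.963158 Da, Na+ 22.989218 Da), so that
computed values agree with printed accurate masses to 4 decimals.
"""
from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core_model_io.model import DataCube, FeatureDef, ValidationError

__all__ = [
    "MONOISOTOPIC_MASSES",
    "PROTON_MASS",
    "ADDUCTS",
    "DELTA_RULES",
    "Compound",
    "DeltaRule",
    "monoisotopic_mass",
    "adduct_mz",
    "find_delta_pairs",
    "match_compounds",
    "builtin_compounds",
]

#: Most-abundant-isotope masses, Da (IUPAC/CODATA).
MONOISOTOPIC_MASSES = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "K": 38.96370668,
    "Na": 22.9897692809,
    "Cl": 34.96885268,
    "F": 18.99840322,
}

PROTON_MASS = 1.007276
ELECTRON_MASS = 0.00054858
K_CATION = MONOISOTOPIC_MASSES["K"] - ELECTRON_MASS     # 38.963158
NA_CATION = MONOISOTOPIC_MASSES["Na"] - ELECTRON_MASS   # 22.989221

#: adduct name -> (mass shift added to neutral M, polarity)
ADDUCTS = {
    "[M+H]+": (PROTON_MASS, "+"),
    "[M+Na]+": (NA_CATION, "+"),
    "[M+K]+": (K_CATION, "+"),
    "[M-H]-": (-PROTON_MASS, "-"),
    "[M+K-2H]-": (K_CATION - 2 * PROTON_MASS, "-"),
    "[M+Na-2H]-": (NA_CATION - 2 * PROTON_MASS, "-"),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Compound:
    name: str
    formula: str = ""
    mass: float | None = None  # neutral monoisotopic mass, Da

    @property
    def neutral_mass(self) -> float:
        m = self.mass if self.mass is not None else monoisotopic_mass(self.formula)
        if m <= 0:
            raise ValidationError(f"compound {self.name!r} has nonpositive mass")
        return m


@dataclass(frozen=True)
class DeltaRule:
    name: str
    delta_mass: float
    tolerance: float = 0.05

    def __post_init__(self):
        if self.delta_mass <= 0 or self.tolerance <= 0:
            raise ValidationError("delta_mass and tolerance must be positive")


#: Characteristic mass differences of common PTMs / cation exchanges, Da.
DELTA_RULES = {
    "methylation": DeltaRule("methylation", 14.01565),
    "acetylation": DeltaRule("acetylation", 42.01057),
    "K_for_H": DeltaRule("K_for_H", MONOISOTOPIC_MASSES["K"] - MONOISOTOPIC_MASSES["H"]),
    "Na_for_H": DeltaRule("Na_for_H", MONOISOTOPIC_MASSES["Na"] - MONOISOTOPIC_MASSES["H"]),
    "phosphorylation": DeltaRule("phosphorylation", 79.96633),
}


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition string like ``C6H14O12P2``."""
    if not formula or not formula.strip():
        raise ValidationError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValidationError(f"unparseable formula fragment {formula[pos:m.start()]!r}")
        pos = m.end()
        el, n = m.group(1), int(m.group(2) or 1)
        if el not in MONOISOTOPIC_MASSES:
            raise ValidationError(f"unknown element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(formula):
        raise ValidationError(f"unparseable formula fragment {formula[pos:]!r}")
    return counts


def monoisotopic_mass(formula: str) -> float:
    """Neutral monoisotopic mass (Da) from the embedded isotope table."""
    counts = parse_formula(formula)
    return sum(MONOISOTOPIC_MASSES[el] * n for el, n in counts.items())


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """Singly charged ion m/z for *neutral_mass* under the named adduct."""
    if neutral_mass <= 0:
        raise ValidationError("neutral mass must be positive")
    if adduct not in ADDUCTS:
        raise ValidationError(f"unknown adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    return neutral_mass + ADDUCTS[adduct][0]


def _spatial_corr(cube: DataCube, i: int, j: int) -> float:
    ok = cube.valid if cube.valid is not None else np.ones(len(cube.values), bool)
    a, b = cube.values[ok, i], cube.values[ok, j]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def find_delta_pairs(
    features: list[FeatureDef],
    cube: DataCube | None,
    rules,
    min_spatial_corr: float = 0.5,
):
    """Find feature pairs separated by a known PTM/adduct mass difference.

    Returns a list of dicts with keys feature_a, feature_b (a < b by m/z),
    rule, observed_delta (rounded to 4 decimals) and corr; each unordered
    pair is reported once per matching rule.  When *cube* is None the
    spatial-correlation gate is skipped.
    """
    feats = sorted(features, key=lambda f: f.center_mz)
    order = {id(f): i for i, f in enumerate(features)}
    out = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            a, b = feats[i], feats[j]
            delta = b.center_mz - a.center_mz
            for rule in rules:
                if abs(delta - rule.delta_mass) > rule.tolerance:
                    continue
                corr = None
                if cube is not None:
                    corr = _spatial_corr(cube, order[id(a)], order[id(b)])
                    if corr < min_spatial_corr:
                        continue
                out.append(
                    {
                        "feature_a": a,
                        "feature_b": b,
                        "rule": rule.name,
                        "observed_delta": round(delta, 4),
                        "corr": corr,
                    }
                )
    return out


def match_compounds(
    observed_mz: float,
    polarity: str,
    compounds,
    adducts=None,
    ppm_tol: float = 10.0,
):
    """ppm-match an observed m/z against (compound, adduct) candidates.

    Candidates within *ppm_tol* are returned ranked by absolute ppm error.
    """
    if ppm_tol <= 0:
        raise ValidationError("ppm_tol must be positive")
    compounds = list(compounds)
    if not compounds:
        raise ValidationError("empty compound table")
    adducts = adducts or [a for a, (_, pol) in ADDUCTS.items() if pol == polarity]
    hits = []
    for comp in compounds:
        for adduct in adducts:
            if ADDUCTS[adduct][1] != polarity:
                continue
            theo = adduct_mz(comp.neutral_mass, adduct)
            ppm = (observed_mz - theo) / theo * 1e6
            if abs(ppm) <= ppm_tol:
                hits.append({"compound": comp, "adduct": adduct,
                             "theoretical_mz": theo, "ppm_error": ppm})
    hits.sort(key=lambda h: abs(h["ppm_error"]))
    return hits


def builtin_compounds() -> list[Compound]:
    """Small embedded table of CSD-relevant brain metabolites."""
    return [
        Compound("glutamate", "C5H9NO4"),
        Compound("fructose 1,6-bisphosphate", "C6H14O12P2"),
        Compound("AMP", "C10H14N5O7P"),
        Compound("ADP", "C10H15N5O10P2"),
        Compound("ATP", "C10H16N5O13P3"),
        Compound("lactate", "C3H6O3"),
        Compound("pyruvate", "C3H4O3"),
        Compound("glucose", "C6H12O6"),
        Compound("creatine", "C4H9N3O2"),
    ]


def read_compound_table(path) -> list[Compound]:
    """CSV columns: name, formula (optional), mass (optional)."""
    out = []
    with open(Path(path), newline="") as fh:
        for row in csv.DictReader(fh):
            mass = row.get("mass")
            out.append(Compound(row["name"], row.get("formula", "") or "",
                                float(mass) if mass else None))
    if not out:
        raise ValidationError(f"empty compound table: {path}")
    return out
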