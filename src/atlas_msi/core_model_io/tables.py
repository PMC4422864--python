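"""TSV serialization of region statistics tables and feature lists."""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .model import ValidationError

#: Canonical column order of a region statistics table.
STATS_COLUMNS = [
    "feature_mz",
    "roi",
    "comparison",
    "n",
    "mean_a",
    "mean_b",
    "estimate",
    "direction",
    "t",
    "p_raw",
    "q_bh",
    "significant",
]


def write_stats_table(table: pd.DataFrame, path) -> Path:
    """Write a stats table as TSV (header always present, even when empty)."""
    path = Path(path)
    missing = [c for c in STATS_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"stats table missing columns: {missing}")
    table[STATS_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_stats_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_feature_table(features, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [{"center_mz": f.center_mz, "lo": f.lo, "hi": f.hi, "snr": f.snr} for f in features]
    ).to_csv(path, sep="\t", index=False)
    return path


def read_feature_table(path):
    from .model import FeatureDef

    df = pd.read_csv(path, sep="\t")
    return [FeatureDef(r.center_mz, r.lo, r.hi, r.snr) for r in df.itertuples()]
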