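import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atlas_msi.core_model_io.model import (
    AtlasSection,
    DataCube,
    FeatureDef,
    StudyDesign,
    ValidationError,
)
from atlas_msi.roi_stats import (
    bh_adjust,
    block_randomize,
    extract_region_profiles,
    group_test,
    paired_hemisphere_test,
    qc_metabolite_ratio,
    run_study_statistics,
)
from atlas_msi.synthetic_data import NoiseModel, simulate_region_profiles


def brute_force_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i}(p_(j) * m / j), capped."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
        q[idx] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_adjust([0.05, 0.05, 0.05]), [0.05] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_1000_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 51)))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_q_geq_p_and_rank_preserving(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        order_p = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order_p]) >= -1e-15)


def _profiles(rows):
    return pd.DataFrame(rows)


def _paired_frame(left, right, roi="cortex", mz=100.0):
    rows = []
    for i, (l, r) in enumerate(zip(left, right)):
        rows += [dict(animal_id=f"a{i}", roi=roi, hemisphere="L", n_pixels=10,
                      feature_mz=mz, value=l),
                 dict(animal_id=f"a{i}", roi=roi, hemisphere="R", n_pixels=10,
                      feature_mz=mz, value=r)]
    return _profiles(rows)


class TestPairedTest:
    def test_frozen_oracle(self):
        # differences (1.0, 1.2, 0.8): closed form t = 1 / (0.2/sqrt(3)),
        # p from the t(2) survival function (high-precision oracle)
        prof = _paired_frame([2.0, 3.2, 1.8], [1.0, 2.0, 1.0])
        t, p, est = paired_hemisphere_test(prof, "cortex", 100.0)
        assert t == pytest.approx(8.6603, abs=1e-4)
        assert p == pytest.approx(0.013072, abs=1e-5)
        assert est == pytest.approx(1.0)

    def test_identical_hemispheres(self):
        prof = _paired_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        t, p, est = paired_hemisphere_test(prof, "cortex", 100.0)
        assert t == 0.0 and p == 1.0 and est == 0.0

    def test_zero_variance_nonzero_mean(self):
        prof = _paired_frame([2.0, 3.0], [1.0, 2.0])
        t, p, est = paired_hemisphere_test(prof, "cortex", 100.0)
        assert math.isinf(t) and p == 0.0 and est == 1.0

    def test_n1_rejected(self):
        with pytest.raises(ValidationError, match=">=2"):
            paired_hemisphere_test(_paired_frame([1.0], [0.5]), "cortex", 100.0)

    def test_planted_lfc_detected(self, atlas3, default_design):
        prof = simulate_region_profiles(default_design, atlas3[0][0], seed=7)
        groups = dict(zip(default_design.table["animal_id"], default_design.groups))
        sub = prof[prof["animal_id"].map(groups) == "R192Q-CSD"]
        t, p, est = paired_hemisphere_test(sub, "cortex", 146.07)
        assert p < 0.05 and est > 0  # right hemisphere planted lower


class TestGroupTest:
    def test_identical_groups(self):
        t, p, est = group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_frozen_oracle(self):
        # pooled-variance closed form: t = -1 / sqrt(2/3)
        t, p, est = group_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-1.224745, abs=1e-5)
        assert p == pytest.approx(0.287864, abs=1e-5)
        assert est == pytest.approx(-1.0)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValidationError):
            group_test([1.0], [2.0, 3.0])


class TestExtractRegionProfiles:
    def _aligned_cube(self, atlas_sec, paint):
        h, w = atlas_sec.labels.shape
        coords = np.array([[x, y] for y in range(h) for x in range(w)])
        values = paint.reshape(-1, 1)
        return DataCube(coords=coords, features=[FeatureDef(100.0, 99.0, 101.0)],
                        values=values, valid=np.isfinite(values[:, 0]),
                        transform_applied=True,
                        meta={"animal_id": "a0"}).validate()

    def test_uniform_cube(self, atlas3):
        sec = atlas3[0][0]
        cube = self._aligned_cube(sec, np.full(sec.labels.shape, 7.0))
        prof = extract_region_profiles(cube, sec)
        assert (prof["value"] == 7.0).all()
        assert set(prof["roi"]) == {"cortex", "striatum", "hippocampus", "thalamus"}
        assert set(prof["hemisphere"]) == {"L", "R"}

    def test_painted_hemispheres(self, atlas3):
        sec = atlas3[0][0]
        paint = np.where(sec.hemisphere_mask("L"), 2.0, 4.0)
        prof = extract_region_profiles(self._aligned_cube(sec, paint), sec)
        cortex = prof[prof.roi == "cortex"].set_index("hemisphere")["value"]
        assert cortex["L"] == 2.0 and cortex["R"] == 4.0

    def test_unregistered_cube_rejected(self, atlas3):
        sec = atlas3[0][0]
        cube = self._aligned_cube(sec, np.ones(sec.labels.shape))
        cube.transform_applied = False
        with pytest.raises(ValidationError, match="registered"):
            extract_region_profiles(cube, sec)

    def test_empty_roi_omitted(self, atlas3):
        sec = atlas3[0][0]
        paint = np.full(sec.labels.shape, np.nan)
        paint[sec.roi_mask("cortex")] = 1.0
        prof = extract_region_profiles(self._aligned_cube(sec, paint), sec)
        assert set(prof["roi"]) == {"cortex"}


class TestRunStudyStatistics:
    def test_planted_recovery_and_clean_null_groups(self, atlas3, default_design):
        prof = simulate_region_profiles(default_design, atlas3[0][0], seed=3)
        table = run_study_statistics(prof, default_design)
        for mz, roi in [(146.07, "cortex"), (146.07, "thalamus"),
                        (170.2, "striatum"), (158.3, "hippocampus")]:
            sub = table[(table.roi == roi) & (table.comparison == "R192Q-CSD:L-vs-R")
                        & np.isclose(table.feature_mz, mz)]
            assert len(sub) == 1 and bool(sub.significant.iloc[0])
        null_rows = table[table.comparison.str.contains("Naive|Sham")]
        assert null_rows.significant.mean() <= 0.05

    def test_alpha_zero_nothing_significant(self, atlas3, default_design):
        prof = simulate_region_profiles(default_design, atlas3[0][0], seed=3)
        table = run_study_statistics(prof, default_design, alpha=0.0)
        assert not table.significant.any()

    def test_missing_animals_listed(self, atlas3, default_design):
        prof = simulate_region_profiles(default_design, atlas3[0][0], seed=3)
        prof = prof[prof.animal_id != "m01"]
        with pytest.raises(ValidationError, match="m01"):
            run_study_statistics(prof, default_design)

    def test_q_geq_p_and_flag_consistency(self, atlas3, default_design):
        prof = simulate_region_profiles(default_design, atlas3[0][0], seed=5)
        table = run_study_statistics(prof, default_design)
        assert (table.q_bh >= table.p_raw - 1e-12).all()
        assert ((table.q_bh < 0.05) == table.significant).all()


class TestBlockRandomize:
    def test_default_layout_max_diversity(self, default_design):
        out = block_randomize(default_design, slots_per_slide=4, seed=0)
        t = out.table
        assert set(t.slide_id) == set(range(8))
        for slide, sub in t.groupby("slide_id"):
            groups = sub["genotype"] + "-" + sub["condition"]
            assert len(sub) == 4
            assert groups.nunique() == 4  # always arithmetically possible here
        assert sorted(t.acquisition_order) == list(range(32))
        for _, sub in t.groupby("slide_id"):
            assert sorted(sub.slide_position) == list(range(len(sub)))

    def test_determinism(self, default_design):
        a = block_randomize(default_design, 4, seed=9).table
        b = block_randomize(default_design, 4, seed=9).table
        pd.testing.assert_frame_equal(a, b)
        c = block_randomize(default_design, 4, seed=10).table
        assert not a["slide_id"].equals(c["slide_id"]) or \
            not a["acquisition_order"].equals(c["acquisition_order"])

    def test_single_group_degenerate(self):
        design = StudyDesign.default({("WT", "Naive"): 4})
        out = block_randomize(design, 4, seed=1)
        assert (out.table.slide_id == 0).all()

    def test_bad_slots(self, default_design):
        with pytest.raises(ValidationError):
            block_randomize(default_design, 0, seed=0)


class TestQC:
    def _prof(self, ratios):
        rows = []
        for i, r in enumerate(ratios):
            rows += [dict(animal_id=f"a{i}", roi="cortex", hemisphere="L",
                          n_pixels=10, feature_mz=1.0, value=r),
                     dict(animal_id=f"a{i}", roi="cortex", hemisphere="L",
                          n_pixels=10, feature_mz=2.0, value=1.0)]
        return _profiles(rows)

    def test_constant_ratio_degenerate(self):
        prof = self._prof([2.0, 2.0, 2.0, 2.0])
        times = {f"a{i}": float(i) for i in range(4)}
        out = qc_metabolite_ratio(prof, 1.0, 2.0, times)
        assert out["degenerate"] and out["r"] == 0.0

    def test_numerator_equals_denominator(self):
        prof = self._prof([1.0, 1.0, 1.0])
        out = qc_metabolite_ratio(prof, 2.0, 2.0, {f"a{i}": float(i) for i in range(3)})
        assert all(v == 1.0 for v in out["ratios"].values())

    def test_independent_ratio_not_correlated(self):
        rng = np.random.default_rng(0)
        ps, n = [], 40
        for s in range(20):
            ratios = 2.0 + rng.normal(0, 0.1, n)
            prof = self._prof(ratios)
            times = {f"a{i}": float(rng.random()) for i in range(n)}
            out = qc_metabolite_ratio(prof, 1.0, 2.0, times)
            ps.append(out["p"])
        assert np.mean(np.asarray(ps) < 0.05) < 0.2

    def test_zero_denominator_excluded(self):
        rows = [dict(animal_id="a0", roi="cortex", hemisphere="L", n_pixels=10,
                     feature_mz=1.0, value=1.0),
                dict(animal_id="a0", roi="cortex", hemisphere="L", n_pixels=10,
                     feature_mz=2.0, value=0.0)]
        out = qc_metabolite_ratio(_profiles(rows), 1.0, 2.0, {"a0": 1.0})
        assert out["excluded"] == ["a0"]
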