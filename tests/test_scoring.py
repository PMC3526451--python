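"""Normalisation and robust Z-scoring: oracles, invariances, exclusion contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rnaihts as r
from rnaihts.scoring import (
    CONTROL_REFERENCE,
    DegenerateReferenceError,
    ScoringConfig,
    average_replicates,
    compute_ratio,
    plate_median_center,
    robust_z,
    score_screen,
)


def brute_force_z(x, ref, mad_scale=1.4826):
    """Independent oracle: sort-based median and MAD, no numpy shortcuts."""

    def median(vals):
        s = sorted(vals)
        n = len(s)
        mid = n // 2
        return s[mid] if n % 2 else 0.5 * (s[mid - 1] + s[mid])

    med = median(ref)
    mad = median([abs(v - med) for v in ref])
    return (x - med) / (mad_scale * mad)


class TestComputeRatio:
    def test_plain_ratio(self):
        assert compute_ratio(200.0, 100.0) == 2.0

    def test_zero_fl_is_zero_in_linear_mode(self):
        assert compute_ratio(0.0, 100.0) == 0.0

    def test_zero_rl_flags_unscorable(self):
        assert compute_ratio(100.0, 0.0) is None

    def test_log2_mode(self):
        assert compute_ratio(400.0, 100.0, use_log2=True) == pytest.approx(2.0)
        assert compute_ratio(0.0, 100.0, use_log2=True) is None


class TestPlateMedianCenter:
    def test_equal_ratios_center_to_one(self):
        out = plate_median_center(np.full(5, 5.0), np.full(5, 5.0))
        assert np.allclose(out, 1.0)

    def test_hand_computed_example(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])  # median 2.5
        out = plate_median_center(ref, ref)
        assert np.allclose(out, [0.4, 0.8, 1.2, 1.6])

    def test_log_mode_subtracts(self):
        ref = np.array([1.0, 2.0, 3.0])
        assert np.allclose(plate_median_center(ref, ref, use_log2=True), [-1.0, 0.0, 1.0])


class TestRobustZ:
    def test_frozen_example(self):
        # median 3, raw MAD 1 -> Z = 1 / 1.4826
        z = robust_z(4.0, [1, 2, 3, 4, 100], ScoringConfig(min_reference_wells=5))
        assert z == pytest.approx(1.0 / 1.4826, abs=1e-12)

    def test_x_at_median_scores_zero(self):
        assert robust_z(3.0, [1, 2, 3, 4, 100], ScoringConfig(min_reference_wells=5)) == 0.0

    def test_constant_reference_raises(self):
        with pytest.raises(DegenerateReferenceError):
            robust_z(1.0, [2.0] * 10, ScoringConfig())

    def test_too_small_reference_raises(self):
        with pytest.raises(ValueError):
            robust_z(1.0, [1.0, 2.0], ScoringConfig())

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        cfg = ScoringConfig()
        for _ in range(1000):
            ref = rng.normal(size=rng.integers(8, 60)).tolist()
            x = float(rng.normal())
            assert robust_z(x, ref, cfg) == pytest.approx(
                brute_force_z(x, ref), abs=1e-12
            )

    @given(
        xs=st.tuples(
            st.floats(-50, 50), st.floats(-50, 50)
        ).filter(lambda t: t[1] - t[0] > 1e-6),
        seed=st.integers(0, 10_000),
    )
    def test_strictly_increasing_in_x(self, xs, seed):
        ref = np.random.default_rng(seed).normal(size=20).tolist()
        cfg = ScoringConfig()
        assert robust_z(xs[0], ref, cfg) < robust_z(xs[1], ref, cfg)


def test_plate_gain_on_both_channels_leaves_z_ratio_unchanged(small_null_screen):
    dataset, _, _ = small_null_screen
    scored = score_screen(dataset, None, ScoringConfig())
    meas = dataset.measurements.copy()
    meas.loc[meas["plate"] == 2, "intensity"] *= 7.0
    scaled = r.ScreenDataset(dataset.layout, meas, dataset.replicates)
    scored2 = score_screen(scaled, None, ScoringConfig())
    pd.testing.assert_series_equal(
        scored.per_replicate["z_ratio"], scored2.per_replicate["z_ratio"], atol=1e-9, rtol=0
    )


def test_fl_only_gain_shifts_z_fl_and_z_ratio_up(small_null_screen):
    dataset, _, _ = small_null_screen
    scored = score_screen(dataset, None, ScoringConfig())
    meas = dataset.measurements.copy()
    boost = (
        (meas["plate"] == 1)
        & (meas["row"] == "C")
        & (meas["column"] == 3)
        & (meas["channel"] == "FL")
    )
    meas.loc[boost, "intensity"] *= 3.0
    scored2 = score_screen(
        r.ScreenDataset(dataset.layout, meas, dataset.replicates), None, ScoringConfig()
    )
    sel = (
        (scored.per_replicate["plate"] == 1)
        & (scored.per_replicate["row"] == "C")
        & (scored.per_replicate["column"] == 3)
    )
    assert (scored2.per_replicate.loc[sel, "z_fl"] > scored.per_replicate.loc[sel, "z_fl"]).all()
    assert (
        scored2.per_replicate.loc[sel, "z_ratio"] > scored.per_replicate.loc[sel, "z_ratio"]
    ).all()


def test_screen_log_scoring_equals_physically_filtered_dataset(small_null_screen):
    """Two-pass contract: excluding wells via the log is identical to deleting
    their measurements before scoring -- excluded wells influence nothing."""
    dataset, _, _ = small_null_screen
    excl = pd.DataFrame(
        {
            "replicate": ["ALL", 2],
            "plate": [1, 3],
            "row": ["A", "B"],
            "column": [5, 7],
            "reason": ["contamination", "liquid_handling"],
            "note": ["", ""],
        }
    )
    with_log = score_screen(dataset, excl, ScoringConfig())

    meas = dataset.measurements
    drop = ((meas["plate"] == 1) & (meas["row"] == "A") & (meas["column"] == 5)) | (
        (meas["plate"] == 3)
        & (meas["row"] == "B")
        & (meas["column"] == 7)
        & (meas["replicate"] == 2)
    )
    filtered = r.ScreenDataset(dataset.layout, meas[~drop], dataset.replicates)
    from_scratch = score_screen(filtered, None, ScoringConfig())

    a = with_log.per_replicate
    b = from_scratch.per_replicate
    kept = ~a["excluded"]
    assert np.allclose(
        a.loc[kept, "z_ratio"], b.loc[kept.index[kept], "z_ratio"], atol=1e-12
    )
    # the logged wells carry no Z at all
    assert a.loc[a["reason"] == "contamination", "z_ratio"].isna().all()


def test_null_screen_z_calibration(small_null_scored):
    per = small_null_scored.per_replicate
    samples = per[(per["role"] == "sample") & ~per["excluded"]]
    for _, grp in samples.groupby("replicate"):
        assert abs(grp["z_ratio"].median()) < 0.05
        assert 0.02 < (grp["z_ratio"].abs() >= 2).mean() < 0.08


def test_control_mode_matches_genome_mode_on_null_screen(full_null_scored, full_null_screen):
    """With non-interacting controls drawn from the sample distribution's
    centre, control-referenced Z-scores track genome-mode Z-scores closely
    (default layout: few controls per plate, so control statistics pool
    across plates)."""
    dataset, _ = full_null_screen
    control = score_screen(dataset, None, ScoringConfig(z_reference=CONTROL_REFERENCE))
    m = full_null_scored.averaged.merge(
        control.averaged, on=["plate", "row", "column"], suffixes=("_g", "_c")
    )
    m = m[m["role_g"] == "sample"]
    delta = (m["avg_z_ratio_g"] - m["avg_z_ratio_c"]).abs()
    # the two referencing modes differ only through control-set estimation
    # noise, which scales with |z|; the bulk of the wells must agree tightly
    assert delta.quantile(0.95) <= 0.2
    assert delta.median() <= 0.1


class TestAverageReplicates:
    @staticmethod
    def _frame(zs, excluded):
        rows = []
        for rep, (z, ex) in enumerate(zip(zs, excluded), start=1):
            rows.append(
                {
                    "plate": 1,
                    "row": "A",
                    "column": 1,
                    "clone_id": "c1",
                    "gene_id": "g1",
                    "role": "sample",
                    "replicate": rep,
                    "ratio": 1.0,
                    "z_ratio": z,
                    "z_fl": z,
                    "z_rl": 0.0,
                    "excluded": ex,
                    "reason": "other" if ex else "",
                }
            )
        return pd.DataFrame(rows)

    def test_simple_mean(self):
        avg = average_replicates(self._frame([2.0, 4.0, 3.0], [False] * 3))
        assert avg.loc[0, "avg_z_ratio"] == pytest.approx(3.0)
        assert avg.loc[0, "n_valid_replicates"] == 3

    def test_excluded_replicate_dropped_from_mean(self):
        avg = average_replicates(self._frame([2.0, 4.0, np.nan], [False, False, True]))
        assert avg.loc[0, "avg_z_ratio"] == pytest.approx(3.0)
        assert avg.loc[0, "n_valid_replicates"] == 2

    def test_all_excluded_flags_insufficient_data(self):
        avg = average_replicates(self._frame([np.nan] * 3, [True] * 3))
        assert avg.loc[0, "n_valid_replicates"] == 0
        assert np.isnan(avg.loc[0, "avg_z_ratio"])


def test_scoring_config_validation():
    with pytest.raises(ValueError):
        ScoringConfig(mad_scale=0.0)
    with pytest.raises(ValueError):
        ScoringConfig(trend_threshold=3.0)
    with pytest.raises(ValueError):
        ScoringConfig(z_reference="whatever")
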