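"""Hit-selection rules, tier boundaries, screen comparison, coverage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rnaihts as r
from rnaihts.hits import (
    AVAIL_NA,
    AVAIL_SCORED,
    FLAG_FL,
    FLAG_REPLICATE,
    FLAG_RL,
    TIER_INSUFFICIENT,
    TIER_NOT,
    TIER_SIGNIFICANT,
    TIER_TRENDING,
    SelectionConfig,
    classify_z,
    compare_screens,
    coverage_summary,
    gene_calls,
    select_primary_hits,
    tertiary_confirmation,
)
from rnaihts.scoring import ZScoreTable


@pytest.mark.parametrize(
    "z,expected",
    [
        (-7.9, TIER_SIGNIFICANT),
        (2.0, TIER_SIGNIFICANT),  # boundary inclusive
        (-2.0, TIER_SIGNIFICANT),
        (1.9999, TIER_TRENDING),
        (1.8, TIER_TRENDING),
        (1.7, TIER_TRENDING),  # boundary inclusive
        (-1.7, TIER_TRENDING),
        (1.6999, TIER_NOT),
        (0.5, TIER_NOT),
        (0.0, TIER_NOT),
    ],
)
def test_classify_z_boundaries(z, expected):
    assert classify_z(z) == expected


@given(st.floats(-20, 20, allow_nan=False))
def test_classify_z_partition_is_exhaustive_and_exclusive(z):
    assert classify_z(z) in (TIER_SIGNIFICANT, TIER_TRENDING, TIER_NOT)


def _z_table(wells):
    """Build a ZScoreTable from (clone, gene, rep_zs, avg_fl, avg_rl) specs."""
    per_rows, avg_rows = [], []
    for i, (clone, gene, rep_zs, avg_fl, avg_rl) in enumerate(wells):
        valid = [z for z in rep_zs if z is not None]
        for rep, z in enumerate(rep_zs, start=1):
            per_rows.append(
                {
                    "plate": 1,
                    "row": "A",
                    "column": i + 1,
                    "clone_id": clone,
                    "gene_id": gene,
                    "role": "sample",
                    "replicate": rep,
                    "ratio": 1.0,
                    "z_ratio": np.nan if z is None else z,
                    "z_fl": avg_fl,
                    "z_rl": avg_rl,
                    "excluded": z is None,
                    "reason": "other" if z is None else "",
                }
            )
        avg_rows.append(
            {
                "plate": 1,
                "row": "A",
                "column": i + 1,
                "clone_id": clone,
                "gene_id": gene,
                "role": "sample",
                "avg_z_ratio": np.mean(valid) if valid else np.nan,
                "avg_z_fl": avg_fl,
                "avg_z_rl": avg_rl,
                "n_valid_replicates": len(valid),
            }
        )
    return ZScoreTable(pd.DataFrame(per_rows), pd.DataFrame(avg_rows))


class TestSelectPrimaryHits:
    def test_all_rules_pass_gives_significant_negative_regulator(self):
        zt = _z_table([("c1", "g1", (3.1, 2.9, 2.8), 2.7, 0.3)])
        call = select_primary_hits(zt).iloc[0]
        assert call.tier == TIER_SIGNIFICANT
        assert call.direction == "negative_regulator"  # reporter up on knockdown
        assert call.filter_flags == ""

    def test_rl_driven_ratio_is_rejected_with_flags(self):
        # ratio pushed by a large RL change while FL is flat
        zt = _z_table([("c1", "g1", (2.7, 2.5, 2.6), 0.4, -3.5)])
        call = select_primary_hits(zt).iloc[0]
        assert call.tier == TIER_NOT
        flags = set(call.filter_flags.split(";"))
        assert flags == {FLAG_FL, FLAG_RL}

    def test_single_significant_replicate_fails_replicate_rule(self):
        zt = _z_table([("c1", "g1", (4.5, 1.5, 1.0), 3.0, 0.0)])
        call = select_primary_hits(zt).iloc[0]
        assert call.tier == TIER_NOT
        assert FLAG_REPLICATE in call.filter_flags

    def test_sign_inconsistent_replicates_do_not_count(self):
        # two replicates reach |z| >= 2 but one with the wrong sign
        zt = _z_table([("c1", "g1", (6.8, -2.5, 1.8), 2.8, 0.0)])
        call = select_primary_hits(zt).iloc[0]
        assert FLAG_REPLICATE in call.filter_flags

    def test_trending_band(self):
        zt = _z_table([("c1", "g1", (1.8, 1.9, 1.7), 1.5, 0.0)])
        call = select_primary_hits(zt).iloc[0]
        assert call.tier == TIER_TRENDING
        assert call.direction == "negative_regulator"

    def test_insufficient_data(self):
        zt = _z_table([("c1", "g1", (3.0, None, None), 3.0, 0.0)])
        call = select_primary_hits(zt).iloc[0]
        assert call.tier == TIER_INSUFFICIENT
        assert call.direction == "none"

    def test_every_clone_gets_exactly_one_tier(self, planted_scored):
        calls = select_primary_hits(planted_scored)
        assert calls["tier"].isin(
            [TIER_SIGNIFICANT, TIER_TRENDING, TIER_NOT, TIER_INSUFFICIENT]
        ).all()
        assert len(calls) == len(calls.drop_duplicates(["plate", "row", "column"]))

    def test_raising_threshold_never_adds_hits(self, planted_scored):
        lo = select_primary_hits(planted_scored, SelectionConfig(z_threshold=2.0))
        hi = select_primary_hits(
            planted_scored, SelectionConfig(z_threshold=2.5, trend_threshold=1.7)
        )
        hits_lo = set(lo.loc[lo["tier"] == TIER_SIGNIFICANT, "clone_id"])
        hits_hi = set(hi.loc[hi["tier"] == TIER_SIGNIFICANT, "clone_id"])
        assert hits_hi <= hits_lo

    def test_rl_artifact_genes_need_the_single_channel_rules(self, planted_screen, planted_scored):
        _, truth, _ = planted_screen
        artifacts = set(truth.loc[truth["class"] == "rl_artifact", "clone_id"])
        strict = select_primary_hits(planted_scored)
        loose = select_primary_hits(
            planted_scored,
            SelectionConfig(require_fl_significant=False, require_rl_nonsignificant=False),
        )
        called_strict = set(strict.loc[strict["tier"] == TIER_SIGNIFICANT, "clone_id"])
        called_loose = set(loose.loc[loose["tier"] == TIER_SIGNIFICANT, "clone_id"])
        assert not (called_strict & artifacts)
        assert called_loose & artifacts


def test_gene_calls_take_extreme_clone_and_flag_discordance():
    zt = _z_table(
        [
            ("c1", "gA", (3.0, 3.2, 2.9), 3.0, 0.0),
            ("c2", "gA", (-2.5, -2.6, -2.4), -2.5, 0.0),
            ("c3", "gB", (0.1, 0.2, 0.0), 0.1, 0.0),
        ]
    )
    per_gene = gene_calls(select_primary_hits(zt))
    rec = per_gene[per_gene["gene_id"] == "gA"].iloc[0]
    assert rec.clone_id == "c1"  # |3.03| > |-2.5|
    assert bool(rec.discordant_clones)
    assert not per_gene[per_gene["gene_id"] == "gB"]["discordant_clones"].iloc[0]


class TestCompareScreens:
    @staticmethod
    def _calls(genes_tiers):
        return pd.DataFrame(
            {"gene_id": list(genes_tiers), "tier": list(genes_tiers.values())}
        )

    def test_disjoint_hit_lists_overlap_zero(self):
        a = self._calls({"g1": TIER_SIGNIFICANT, "g2": TIER_SIGNIFICANT})
        b = self._calls({"g1": TIER_NOT, "g2": TIER_NOT})
        avail = {"g1": AVAIL_SCORED, "g2": AVAIL_SCORED}
        assert compare_screens(a, b, avail).overlap_count == 0

    def test_na_genes_counted_separately(self):
        a = self._calls({f"g{i}": TIER_SIGNIFICANT for i in range(6)})
        b = self._calls({f"g{i}": TIER_SIGNIFICANT for i in range(6)})
        avail = {f"g{i}": (AVAIL_NA if i < 5 else AVAIL_SCORED) for i in range(6)}
        cmpres = compare_screens(a, b, avail)
        assert len(cmpres.na_excluded_genes) == 5
        assert cmpres.overlap_count == 1

    def test_missing_availability_entry_raises(self):
        a = self._calls({"g1": TIER_SIGNIFICANT})
        b = self._calls({"g1": TIER_SIGNIFICANT})
        with pytest.raises(KeyError, match="g1"):
            compare_screens(a, b, {})


class TestTertiaryConfirmation:
    def test_empty_inputs_confirm_nothing(self):
        empty = pd.DataFrame({"gene_id": [], "tier": []})
        assert tertiary_confirmation(empty, empty, set()) == set()

    def test_confirmed_restricted_to_primary_hits(self):
        primary = pd.DataFrame({"gene_id": ["g1"], "tier": [TIER_SIGNIFICANT]})
        tertiary = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "tier": [TIER_SIGNIFICANT, TIER_SIGNIFICANT]}
        )
        assert tertiary_confirmation(primary, tertiary) == {"g1"}

    def test_prior_multi_reagent_genes_count_when_primary(self):
        primary = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "tier": [TIER_SIGNIFICANT, TIER_SIGNIFICANT]}
        )
        tertiary = pd.DataFrame({"gene_id": [], "tier": []})
        assert tertiary_confirmation(primary, tertiary, {"g2", "g9"}) == {"g2"}


class TestCoverageSummary:
    def test_no_exclusions_means_no_excluded_genes(self, planted_screen, planted_scored):
        dataset, _, _ = planted_screen
        calls = select_primary_hits(planted_scored)
        cov = coverage_summary(dataset.layout, planted_scored, calls, genome_size=14000)
        stats = dict(zip(cov["statistic"], cov["n_genes"]))
        assert stats["genes_excluded_screening_errors"] == 0
        assert stats["genes_in_library"] == stats["remaining_genome_coverage"]

    def test_plates_lost_in_two_replicates_exclude_their_genes(self, small_null_screen):
        dataset, _, _ = small_null_screen
        excl = pd.DataFrame(
            {
                "replicate": [1, 2, 1, 2],
                "plate": [1, 1, 2, 2],
                "row": ["*"] * 4,
                "column": ["*"] * 4,
                "reason": ["liquid_handling"] * 4,
                "note": [""] * 4,
            }
        )
        from rnaihts.io import read_screen_log  # reuse wildcard expansion
        import rnaihts.model as m

        # expand wildcards the same way the reader does
        rows = []
        for _, rec in excl.iterrows():
            for row in m.ROW_LETTERS:
                for col in range(1, m.N_COLUMNS + 1):
                    rows.append((rec.replicate, rec.plate, row, col, rec.reason, ""))
        expanded = pd.DataFrame(rows, columns=m.EXCLUSION_COLUMNS)
        scored = r.score_screen(dataset, expanded, r.ScoringConfig())
        calls = select_primary_hits(scored)
        cov = coverage_summary(dataset.layout, scored, calls, genome_size=14000)
        stats = dict(zip(cov["statistic"], cov["n_genes"]))
        # plates 1-2 retain one replicate (>= 2 required), their genes drop out
        ann = dataset.layout.annotations
        lost = set(ann.loc[(ann["role"] == "sample") & ann["plate"].isin([1, 2]), "gene_id"])
        assert stats["genes_excluded_screening_errors"] == len(lost)

    def test_null_screen_final_hits_near_zero(self, small_null_scored, small_null_screen):
        dataset, _, _ = small_null_screen
        calls = select_primary_hits(small_null_scored)
        cov = coverage_summary(dataset.layout, small_null_scored, calls, genome_size=14000)
        stats = dict(zip(cov["statistic"], cov["n_genes"]))
        assert stats["final_hits"] <= 0.005 * stats["genes_in_library"]
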