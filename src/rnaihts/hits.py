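"""Hit selection rules, tier classification and screen comparison.

A clone is a *significant* primary hit when all of the following hold on
its averaged and per-replicate Z-scores:

(i)   ``|avg Z(FL/RL)| >= z_threshold``;
(ii)  at least ``min_significant_replicates`` replicates individually reach
      ``|Z(FL/RL)| >= z_threshold`` with the sign of the average;
(iii) ``|avg Z(FL)| >= z_threshold`` with the same sign (the effect must be
      visible in the pathway reporter channel alone); and
(iv)  ``|avg Z(RL)| < z_threshold`` (the effect must not be driven by the
      viability channel -- this removes RL-stability artefacts such as
      heat-shock and proteolysis genes that skew the ratio through Renilla
      luciferase alone).

Clones with ``trend_threshold <= |avg Z| < z_threshold`` are *trending*.
A negative average Z (reporter down on knockdown) marks a positive pathway
regulator, and vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .scoring import ZScoreTable

TIER_SIGNIFICANT = "significant"
TIER_TRENDING = "trending"
TIER_NOT = "not_significant"
TIER_INSUFFICIENT = "insufficient_data"

DIR_POS = "positive_regulator"
DIR_NEG = "negative_regulator"
DIR_NONE = "none"

FLAG_REPLICATE = "failed_replicate_rule"
FLAG_FL = "failed_fl_rule"
FLAG_RL = "failed_rl_rule"


@dataclass
class SelectionConfig:
    z_threshold: float = 2.0
    trend_threshold: float = 1.7
    min_significant_replicates: int = 2
    require_fl_significant: bool = True
    require_rl_nonsignificant: bool = True
    require_sign_consistency: bool = True

    def __post_init__(self) -> None:
        if self.min_significant_replicates < 1:
            raise ValueError("min_significant_replicates must be >= 1")
        if not 0 < self.trend_threshold <= self.z_threshold:
            raise ValueError("need 0 < trend_threshold <= z_threshold")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "SelectionConfig":
        known = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in mapping.items() if k in known})

    def for_rescreen(self) -> "SelectionConfig":
        """Re-screen variant: single-channel rules off (only the ratio Z is
        reported for control-referenced re-screens)."""
        return SelectionConfig(
            z_threshold=self.z_threshold,
            trend_threshold=self.trend_threshold,
            min_significant_replicates=self.min_significant_replicates,
            require_fl_significant=False,
            require_rl_nonsignificant=False,
            require_sign_consistency=self.require_sign_consistency,
        )


def classify_z(z: float, config: SelectionConfig | None = None) -> str:
    """Tier of a single averaged Z: |Z| >= 2.0 significant, 1.7 <= |Z| < 2.0
    trending, else not significant.  Boundaries are inclusive on the lower
    edge of each tier."""
    cfg = config or SelectionConfig()
    if not np.isfinite(z):
        return TIER_INSUFFICIENT
    a = abs(z)
    if a >= cfg.z_threshold:
        return TIER_SIGNIFICANT
    if a >= cfg.trend_threshold:
        return TIER_TRENDING
    return TIER_NOT


def _direction(tier: str, z: float) -> str:
    if tier in (TIER_SIGNIFICANT, TIER_TRENDING):
        return DIR_POS if z < 0 else DIR_NEG
    return DIR_NONE


def select_primary_hits(
    z_table: ZScoreTable, config: SelectionConfig | None = None
) -> pd.DataFrame:
    """Apply the full hit-selection rule set to a scored genome screen.

    Returns clone-level calls for all sample wells: clone_id, gene_id, tier,
    direction, avg_z_ratio, avg_z_fl, avg_z_rl, n_valid_replicates,
    n_significant_replicates, filter_flags (semicolon-joined).
    """
    cfg = config or SelectionConfig()
    avg = z_table.averaged
    avg = avg[avg["role"] == "sample"].reset_index(drop=True)
    per = z_table.per_replicate
    per = per[(per["role"] == "sample") & ~per["excluded"]]

    sign = np.sign(avg["avg_z_ratio"].to_numpy())
    rep = per.merge(
        avg[["plate", "row", "column"]].assign(_avg_sign=sign),
        on=["plate", "row", "column"],
        how="inner",
    )
    rep_sig = np.abs(rep["z_ratio"]) >= cfg.z_threshold
    if cfg.require_sign_consistency:
        rep_sig &= np.sign(rep["z_ratio"]) == rep["_avg_sign"]
    n_sig = (
        rep.assign(_sig=rep_sig)
        .groupby(["plate", "row", "column"], as_index=False)["_sig"]
        .sum()
        .rename(columns={"_sig": "n_significant_replicates"})
    )
    avg = avg.merge(n_sig, on=["plate", "row", "column"], how="left")
    avg["n_significant_replicates"] = (
        avg["n_significant_replicates"].fillna(0).astype(int)
    )

    az = avg["avg_z_ratio"].to_numpy()
    afl = avg["avg_z_fl"].to_numpy()
    arl = avg["avg_z_rl"].to_numpy()
    nval = avg["n_valid_replicates"].to_numpy()

    candidate = np.abs(az) >= cfg.z_threshold
    rep_ok = avg["n_significant_replicates"].to_numpy() >= cfg.min_significant_replicates
    fl_ok = np.abs(afl) >= cfg.z_threshold
    if cfg.require_sign_consistency:
        fl_ok &= np.sign(afl) == np.sign(az)
    rl_ok = np.abs(arl) < cfg.z_threshold

    tiers, directions, flag_col = [], [], []
    for i in range(len(avg)):
        if nval[i] < cfg.min_significant_replicates:
            tiers.append(TIER_INSUFFICIENT)
            directions.append(DIR_NONE)
            flag_col.append("")
            continue
        flags = []
        if candidate[i]:
            if not rep_ok[i]:
                flags.append(FLAG_REPLICATE)
            if cfg.require_fl_significant and not fl_ok[i]:
                flags.append(FLAG_FL)
            if cfg.require_rl_nonsignificant and not rl_ok[i]:
                flags.append(FLAG_RL)
            tier = TIER_SIGNIFICANT if not flags else TIER_NOT
        else:
            tier = classify_z(az[i], cfg)
        tiers.append(tier)
        directions.append(_direction(tier, az[i]))
        flag_col.append(";".join(flags))

    out = avg.assign(tier=tiers, direction=directions, filter_flags=flag_col)
    cols = [
        "plate",
        "row",
        "column",
        "clone_id",
        "gene_id",
        "tier",
        "direction",
        "avg_z_ratio",
        "avg_z_fl",
        "avg_z_rl",
        "n_valid_replicates",
        "n_significant_replicates",
        "filter_flags",
    ]
    return out[cols]


def rescreen_hits(
    z_table: ZScoreTable, config: SelectionConfig | None = None
) -> pd.DataFrame:
    """Hit calls for a control-referenced re-screen.

    Tier assignment is by :func:`classify_z` on the averaged ratio Z with
    the same replicate rule; the single-channel FL/RL rules default to off
    (re-screens report the ratio Z only).
    """
    cfg = (config or SelectionConfig()).for_rescreen()
    return select_primary_hits(z_table, cfg)


def gene_calls(clone_calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse clone-level calls to gene level.

    The extreme clone (largest |avg Z|) represents the gene; clones of one
    gene called in opposite directions are flagged discordant.
    """
    df = clone_calls.copy()
    df["_abs"] = df["avg_z_ratio"].abs().fillna(-np.inf)
    order = df.sort_values("_abs", ascending=False, kind="mergesort")
    top = order.drop_duplicates(subset="gene_id", keep="first").drop(columns="_abs")
    called = df[df["tier"].isin([TIER_SIGNIFICANT, TIER_TRENDING])]
    n_dir = called.groupby("gene_id")["direction"].nunique()
    discordant = set(n_dir[n_dir > 1].index)
    top = top.assign(discordant_clones=top["gene_id"].isin(discordant))
    return top.sort_values(["plate", "row", "column"], kind="mergesort").reset_index(drop=True)


AVAIL_SCORED = "scored"
AVAIL_NA = "NA_excluded"
AVAIL_SINGLE_REP = "single_replicate_flag"
AVAIL_ABSENT = "not_in_library"


@dataclass
class ScreenComparison:
    """Join of two screens' calls with availability-aware overlap counts."""

    table: pd.DataFrame
    overlap_genes: set[str]
    na_excluded_genes: set[str]
    single_replicate_genes: set[str]
    not_in_library_genes: set[str]

    @property
    def overlap_count(self) -> int:
        return len(self.overlap_genes)


def compare_screens(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    availability_b: Mapping[str, str],
) -> ScreenComparison:
    """Compare hit lists of screen A against screen B at gene level.

    ``availability_b`` maps every gene of interest to its data status in
    screen B (scored / NA_excluded / single_replicate_flag / not_in_library).
    The overlap counts genes significant in both screens whose screen-B data
    is fully scored; genes lost to exclusions or to a single significant
    replicate are tallied separately, not as overlap.
    """
    a = calls_a[["gene_id", "tier"]].rename(columns={"tier": "tier_a"})
    b = calls_b[["gene_id", "tier"]].rename(columns={"tier": "tier_b"})
    joined = a.merge(b, on="gene_id", how="left")
    missing = [g for g in joined["gene_id"] if g not in availability_b]
    if missing:
        raise KeyError(f"genes absent from availability table: {sorted(set(missing))}")
    joined["availability_b"] = [availability_b[g] for g in joined["gene_id"]]

    a_hits = joined[joined["tier_a"] == TIER_SIGNIFICANT]
    overlap = set(
        a_hits.loc[
            (a_hits["tier_b"] == TIER_SIGNIFICANT)
            & (a_hits["availability_b"] == AVAIL_SCORED),
            "gene_id",
        ]
    )
    na = set(a_hits.loc[a_hits["availability_b"] == AVAIL_NA, "gene_id"])
    single = set(a_hits.loc[a_hits["availability_b"] == AVAIL_SINGLE_REP, "gene_id"])
    absent = set(a_hits.loc[a_hits["availability_b"] == AVAIL_ABSENT, "gene_id"])
    return ScreenComparison(
        table=joined,
        overlap_genes=overlap,
        na_excluded_genes=na,
        single_replicate_genes=single,
        not_in_library_genes=absent,
    )


def tertiary_confirmation(
    calls_primary: pd.DataFrame,
    calls_tertiary: pd.DataFrame,
    prior_multi_dsrna: Iterable[str] = (),
) -> set[str]:
    """Genes confirmed by an independent reagent design.

    A primary hit is confirmed when its tertiary (re-designed dsRNA) call is
    significant, or when it was already covered by two independent library
    reagents (``prior_multi_dsrna``).  The result is restricted to primary
    hits.
    """
    primary = set(
        calls_primary.loc[calls_primary["tier"] == TIER_SIGNIFICANT, "gene_id"]
    )
    tert = set(
        calls_tertiary.loc[calls_tertiary["tier"] == TIER_SIGNIFICANT, "gene_id"]
    )
    return (tert | set(prior_multi_dsrna)) & primary


def coverage_summary(
    layout,
    z_table: ZScoreTable,
    calls: pd.DataFrame,
    genome_size: int,
    config: SelectionConfig | None = None,
) -> pd.DataFrame:
    """Screen-level coverage counts, one row per statistic.

    Counts genes in the library, genes with no scoreable replicate pair
    (fully lost to exclusions), genes with a significant averaged ratio Z,
    and final hits after all selection rules; percentages are against the
    supplied genome size.
    """
    cfg = config or SelectionConfig()
    genes = layout.sample_genes()
    avg = z_table.averaged
    avg = avg[avg["role"] == "sample"]
    scoreable = avg[avg["n_valid_replicates"] >= cfg.min_significant_replicates]
    genes_scoreable = set(scoreable["gene_id"])
    excluded_genes = genes - genes_scoreable
    sig_avg = set(
        scoreable.loc[
            scoreable["avg_z_ratio"].abs() >= cfg.z_threshold, "gene_id"
        ]
    )
    final = set(calls.loc[calls["tier"] == TIER_SIGNIFICANT, "gene_id"])
    rows = [
        ("genes_in_library", len(genes)),
        ("genes_excluded_screening_errors", len(excluded_genes)),
        ("remaining_genome_coverage", len(genes_scoreable)),
        ("genes_significant_avg_ratio", len(sig_avg)),
        ("final_hits", len(final)),
    ]
    return pd.DataFrame(
        {
            "statistic": [r[0] for r in rows],
            "n_genes": [r[1] for r in rows],
            "pct_of_genome": [round(100.0 * r[1] / genome_size, 1) for r in rows],
        }
    )
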