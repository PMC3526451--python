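"""Plate normalisation and robust Z-scoring of dual-luciferase screens.

The scoring model follows standard high-throughput-screening practice for
FL/RL reporter ratios:

1. per well, the ratio FL/RL normalises pathway activity to cell number;
2. per plate, ratios (and each raw channel) are median-centred against the
   plate's reference wells, removing plate-to-plate gain differences;
3. per replicate, every centred value is converted to a robust Z-score
   ``Z = (x - median) / (1.4826 * MAD)`` against a reference population --
   either all sample wells of the replicate (genome mode) or the
   non-interacting control wells (control mode, used for re-screens whose
   plates are dominated by interacting wells).

Exclusions from the screen log are applied *before* any reference statistic
is computed, so an excluded well influences nothing downstream (two-pass
contract).  Z-scores of the replicates are then averaged per well.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .model import ScreenDataset, expand_exclusions

GENOME_REFERENCE = "plate_samples"
CONTROL_REFERENCE = "noninteracting_controls"


class DegenerateReferenceError(RuntimeError):
    """The reference population has zero spread (MAD = 0): Z-scores undefined."""


@dataclass
class ScoringConfig:
    """Constants of the normalisation / Z-scoring step.

    mad_scale
        Multiplier on the raw MAD; 1.4826 makes the MAD a consistent
        estimator of the standard deviation under normality.  Set 1.0 for
        the raw MAD.
    use_log2
        Score log2(FL/RL) instead of the linear ratio (centering becomes
        subtractive).  Luminescence noise is multiplicative, so log scale is
        a defensible alternative; linear is the default.
    z_reference
        ``plate_samples`` (genome mode) or ``noninteracting_controls``
        (control mode, for re-screens).
    min_reference_wells
        Minimum reference wells a plate must contribute; plates below it are
        flagged and their wells excluded (genome mode) or fall back to
        pooled control statistics (control mode).
    """

    mad_scale: float = 1.4826
    use_log2: bool = False
    z_reference: str = GENOME_REFERENCE
    min_reference_wells: int = 8
    z_threshold: float = 2.0
    trend_threshold: float = 1.7
    per_plate_z: bool = False  # genome mode: score within plates instead of replicate-wide

    def __post_init__(self) -> None:
        if self.mad_scale <= 0:
            raise ValueError("mad_scale must be > 0")
        if self.min_reference_wells < 3:
            raise ValueError("min_reference_wells must be >= 3")
        if not 0 < self.trend_threshold <= self.z_threshold:
            raise ValueError("need 0 < trend_threshold <= z_threshold")
        if self.z_reference not in (GENOME_REFERENCE, CONTROL_REFERENCE):
            raise ValueError(f"unknown z_reference {self.z_reference!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ScoringConfig":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        return cls(**{k: v for k, v in mapping.items() if k in known})


@dataclass
class ZScoreTable:
    """Per-replicate scores plus cross-replicate averages.

    ``per_replicate`` columns: plate, row, column, clone_id, gene_id, role,
    replicate, ratio, z_ratio, z_fl, z_rl, excluded, reason.
    ``averaged`` columns: the well key plus avg_z_ratio, avg_z_fl, avg_z_rl
    and n_valid_replicates (averages over non-excluded replicates only).
    """

    per_replicate: pd.DataFrame
    averaged: pd.DataFrame
    flags: list[str] = field(default_factory=list)


def compute_ratio(fl: float, rl: float, use_log2: bool = False) -> float | None:
    """FL/RL ratio of one well; ``None`` marks the well unscorable (RL <= 0,
    or FL <= 0 in log mode)."""
    if rl <= 0:
        return None
    if use_log2:
        if fl <= 0:
            return None
        return float(np.log2(fl / rl))
    return fl / rl


def robust_z(
    x: float | np.ndarray,
    reference: Iterable[float],
    config: ScoringConfig | None = None,
) -> float | np.ndarray:
    """Robust Z-score of ``x`` against a reference population.

    ``Z = (x - median(ref)) / (mad_scale * median(|ref - median(ref)|))``.
    Raises :class:`DegenerateReferenceError` when the reference MAD is zero
    and ``ValueError`` when the reference is smaller than
    ``min_reference_wells``.
    """
    cfg = config or ScoringConfig()
    ref = np.asarray(list(reference), dtype=float)
    if ref.size < cfg.min_reference_wells:
        raise ValueError(
            f"reference has {ref.size} wells, need >= {cfg.min_reference_wells}"
        )
    med = float(np.median(ref))
    mad = float(np.median(np.abs(ref - med)))
    if mad == 0.0:
        raise DegenerateReferenceError("reference MAD is zero")
    return (np.asarray(x, dtype=float) - med) / (cfg.mad_scale * mad)


def plate_median_center(
    values: np.ndarray,
    reference_values: np.ndarray,
    use_log2: bool = False,
) -> np.ndarray:
    """Centre all of a plate's values on the median of its reference wells.

    Linear mode divides by the reference median; log mode subtracts it.
    Reference wells contribute to the median; any well (controls included)
    is transformed.
    """
    med = float(np.median(np.asarray(reference_values, dtype=float)))
    vals = np.asarray(values, dtype=float)
    if use_log2:
        return vals - med
    if med <= 0:
        raise DegenerateReferenceError("plate reference median <= 0 in linear mode")
    return vals / med


def _mark(df: pd.DataFrame, mask: pd.Series | np.ndarray, reason: str) -> None:
    mask = np.asarray(mask, dtype=bool) & ~df["excluded"].to_numpy()
    df.loc[mask, "excluded"] = True
    df.loc[mask, "reason"] = reason


def _ref_stats(values: np.ndarray, cfg: ScoringConfig) -> tuple[float, float]:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, mad


def score_replicate(
    dataset: ScreenDataset,
    exclusions: pd.DataFrame | None,
    config: ScoringConfig,
    replicate: int,
) -> pd.DataFrame:
    """Score one replicate: ratios, plate centering, robust Z per channel.

    Returns the per-replicate frame described by :class:`ZScoreTable`.
    Degenerate plates/references are propagated as exclusion flags on the
    affected wells, never as silent zeros.
    """
    ann = dataset.layout.annotations
    meas = dataset.measurements
    meas = meas[meas["replicate"] == replicate]
    wide = (
        meas.pivot_table(
            index=["plate", "row", "column"],
            columns="channel",
            values="intensity",
            aggfunc="first",
        )
        .reindex(columns=["FL", "RL"])
        .reset_index()
    )
    wide.columns.name = None
    df = ann.merge(wide, on=["plate", "row", "column"], how="left")
    df["replicate"] = replicate
    df["excluded"] = False
    df["reason"] = ""

    _mark(df, df["role"] == "empty", "empty")

    excl = expand_exclusions(exclusions, dataset.replicates)
    if len(excl):
        excl = excl[excl["replicate"] == replicate]
    if len(excl):
        hit = df.merge(
            excl[["plate", "row", "column", "reason"]].rename(columns={"reason": "_xreason"}),
            on=["plate", "row", "column"],
            how="left",
        )["_xreason"]
        for reason in hit.dropna().unique():
            _mark(df, (hit == reason).to_numpy(), str(reason))

    fl = df["FL"].to_numpy(dtype=float)
    rl = df["RL"].to_numpy(dtype=float)
    _mark(df, np.isnan(fl) | np.isnan(rl), "other")  # missing channel
    _mark(df, rl <= 0, "other")
    if config.use_log2:
        _mark(df, fl <= 0, "other")

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rl > 0, fl / rl, np.nan)
        if config.use_log2:
            ratio = np.where((rl > 0) & (fl > 0), np.log2(np.where(fl > 0, fl, 1.0) / rl), np.nan)
    df["ratio"] = ratio
    df["_fl_raw"] = fl
    df["_rl_raw"] = rl

    ref_role = "sample" if config.z_reference == GENOME_REFERENCE else "noninteracting_control"
    flags: list[str] = []

    # --- per-plate centering -------------------------------------------------
    for col_in, col_out in (("ratio", "c_ratio"), ("_fl_raw", "c_fl"), ("_rl_raw", "c_rl")):
        df[col_out] = np.nan
    for plate, idx in df.groupby("plate").groups.items():
        sub = df.loc[idx]
        ok = ~sub["excluded"]
        ref = ok & (sub["role"] == ref_role)
        if ref.sum() < config.min_reference_wells:
            if config.z_reference == CONTROL_REFERENCE:
                # fall back to the plate's sample wells for centering only
                ref = ok & (sub["role"] == "sample")
            if ref.sum() < config.min_reference_wells:
                flags.append(f"plate {plate} replicate {replicate}: too few reference wells")
                _mark(df, df.index.isin(idx), "other")
                continue
        for col_in, col_out in (("ratio", "c_ratio"), ("_fl_raw", "c_fl"), ("_rl_raw", "c_rl")):
            ref_vals = sub.loc[ref, col_in].to_numpy(dtype=float)
            try:
                df.loc[idx, col_out] = plate_median_center(
                    sub[col_in].to_numpy(dtype=float), ref_vals, config.use_log2
                )
            except DegenerateReferenceError:
                flags.append(
                    f"plate {plate} replicate {replicate}: degenerate centering median ({col_in})"
                )
                _mark(df, df.index.isin(idx), "other")
                break

    # --- robust Z against the replicate-wide reference population -----------
    ok = ~df["excluded"].to_numpy()
    is_ref = ok & (df["role"] == ref_role).to_numpy()
    for z_col, c_col in (("z_ratio", "c_ratio"), ("z_fl", "c_fl"), ("z_rl", "c_rl")):
        df[z_col] = np.nan
        vals = df[c_col].to_numpy(dtype=float)

        def z_from(ref_vals: np.ndarray, target: np.ndarray) -> np.ndarray | None:
            med, mad = _ref_stats(ref_vals, config)
            if mad == 0.0:
                return None
            return (target - med) / (config.mad_scale * mad)

        if config.z_reference == GENOME_REFERENCE and not config.per_plate_z:
            ref_vals = vals[is_ref & ~np.isnan(vals)]
            if ref_vals.size < config.min_reference_wells:
                flags.append(f"replicate {replicate}: too few reference wells for {z_col}")
                _mark(df, ok, "other")
                break
            z = z_from(ref_vals, vals)
            if z is None:
                flags.append(f"replicate {replicate}: degenerate reference MAD for {z_col}")
                _mark(df, ok, "other")
                break
            df.loc[ok, z_col] = z[ok]
        else:
            # per-plate references; control mode pools plates whose control
            # count falls below min_reference_wells
            pooled = vals[is_ref & ~np.isnan(vals)]
            for plate, idx in df.groupby("plate").groups.items():
                in_plate = df.index.isin(idx)
                plate_ok = ok & in_plate
                plate_ref = vals[is_ref & in_plate & ~np.isnan(vals)]
                ref_vals = (
                    plate_ref if plate_ref.size >= config.min_reference_wells else pooled
                )
                if ref_vals.size < config.min_reference_wells:
                    flags.append(
                        f"plate {plate} replicate {replicate}: too few reference wells for {z_col}"
                    )
                    _mark(df, plate_ok, "other")
                    continue
                z = z_from(ref_vals, vals)
                if z is None:
                    flags.append(
                        f"plate {plate} replicate {replicate}: degenerate reference for {z_col}"
                    )
                    _mark(df, plate_ok, "other")
                    continue
                df.loc[plate_ok, z_col] = z[plate_ok]

    # excluded wells carry no values at all
    for col in ("ratio", "z_ratio", "z_fl", "z_rl"):
        df.loc[df["excluded"], col] = np.nan

    out = df[
        [
            "plate",
            "row",
            "column",
            "clone_id",
            "gene_id",
            "role",
            "replicate",
            "ratio",
            "z_ratio",
            "z_fl",
            "z_rl",
            "excluded",
            "reason",
        ]
    ].copy()
    out.attrs["flags"] = flags
    return out


def average_replicates(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of each Z column over non-excluded replicates per well."""
    valid = per_replicate[~per_replicate["excluded"] & per_replicate["z_ratio"].notna()]
    key = ["plate", "row", "column", "clone_id", "gene_id", "role"]
    base = per_replicate[key].drop_duplicates().reset_index(drop=True)
    if len(valid):
        agg = (
            valid.groupby(key, as_index=False)
            .agg(
                avg_z_ratio=("z_ratio", "mean"),
                avg_z_fl=("z_fl", "mean"),
                avg_z_rl=("z_rl", "mean"),
                n_valid_replicates=("replicate", "size"),
            )
        )
        out = base.merge(agg, on=key, how="left")
    else:
        out = base.assign(
            avg_z_ratio=np.nan, avg_z_fl=np.nan, avg_z_rl=np.nan, n_valid_replicates=0
        )
    out["n_valid_replicates"] = out["n_valid_replicates"].fillna(0).astype(int)
    return out.sort_values(["plate", "row", "column"], kind="mergesort").reset_index(drop=True)


def score_screen(
    dataset: ScreenDataset,
    exclusions: pd.DataFrame | None = None,
    config: ScoringConfig | None = None,
) -> ZScoreTable:
    """Score every replicate of a screen and average the replicate Z-scores."""
    cfg = config or ScoringConfig()
    if dataset.replicates < 2:
        raise ValueError("hit selection requires >= 2 replicates")
    frames, flags = [], []
    for rep in range(1, dataset.replicates + 1):
        scored = score_replicate(dataset, exclusions, cfg, rep)
        flags.extend(scored.attrs.get("flags", []))
        frames.append(scored)
    per_rep = pd.concat(frames, ignore_index=True)
    return ZScoreTable(per_replicate=per_rep, averaged=average_replicates(per_rep), flags=flags)
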