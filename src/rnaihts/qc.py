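"""Quality-control summaries: per-plate box statistics, plate heat-map
matrices, and single-channel scatter tables.

All QC outputs are numeric tables; plotting is a thin optional layer (see
:func:`render_heatmap`), so the statistics can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import N_COLUMNS, N_ROWS, ROW_LETTERS
from .scoring import ZScoreTable


def plate_boxstats(z_table: ZScoreTable, value: str = "z_ratio") -> pd.DataFrame:
    """Box/whisker statistics per replicate x plate on non-excluded sample wells.

    Quartiles use linear interpolation (the numpy default, "type 7");
    whiskers follow the 1.5 x IQR rule (most extreme data point inside the
    fence); notches are ``median -/+ 1.57 x IQR / sqrt(n)`` -- non-overlap
    of two plates' notches suggests significantly different medians.
    """
    per = z_table.per_replicate
    per = per[(per["role"] == "sample") & ~per["excluded"] & per[value].notna()]
    rows = []
    for (rep, plate), grp in per.groupby(["replicate", "plate"]):
        v = grp[value].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = v[(v >= lo_fence) & (v <= hi_fence)]
        notch = 1.57 * iqr / np.sqrt(v.size)
        rows.append(
            {
                "replicate": rep,
                "plate": plate,
                "n": v.size,
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": iqr,
                "whisker_low": inside.min(),
                "whisker_high": inside.max(),
                "notch_low": med - notch,
                "notch_high": med + notch,
                "n_outliers": int(((v < lo_fence) | (v > hi_fence)).sum()),
            }
        )
    return pd.DataFrame(rows)


def heatmap_matrices(
    z_table: ZScoreTable,
    filtered: bool = False,
    exclusions: pd.DataFrame | None = None,
) -> dict[int, np.ndarray]:
    """One 16 x 24 matrix of averaged ratio Z-scores per plate.

    Wells without a value are NaN, never zero-filled.  With
    ``filtered=True`` control wells and wells named in ``exclusions``
    (any replicate) are masked out as well, mirroring the
    unfiltered-versus-filtered heat-map pair used for error spotting.
    """
    avg = z_table.averaged
    excl_set: set[tuple[int, str, int]] = set()
    if exclusions is not None and len(exclusions):
        excl_set = {
            (int(p), r, int(c))
            for p, r, c in zip(exclusions["plate"], exclusions["row"], exclusions["column"])
        }
    out: dict[int, np.ndarray] = {}
    for plate, grp in avg.groupby("plate"):
        mat = np.full((N_ROWS, N_COLUMNS), np.nan)
        for rec in grp.itertuples(index=False):
            if filtered and rec.role != "sample":
                continue
            if filtered and (int(rec.plate), rec.row, int(rec.column)) in excl_set:
                continue
            mat[ROW_LETTERS.index(rec.row), rec.column - 1] = rec.avg_z_ratio
        out[int(plate)] = mat
    return out


def channel_scatter_table(
    z_table: ZScoreTable,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Per-well averaged single-channel Z-scores for FL-vs-RL scatter QC.

    ``rl_only_flag`` marks the suspect region of RL-stability artefacts:
    a significant RL Z with a non-significant FL Z.
    """
    avg = z_table.averaged
    avg = avg[avg["n_valid_replicates"] > 0]
    if len(avg) == 0:
        return pd.DataFrame(
            columns=["clone_id", "gene_id", "role", "z_fl", "z_rl", "rl_only_flag"]
        )
    out = pd.DataFrame(
        {
            "clone_id": avg["clone_id"],
            "gene_id": avg["gene_id"],
            "role": avg["role"],
            "z_fl": avg["avg_z_fl"],
            "z_rl": avg["avg_z_rl"],
        }
    )
    out["rl_only_flag"] = (out["z_rl"].abs() >= z_threshold) & (
        out["z_fl"].abs() < z_threshold
    )
    return out.reset_index(drop=True)


def render_heatmap(matrix: np.ndarray, path: str | Path, title: str = "") -> None:
    """Optional cosmetic rendering of one plate matrix to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 5))
    im = ax.imshow(matrix, cmap="RdBu_r", vmin=-5, vmax=5)
    ax.set_yticks(range(N_ROWS), list(ROW_LETTERS))
    ax.set_xticks(range(0, N_COLUMNS, 2), [str(c) for c in range(1, N_COLUMNS + 1, 2)])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="average Z (FL/RL)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
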