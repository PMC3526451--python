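"""Synthetic dual-luciferase screen generator.

Generates complete screens -- library layouts with control wells and a
plate-identifying DIAP1 barcode, per-gene ground truth, two-channel
measurements with realistic artefacts, and off-target prediction graphs --
so every pipeline stage can be exercised without external data.

The measurement model is multiplicative throughout, reflecting positive,
heteroscedastic luminescence readouts:

    I_channel = baseline x gene_effect x plate_gain x edge_bias x noise

with mean-one lognormal well noise per channel, independent per-plate and
per-replicate channel gains, an optional edge-row bias applied to a random
subset of plate copies, rare dropout wells reading near zero, and explicit
whole-plate liquid-handling failures.  Gene effects are channel-specific by
class: pathway regulators move FL only, viability genes move both channels
proportionately (invisible to the FL/RL ratio), and RL-stability artefact
genes move RL only -- the class whose ratio scores the single-channel hit
rules exist to reject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .model import (
    N_COLUMNS,
    ROW_LETTERS,
    LibraryLayout,
    ScreenDataset,
)
from .ote import OteGraph

CLASS_NULL = "null"
CLASS_POS = "pos_regulator"
CLASS_NEG = "neg_regulator"
CLASS_VIABILITY = "viability"
CLASS_RL_ARTIFACT = "rl_artifact"
GENE_CLASSES = (CLASS_NULL, CLASS_POS, CLASS_NEG, CLASS_VIABILITY, CLASS_RL_ARTIFACT)


@dataclass
class TruthModel:
    """Ground-truth gene classes and their channel effects.

    Proportions roughly match a signalling screen: a fraction of a percent
    of true regulators in either direction, a small viability class and a
    small RL-stability artefact class.  ``pos_fl_factor`` is the FL
    multiplier on knockdown of a positive regulator (reporter down),
    ``neg_fl_factor`` of a negative regulator (reporter up);
    ``viability_factor`` hits both channels; ``rl_artifact_factor`` hits RL
    only.
    """

    p_null: float = 0.97
    p_pos: float = 0.005
    p_neg: float = 0.005
    p_viability: float = 0.015
    p_rl_artifact: float = 0.005
    pos_fl_factor: float = 0.25
    neg_fl_factor: float = 4.0
    viability_factor: float = 0.3
    rl_artifact_factor: float = 3.0

    def __post_init__(self) -> None:
        props = self.proportions
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        for f in (
            self.pos_fl_factor,
            self.neg_fl_factor,
            self.viability_factor,
            self.rl_artifact_factor,
        ):
            if f <= 0:
                raise ValueError("effect factors must be > 0")

    @property
    def proportions(self) -> dict[str, float]:
        return {
            CLASS_NULL: self.p_null,
            CLASS_POS: self.p_pos,
            CLASS_NEG: self.p_neg,
            CLASS_VIABILITY: self.p_viability,
            CLASS_RL_ARTIFACT: self.p_rl_artifact,
        }

    def factors(self, gene_class: str) -> tuple[float, float]:
        """(FL multiplier, RL multiplier) of a gene class."""
        return {
            CLASS_NULL: (1.0, 1.0),
            CLASS_POS: (self.pos_fl_factor, 1.0),
            CLASS_NEG: (self.neg_fl_factor, 1.0),
            CLASS_VIABILITY: (self.viability_factor, self.viability_factor),
            CLASS_RL_ARTIFACT: (1.0, self.rl_artifact_factor),
        }[gene_class]


@dataclass
class ErrorModel:
    """Technical artefacts layered onto the measurements.

    ``plate_gain_sd`` is the lognormal sigma of independent per-plate,
    per-replicate, per-channel gains; ``well_cv`` the coefficient of
    variation of mean-one lognormal well noise per channel.  Edge bias
    multiplies ``edge_rows`` wells by ``edge_factor`` on the channels in
    ``edge_channels`` (FL only by default, so the artefact survives the
    ratio) for a random ``edge_plate_prob`` fraction of plate copies.
    ``dropout_prob`` wells read uniformly in (0, 1%) of baseline on both
    channels; ``failed_plates`` lists (replicate, plate) pairs whose whole
    plate reads like dropout -- the liquid-handling failure mode the screen
    log exists to remove.
    """

    plate_gain_sd: float = 0.15
    well_cv: float = 0.1
    edge_rows: tuple[str, ...] = ("A", "B")
    edge_factor: float = 0.7
    edge_plate_prob: float = 0.05
    edge_channels: tuple[str, ...] = ("FL",)
    dropout_prob: float = 0.001
    failed_plates: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for p in (self.edge_plate_prob, self.dropout_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.edge_factor <= 0 or self.plate_gain_sd < 0 or self.well_cv < 0:
            raise ValueError("factors must be > 0 and spreads >= 0")

    @classmethod
    def noise_free(cls) -> "ErrorModel":
        return cls(plate_gain_sd=0.0, well_cv=0.0, edge_plate_prob=0.0, dropout_prob=0.0)


# (role, gene, FL factor, RL factor) of the fixed control columns 23/24
CONTROL_PLAN = (
    ("pos_control", "dome", 0.15, 1.0),
    ("pos_control", "hop", 0.15, 1.0),
    ("neg_control", "Socs36E", 3.0, 1.0),
    ("neg_control", "Socs36E", 3.0, 1.0),
    ("tech_control_rl", "RLuc", 1.0, 0.1),
    ("tech_control_rl", "RLuc", 1.0, 0.1),
    ("tech_control_gfp", "GFP", 0.6, 1.0),
    ("tech_control_gfp", "GFP", 0.6, 1.0),
    ("noninteracting_control", "ZK686.3", 1.0, 1.0),
    ("noninteracting_control", "ZK686.3", 1.0, 1.0),
    ("noninteracting_control", "ZK686.3", 1.0, 1.0),
    ("noninteracting_control", "ZK686.3", 1.0, 1.0),
)

DIAP1_FACTORS = (0.05, 0.05)  # strong cell death: both channels collapse
N_BARCODE_WELLS = 6


@dataclass
class SimulationConfig:
    """Shape of the simulated screen.

    Defaults mirror a genome-scale screen: 53 plates per genome copy,
    triplicate, two control columns per plate (a 6-well DIAP1 barcode plus
    duplicated pathway, technical and non-interacting controls), the
    remainder library samples (352 genes/plate, one clone per gene).
    Baseline intensities are arbitrary (all downstream statistics are
    scale-invariant) and documented: FL 1e4, RL 1e5 relative light units.
    """

    n_plates: int = 53
    replicates: int = 3
    seed: int = 0
    fl_baseline: float = 1.0e4
    rl_baseline: float = 1.0e5
    control_columns: bool = True  # False: all 384 wells are samples
    n_noninteracting_extra: int = 0  # extra non-interacting wells (re-screen layouts)
    ote_density: float = 0.3  # fraction of clones with >= 1 predicted off-target
    ote_max_edges: int = 3
    ote_circular_fraction: float = 0.05  # fraction of edges aimed at regulator genes


def barcode_rows(plate: int) -> tuple[str, ...]:
    """Plate-unique DIAP1 barcode: the 6 rows carrying lethal wells.

    Documented bijection: the plate number (1-based) indexes the
    lexicographic 6-of-16 row combination (combinatorial number system),
    so every plate up to C(16,6) = 8008 gets a distinct pattern.
    """
    if plate < 1 or plate > comb(16, 6):
        raise ValueError("plate out of barcode range")
    rank = plate - 1
    rows, start = [], 0
    for slots in range(6, 0, -1):
        for candidate in range(start, 16):
            block = comb(16 - candidate - 1, slots - 1)
            if rank < block:
                rows.append(ROW_LETTERS[candidate])
                start = candidate + 1
                break
            rank -= block
    return tuple(rows)


def simulate_library(
    config: SimulationConfig | None = None,
    truth_model: TruthModel | None = None,
) -> tuple[LibraryLayout, pd.DataFrame, OteGraph]:
    """Generate a layout, its per-gene ground truth, and an OTE graph.

    Deterministic given ``config.seed``.  Ground-truth columns: clone_id,
    gene_id, class, fl_factor, rl_factor.
    """
    cfg = config or SimulationConfig()
    tm = truth_model or TruthModel()
    rng = np.random.default_rng(cfg.seed)

    records: list[tuple] = []
    gene_counter = 0
    for plate in range(1, cfg.n_plates + 1):
        barcode = set(barcode_rows(plate)) if cfg.control_columns else set()
        control_cells: list[tuple[str, str, str]] = []  # (role, clone, gene)
        for role, gene, _, _ in CONTROL_PLAN:
            control_cells.append((role, f"CTRL-{gene}", gene))
        control_cells.extend(
            ("noninteracting_control", "CTRL-ZK686.3", "ZK686.3")
            for _ in range(cfg.n_noninteracting_extra)
        )
        control_positions = [
            (row, col)
            for col in (23, 24)
            for row in ROW_LETTERS
            if not (col == 24 and row in barcode)
        ]
        if len(control_cells) > len(control_positions):
            raise ValueError("control layout does not fit on the plate")
        for row in ROW_LETTERS:
            for col in range(1, N_COLUMNS + 1):
                if not cfg.control_columns:
                    gene_counter += 1
                    records.append(
                        (plate, row, col, f"SIM{gene_counter:05d}", f"g{gene_counter:05d}", "sample")
                    )
                elif col == 24 and row in barcode:
                    records.append((plate, row, col, "CTRL-DIAP1", "DIAP1", "lethal_control"))
                elif col >= 23:
                    pos_idx = control_positions.index((row, col))
                    if pos_idx < len(control_cells):
                        role, clone, gene = control_cells[pos_idx]
                        records.append((plate, row, col, clone, gene, role))
                    else:
                        records.append((plate, row, col, "", "", "empty"))
                else:
                    gene_counter += 1
                    records.append(
                        (
                            plate,
                            row,
                            col,
                            f"SIM{gene_counter:05d}",
                            f"g{gene_counter:05d}",
                            "sample",
                        )
                    )
    ann = pd.DataFrame(
        records, columns=["plate", "row", "column", "clone_id", "gene_id", "role"]
    )
    layout = LibraryLayout(
        name=f"synthetic-{cfg.n_plates}x384", annotations=ann, replicate_count_expected=cfg.replicates
    )

    samples = ann[ann["role"] == "sample"]
    clones = samples["clone_id"].to_numpy()
    genes = samples["gene_id"].to_numpy()
    classes = rng.choice(
        GENE_CLASSES, size=len(genes), p=[tm.proportions[c] for c in GENE_CLASSES]
    )
    factors = np.array([tm.factors(c) for c in classes])
    truth = pd.DataFrame(
        {
            "clone_id": clones,
            "gene_id": genes,
            "class": classes,
            "fl_factor": factors[:, 0],
            "rl_factor": factors[:, 1],
        }
    )

    regulator_genes = truth.loc[
        truth["class"].isin([CLASS_POS, CLASS_NEG]), "gene_id"
    ].to_numpy()
    on_target = dict(zip(clones, genes))
    off_targets: dict[str, set[str]] = {c: set() for c in clones}
    has_predictions = rng.random(len(clones)) < cfg.ote_density
    for clone, gene, flagged in zip(clones, genes, has_predictions):
        if not flagged:
            continue
        n_edges = int(rng.integers(1, cfg.ote_max_edges + 1))
        for _ in range(n_edges):
            if regulator_genes.size and rng.random() < cfg.ote_circular_fraction:
                target = str(rng.choice(regulator_genes))
            else:
                target = str(rng.choice(genes))
            if target != gene:
                off_targets[clone].add(target)
    graph = OteGraph(
        on_target=on_target, off_targets={c: frozenset(s) for c, s in off_targets.items()}
    )
    return layout, truth, graph


def _control_factor_map() -> dict[str, tuple[float, float]]:
    out = {"CTRL-DIAP1": DIAP1_FACTORS}
    for role, gene, fl, rl in CONTROL_PLAN:
        out[f"CTRL-{gene}"] = (fl, rl)
    return out


def simulate_measurements(
    layout: LibraryLayout,
    truth: pd.DataFrame,
    error_model: ErrorModel | None = None,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> ScreenDataset:
    """Generate two-channel intensities for every well of every replicate.

    Dropout and failed-plate wells still emit records (near-zero signal), so
    record count is always wells x replicates x 2.  Deterministic given the
    seed (``config.seed + 1`` unless overridden, keeping the library and
    measurement streams independent).
    """
    cfg = config or SimulationConfig()
    em = error_model or ErrorModel()
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    ann = layout.annotations
    n = len(ann)
    fac_map = {
        c: (f, r)
        for c, f, r in zip(truth["clone_id"], truth["fl_factor"], truth["rl_factor"])
    }
    fac_map.update(_control_factor_map())
    pairs = np.array([fac_map.get(c, (1.0, 1.0)) for c in ann["clone_id"]])
    fl_fac, rl_fac = pairs[:, 0], pairs[:, 1]

    plates = ann["plate"].to_numpy()
    plate_ids = np.unique(plates)
    plate_pos = np.searchsorted(plate_ids, plates)
    edge_row = ann["row"].isin(em.edge_rows).to_numpy()
    failed = set(em.failed_plates)

    sigma = float(np.sqrt(np.log1p(em.well_cv**2)))
    frames = []
    for rep in range(1, cfg.replicates + 1):
        gain_fl = np.exp(rng.normal(0.0, em.plate_gain_sd, size=plate_ids.size))
        gain_rl = np.exp(rng.normal(0.0, em.plate_gain_sd, size=plate_ids.size))
        edge_plate = rng.random(plate_ids.size) < em.edge_plate_prob
        noise_fl = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n)) if sigma else np.ones(n)
        noise_rl = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n)) if sigma else np.ones(n)

        fl = cfg.fl_baseline * fl_fac * gain_fl[plate_pos] * noise_fl
        rl = cfg.rl_baseline * rl_fac * gain_rl[plate_pos] * noise_rl
        on_edge = edge_plate[plate_pos] & edge_row
        if "FL" in em.edge_channels:
            fl = np.where(on_edge, fl * em.edge_factor, fl)
        if "RL" in em.edge_channels:
            rl = np.where(on_edge, rl * em.edge_factor, rl)

        dropout = rng.random(n) < em.dropout_prob
        plate_failed = np.array([(rep, int(p)) in failed for p in plates])
        dead = dropout | plate_failed
        if dead.any():
            fl = np.where(dead, rng.uniform(0.0, 0.01 * cfg.fl_baseline, size=n), fl)
            rl = np.where(dead, rng.uniform(0.0, 0.01 * cfg.rl_baseline, size=n), rl)

        for channel, values in (("FL", fl), ("RL", rl)):
            frames.append(
                pd.DataFrame(
                    {
                        "plate": ann["plate"],
                        "row": ann["row"],
                        "column": ann["column"],
                        "replicate": rep,
                        "channel": channel,
                        "intensity": values,
                    }
                )
            )
    measurements = pd.concat(frames, ignore_index=True)
    return ScreenDataset(layout=layout, measurements=measurements, replicates=cfg.replicates)


def simulate_screen(
    config: SimulationConfig | None = None,
    truth_model: TruthModel | None = None,
    error_model: ErrorModel | None = None,
) -> tuple[ScreenDataset, pd.DataFrame, OteGraph]:
    """One-call convenience: library + truth + OTE graph + measurements."""
    cfg = config or SimulationConfig()
    layout, truth, graph = simulate_library(cfg, truth_model)
    dataset = simulate_measurements(layout, truth, error_model, cfg)
    return dataset, truth, graph
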