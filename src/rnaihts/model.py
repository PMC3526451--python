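"""Domain types for 384-well dual-luciferase RNAi screening data.

A screen is a stack of 384-well plates (16 rows A-P x 24 columns), each well
holding one dsRNA clone targeting one gene, read in two luminescence channels:
FL (Firefly luciferase, the pathway reporter) and RL (Renilla luciferase, a
constitutive viability proxy).  Plates carry control wells -- pathway
regulators, technical controls and a plate-identifying "barcode" of lethal
DIAP1 wells -- alongside the library samples.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

ROW_LETTERS = "ABCDEFGHIJKLMNOP"
N_ROWS = 16
N_COLUMNS = 24
WELLS_PER_PLATE = N_ROWS * N_COLUMNS


class ScreenFormatError(ValueError):
    """A table could not be parsed into a valid screen object."""


class WellRole(str, Enum):
    SAMPLE = "sample"
    POS_CONTROL = "pos_control"
    NEG_CONTROL = "neg_control"
    LETHAL_CONTROL = "lethal_control"
    TECH_CONTROL_RL = "tech_control_rl"
    TECH_CONTROL_GFP = "tech_control_gfp"
    NONINTERACTING_CONTROL = "noninteracting_control"
    EMPTY = "empty"


ROLE_VALUES = frozenset(r.value for r in WellRole)
CONTROL_ROLES = frozenset(
    r.value for r in WellRole if r not in (WellRole.SAMPLE, WellRole.EMPTY)
)


class ExclusionReason(str, Enum):
    EDGE_EFFECT = "edge_effect"
    LIQUID_HANDLING = "liquid_handling"
    CONTAMINATION = "contamination"
    CONTROL = "control"
    EMPTY = "empty"
    OTHER = "other"


REASON_VALUES = frozenset(r.value for r in ExclusionReason)

CHANNELS = ("FL", "RL")

_WELL_RE = re.compile(r"^P(\d+)-([A-P])(\d{2})$")


@dataclass(frozen=True, order=True)
class WellAddress:
    """Position of a well: 1-based plate, row letter A-P, column 1-24.

    Ordering is (plate, row, column), a total order.  The canonical string
    form is ``P<plate>-<row><zero-padded column>``, e.g. ``P12-A01``.
    """

    plate: int
    row: str
    column: int

    def __post_init__(self) -> None:
        if self.plate < 1:
            raise ValueError(f"plate index must be >= 1, got {self.plate}")
        if self.row not in ROW_LETTERS:
            raise ValueError(f"row must be one of {ROW_LETTERS!r}, got {self.row!r}")
        if not 1 <= self.column <= N_COLUMNS:
            raise ValueError(f"column must be in 1..{N_COLUMNS}, got {self.column}")

    def __str__(self) -> str:
        return f"P{self.plate}-{self.row}{self.column:02d}"

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = _WELL_RE.match(text)
        if m is None:
            raise ScreenFormatError(f"not a well address: {text!r}")
        return cls(plate=int(m.group(1)), row=m.group(2), column=int(m.group(3)))


@dataclass(frozen=True)
class WellAnnotation:
    """Library annotation of one well: which clone, which gene, which role."""

    address: WellAddress
    clone_id: str
    gene_id: str
    role: WellRole

    def __post_init__(self) -> None:
        empty_ids = self.clone_id == "" and self.gene_id == ""
        if (self.role == WellRole.EMPTY) != empty_ids:
            raise ValueError(
                f"{self.address}: clone_id/gene_id must be empty iff role is "
                f"'empty' (role={self.role.value}, clone={self.clone_id!r})"
            )


@dataclass(frozen=True)
class Measurement:
    """One luminescence reading: well x replicate x channel, in relative
    light units (non-negative)."""

    address: WellAddress
    replicate: int
    channel: str
    intensity: float

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.intensity < 0:
            raise ValueError(f"{self.address}: negative intensity {self.intensity}")


LAYOUT_COLUMNS = ["plate", "row", "column", "clone_id", "gene_id", "role"]


def _check_well_columns(df: pd.DataFrame, where: str) -> None:
    bad_row = ~df["row"].isin(list(ROW_LETTERS))
    if bad_row.any():
        i = int(np.flatnonzero(bad_row.to_numpy())[0])
        raise ScreenFormatError(f"{where}: invalid row {df['row'].iloc[i]!r} (record {i + 1})")
    col = df["column"].to_numpy()
    bad_col = (col < 1) | (col > N_COLUMNS)
    if bad_col.any():
        i = int(np.flatnonzero(bad_col)[0])
        raise ScreenFormatError(f"{where}: invalid column {col[i]} (record {i + 1})")
    if (df["plate"].to_numpy() < 1).any():
        raise ScreenFormatError(f"{where}: plate indices must be >= 1")


@dataclass
class LibraryLayout:
    """Well-level annotation of a screening library.

    ``annotations`` is a table with columns plate, row, column, clone_id,
    gene_id, role.  Addresses are unique; clone_id (not gene_id) is the
    primary reagent key -- one gene may be covered by several clones.
    """

    name: str
    annotations: pd.DataFrame
    replicate_count_expected: int = 3

    def __post_init__(self) -> None:
        df = self.annotations
        missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise ScreenFormatError(f"layout {self.name!r}: missing columns {missing}")
        df = df[LAYOUT_COLUMNS].copy()
        df["plate"] = df["plate"].astype(int)
        df["column"] = df["column"].astype(int)
        df["row"] = df["row"].astype(str)
        for c in ("clone_id", "gene_id", "role"):
            df[c] = df[c].fillna("").astype(str)
        _check_well_columns(df, f"layout {self.name!r}")
        bad_roles = set(df["role"]) - ROLE_VALUES
        if bad_roles:
            raise ScreenFormatError(f"layout {self.name!r}: unknown roles {sorted(bad_roles)}")
        dup = df.duplicated(subset=["plate", "row", "column"], keep=False)
        if dup.any():
            first = df.loc[dup].iloc[0]
            addr = WellAddress(int(first.plate), first.row, int(first.column))
            raise ScreenFormatError(f"layout {self.name!r}: duplicate address {addr}")
        is_empty_role = df["role"] == WellRole.EMPTY.value
        has_ids = (df["clone_id"] != "") | (df["gene_id"] != "")
        if (is_empty_role & has_ids).any() or (~is_empty_role & ~has_ids).any():
            raise ScreenFormatError(
                f"layout {self.name!r}: clone/gene IDs must be empty iff role is 'empty'"
            )
        per_plate = df.groupby("plate")["role"].apply(lambda r: (r == "sample").sum())
        plateless = per_plate[per_plate == 0]
        if len(plateless):
            raise ScreenFormatError(
                f"layout {self.name!r}: plates without sample wells: {list(plateless.index)}"
            )
        df = df.sort_values(["plate", "row", "column"], kind="mergesort").reset_index(drop=True)
        self.annotations = df

    @property
    def plates(self) -> list[int]:
        return sorted(self.annotations["plate"].unique().tolist())

    @property
    def n_wells(self) -> int:
        return len(self.annotations)

    def sample_genes(self) -> set[str]:
        df = self.annotations
        return set(df.loc[df["role"] == "sample", "gene_id"])


MEASUREMENT_COLUMNS = ["plate", "row", "column", "replicate", "channel", "intensity"]


@dataclass
class ValidationReport:
    """Completeness check of a measurement set against its layout."""

    n_expected: int
    n_present: int
    missing: pd.DataFrame  # plate,row,column,replicate,channel combinations absent

    @property
    def complete(self) -> bool:
        return len(self.missing) == 0


@dataclass
class ScreenDataset:
    """Raw two-channel intensities for every well of every replicate."""

    layout: LibraryLayout
    measurements: pd.DataFrame
    replicates: int

    def __post_init__(self) -> None:
        df = self.measurements
        missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ScreenFormatError(f"measurements: missing columns {missing}")
        df = df[MEASUREMENT_COLUMNS].copy()
        df["plate"] = df["plate"].astype(int)
        df["column"] = df["column"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        df["intensity"] = df["intensity"].astype(float)
        _check_well_columns(df, "measurements")
        bad_ch = set(df["channel"]) - set(CHANNELS)
        if bad_ch:
            raise ScreenFormatError(f"measurements: unknown channels {sorted(bad_ch)}")
        neg = df["intensity"].to_numpy() < 0
        if neg.any():
            i = int(np.flatnonzero(neg)[0])
            r = df.iloc[i]
            addr = WellAddress(int(r.plate), r.row, int(r.column))
            raise ScreenFormatError(
                f"measurements: negative intensity {r.intensity} at {addr} "
                f"replicate {r.replicate} channel {r.channel}"
            )
        dup = df.duplicated(subset=["plate", "row", "column", "replicate", "channel"])
        if dup.any():
            r = df.loc[dup].iloc[0]
            addr = WellAddress(int(r.plate), r.row, int(r.column))
            raise ScreenFormatError(
                f"measurements: duplicate record for {addr} "
                f"replicate {r.replicate} channel {r.channel}"
            )
        self.measurements = df.reset_index(drop=True)

    def validate_completeness(self) -> ValidationReport:
        """List (well, replicate, channel) combinations expected but absent.

        Every non-empty layout well is expected in both channels for every
        replicate; exclusion records do not remove the expectation of a raw
        measurement (exclusion is an analysis-time act).
        """
        ann = self.layout.annotations
        wells = ann.loc[ann["role"] != "empty", ["plate", "row", "column"]]
        reps = pd.DataFrame({"replicate": range(1, self.replicates + 1)})
        chans = pd.DataFrame({"channel": list(CHANNELS)})
        expected = wells.merge(reps, how="cross").merge(chans, how="cross")
        present = self.measurements[["plate", "row", "column", "replicate", "channel"]]
        merged = expected.merge(present.assign(_seen=1), how="left")
        missing = merged[merged["_seen"].isna()].drop(columns="_seen").reset_index(drop=True)
        # n_present counts expected combinations actually measured; extra
        # records (e.g. readings of empty wells) are not completeness
        return ValidationReport(len(expected), len(expected) - len(missing), missing)


EXCLUSION_COLUMNS = ["replicate", "plate", "row", "column", "reason", "note"]


def expand_exclusions(exclusions: pd.DataFrame | None, replicates: int) -> pd.DataFrame:
    """Resolve an exclusion table to concrete (replicate, well) records.

    The loaded screen log may carry ``ALL`` wildcards in the replicate column;
    this expands them against the replicate count of the dataset at hand.
    Returns columns replicate, plate, row, column, reason.
    """
    if exclusions is None or len(exclusions) == 0:
        return pd.DataFrame(columns=["replicate", "plate", "row", "column", "reason"])
    out = []
    for _, rec in exclusions.iterrows():
        reps = (
            range(1, replicates + 1)
            if str(rec["replicate"]).upper() == "ALL"
            else [int(rec["replicate"])]
        )
        for rep in reps:
            out.append((rep, int(rec["plate"]), rec["row"], int(rec["column"]), rec["reason"]))
    df = pd.DataFrame(out, columns=["replicate", "plate", "row", "column", "reason"])
    return df.drop_duplicates(subset=["replicate", "plate", "row", "column"]).reset_index(
        drop=True
    )
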