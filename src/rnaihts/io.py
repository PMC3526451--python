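"""Readers and writers for the tab-separated interchange formats.

All tables are UTF-8, tab-delimited, with a header row; gzip-compressed
variants are accepted transparently (pandas dispatches on the ``.gz``
suffix).  Writers emit records in canonical (plate, row, column) order so
that read -> write round-trips are byte-identical on canonical input.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .model import (
    EXCLUSION_COLUMNS,
    LAYOUT_COLUMNS,
    MEASUREMENT_COLUMNS,
    N_COLUMNS,
    REASON_VALUES,
    ROW_LETTERS,
    LibraryLayout,
    ScreenDataset,
    ScreenFormatError,
    ValidationReport,
    WellAddress,
)


def _read_tsv(path: str | Path, required: list[str], where: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ScreenFormatError(f"{where}: cannot read {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"{where}: {path} lacks columns {missing}")
    return df


def _to_int(df: pd.DataFrame, column: str, where: str) -> pd.Series:
    try:
        return df[column].astype(int)
    except ValueError:
        for lineno, v in enumerate(df[column], start=2):  # header is line 1
            try:
                int(v)
            except ValueError:
                raise ScreenFormatError(
                    f"{where}: malformed {column} {v!r} at line {lineno}"
                ) from None
        raise


def read_library_layout(path: str | Path, name: str | None = None) -> LibraryLayout:
    """Read a library layout table (plate, row, column, clone_id, gene_id, role)."""
    where = "library layout"
    df = _read_tsv(path, LAYOUT_COLUMNS, where)
    out = pd.DataFrame(
        {
            "plate": _to_int(df, "plate", where),
            "row": df["row"],
            "column": _to_int(df, "column", where),
            "clone_id": df["clone_id"],
            "gene_id": df["gene_id"],
            "role": df["role"],
        }
    )
    return LibraryLayout(name=name or Path(path).stem, annotations=out)


def write_library_layout(layout: LibraryLayout, path: str | Path) -> None:
    layout.annotations.to_csv(path, sep="\t", index=False)


def read_measurements(*paths: str | Path) -> pd.DataFrame:
    """Read one or more long-format measurement tables into a single frame.

    Columns: plate, row, column, replicate, channel, intensity.  Negative
    intensities and malformed coordinates raise; completeness against a
    layout is checked later by :func:`build_dataset`.
    """
    frames = []
    where = "measurements"
    for path in paths:
        df = _read_tsv(path, MEASUREMENT_COLUMNS, where)
        frames.append(
            pd.DataFrame(
                {
                    "plate": _to_int(df, "plate", where),
                    "row": df["row"],
                    "column": _to_int(df, "column", where),
                    "replicate": _to_int(df, "replicate", where),
                    "channel": df["channel"],
                    "intensity": pd.to_numeric(df["intensity"], errors="raise"),
                }
            )
        )
    return pd.concat(frames, ignore_index=True) if len(frames) > 1 else frames[0]


def write_measurements(measurements: pd.DataFrame, path: str | Path) -> None:
    measurements.sort_values(
        ["replicate", "plate", "row", "column", "channel"], kind="mergesort"
    ).to_csv(path, sep="\t", index=False)


def build_dataset(
    layout: LibraryLayout,
    measurements: pd.DataFrame,
    replicates: int | None = None,
) -> tuple[ScreenDataset, ValidationReport]:
    """Assemble and validate a ScreenDataset; returns it with its completeness report."""
    if replicates is None:
        replicates = int(measurements["replicate"].max())
    ds = ScreenDataset(layout=layout, measurements=measurements, replicates=replicates)
    return ds, ds.validate_completeness()


def read_screen_log(path: str | Path, layout: LibraryLayout | None = None) -> pd.DataFrame:
    """Read a screen log of excluded wells, expanding row/column wildcards.

    Columns: replicate, plate, row, column, reason, note.  ``replicate`` may
    be ``ALL``; ``row`` and ``column`` may be ``*`` (or ``ALL``) to exclude a
    whole plate or whole row/column, expanded over the full 16x24 grid.
    When a layout is given, plates and concrete addresses are validated
    against it.
    """
    df = _read_tsv(path, ["replicate", "plate", "row", "column", "reason"], "screen log")
    if "note" not in df.columns:
        df = df.assign(note="")
    records = []
    for lineno, rec in enumerate(df.itertuples(index=False), start=2):
        reason = rec.reason
        if reason not in REASON_VALUES:
            raise ScreenFormatError(
                f"screen log: unknown reason {reason!r} at line {lineno} "
                f"(allowed: {sorted(REASON_VALUES)})"
            )
        rep = str(rec.replicate).strip()
        if rep.upper() != "ALL":
            rep = int(rep)
        else:
            rep = "ALL"
        plate = int(rec.plate)
        row_field = str(rec.row).strip()
        col_field = str(rec.column).strip()
        rows = list(ROW_LETTERS) if row_field in ("*", "ALL") else [row_field]
        cols = (
            list(range(1, N_COLUMNS + 1))
            if col_field in ("*", "ALL")
            else [int(col_field)]
        )
        wildcard = row_field in ("*", "ALL") or col_field in ("*", "ALL")
        for row in rows:
            for col in cols:
                addr = WellAddress(plate, row, col)  # validates coordinates
                records.append(("ALL" if rep == "ALL" else rep, plate, row, col, reason, rec.note))
                if layout is not None and not wildcard:
                    ann = layout.annotations
                    hit = (
                        (ann["plate"] == plate) & (ann["row"] == row) & (ann["column"] == col)
                    )
                    if not hit.any():
                        raise ScreenFormatError(
                            f"screen log: address {addr} (line {lineno}) not in layout"
                        )
        if layout is not None and plate not in layout.plates:
            raise ScreenFormatError(f"screen log: plate {plate} (line {lineno}) not in layout")
    out = pd.DataFrame(records, columns=EXCLUSION_COLUMNS)
    return out.drop_duplicates(subset=["replicate", "plate", "row", "column"]).reset_index(
        drop=True
    )


def write_screen_log(exclusions: pd.DataFrame, path: str | Path) -> None:
    exclusions.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table (Z-scores, hit calls, QC stats) as TSV."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
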