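"""Circular off-target effect (OTE) analysis.

A hit clone is *circular* when one of its predicted off-target genes is
itself a hit gene of the screen -- a configuration in which the apparent
on-target interaction may in fact be driven by the off-target.  The module
counts circular clones in an observed hit list and builds a random-sampling
null: repeatedly draw ``sample_size`` clones from the whole library and
count how many have a predicted off-target inside the on-target gene set of
the same draw.  Matching is in gene-ID space, so an off-target reached via
a different clone of the same gene still counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass
class OteGraph:
    """Clone -> (on-target gene, set of predicted off-target genes).

    Off-target sets never contain the clone's own on-target gene (self
    edges are dropped at construction); clones without predictions map to
    the empty set.
    """

    on_target: dict[str, str]
    off_targets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.off_targets = {
            c: frozenset(g for g in self.off_targets.get(c, ()) if g != self.on_target[c])
            for c in self.on_target
        }

    @property
    def clones(self) -> list[str]:
        return sorted(self.on_target)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.off_targets.values())

    @classmethod
    def from_edges(cls, edges: pd.DataFrame) -> "OteGraph":
        """Build from an edge table: clone_id, on_target_gene, off_target_gene.

        One edge per row; clones with no predictions appear once with an
        empty off_target_gene field.
        """
        on: dict[str, str] = {}
        off: dict[str, set[str]] = {}
        for rec in edges.itertuples(index=False):
            clone = str(rec.clone_id)
            gene = str(rec.on_target_gene)
            prev = on.setdefault(clone, gene)
            if prev != gene:
                raise ValueError(f"clone {clone}: conflicting on-target genes {prev}/{gene}")
            off.setdefault(clone, set())
            target = str(getattr(rec, "off_target_gene", "") or "")
            if target and target != "nan":
                off[clone].add(target)
        return cls(on_target=on, off_targets={c: frozenset(s) for c, s in off.items()})

    @classmethod
    def read(cls, path: str | Path) -> "OteGraph":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return cls.from_edges(df)

    def write(self, path: str | Path) -> None:
        rows = []
        for clone in self.clones:
            offs = sorted(self.off_targets[clone])
            if offs:
                rows.extend((clone, self.on_target[clone], g) for g in offs)
            else:
                rows.append((clone, self.on_target[clone], ""))
        pd.DataFrame(rows, columns=["clone_id", "on_target_gene", "off_target_gene"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class CircularityResult:
    """Observed circular-OTE rate with its permutation null distribution."""

    observed_count: int | None
    total_clones: int | None
    observed_rate: float | None
    null_rates: list[float]
    null_mean: float
    empirical_p: float | None
    sample_size: int
    iterations: int
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "observed_count": self.observed_count,
            "total_clones": self.total_clones,
            "observed_rate": self.observed_rate,
            "null_rates": self.null_rates,
            "null_mean": self.null_mean,
            "empirical_p": self.empirical_p,
            "sample_size": self.sample_size,
            "iterations": self.iterations,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def observed_circularity(
    hit_clones: Iterable[str],
    hit_genes: Iterable[str],
    graph: OteGraph,
) -> tuple[int, float]:
    """Count hit clones with >= 1 predicted off-target inside the hit-gene set.

    Every hit clone must be present in the graph (an empty prediction set is
    fine); absent clones raise with the offending IDs listed.
    """
    clones = list(hit_clones)
    genes = set(hit_genes)
    missing = sorted(c for c in clones if c not in graph.on_target)
    if missing:
        raise KeyError(f"clones missing from OTE graph: {missing}")
    count = sum(1 for c in clones if graph.off_targets[c] & genes)
    return count, count / len(clones) if clones else 0.0


def permutation_null(
    library_clones: Iterable[str],
    graph: OteGraph,
    sample_size: int = 100,
    iterations: int = 1000,
    seed: int = 0,
) -> CircularityResult:
    """Null distribution of the circular-OTE rate under random clone draws.

    Each iteration samples ``sample_size`` clones uniformly without
    replacement and counts clones whose predicted off-targets intersect the
    on-target gene set of that same sample.  Deterministic given ``seed``.
    """
    clones = np.asarray(sorted(library_clones), dtype=object)
    if sample_size > clones.size:
        raise ValueError(
            f"sample_size {sample_size} exceeds library size {clones.size}"
        )
    missing = sorted(c for c in clones if c not in graph.on_target)
    if missing:
        raise KeyError(f"clones missing from OTE graph: {missing[:10]}")
    on = graph.on_target
    off = graph.off_targets
    rng = np.random.default_rng(seed)
    rates: list[float] = []
    for _ in range(iterations):
        draw = rng.choice(clones, size=sample_size, replace=False)
        sample_genes = {on[c] for c in draw}
        count = sum(1 for c in draw if off[c] & sample_genes)
        rates.append(count / sample_size)
    return CircularityResult(
        observed_count=None,
        total_clones=None,
        observed_rate=None,
        null_rates=rates,
        null_mean=float(np.mean(rates)),
        empirical_p=None,
        sample_size=sample_size,
        iterations=iterations,
        seed=seed,
    )


def empirical_p(observed_rate: float, null_rates: Iterable[float]) -> float:
    """Add-one upper-tail empirical p: ``(1 + #{null >= observed}) / (n + 1)``."""
    rates = list(null_rates)
    if not rates:
        raise ValueError("null_rates must be non-empty")
    ge = sum(1 for r in rates if r >= observed_rate)
    return (1 + ge) / (len(rates) + 1)


def circularity_analysis(
    hit_clones: Iterable[str],
    hit_genes: Iterable[str],
    library_clones: Iterable[str],
    graph: OteGraph,
    sample_size: int = 100,
    iterations: int = 1000,
    seed: int = 0,
) -> CircularityResult:
    """Observed circularity of a hit list plus its library-wide permutation null."""
    clones = list(hit_clones)
    count, rate = observed_circularity(clones, hit_genes, graph)
    null = permutation_null(library_clones, graph, sample_size, iterations, seed)
    return CircularityResult(
        observed_count=count,
        total_clones=len(clones),
        observed_rate=rate,
        null_rates=null.null_rates,
        null_mean=null.null_mean,
        empirical_p=empirical_p(rate, null.null_rates),
        sample_size=sample_size,
        iterations=iterations,
        seed=seed,
    )
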