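"""Genome abundance estimation from read-compatibility tables.

Reads mapped against a reference-genome collection are often compatible
with several genomes (shared or conserved sequence).  Abundances are
therefore estimated with a mixture model: each read is drawn from an
unknown genome with probability proportional to that genome's mixture
weight, and an EM algorithm performs soft assignment of ambiguous reads.
Post-processing applies a minimum-mapped-reads QC gate, a noise floor on
the estimated proportions, and strain-to-species aggregation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReadCompatibilityTable",
    "AbundanceEstimate",
    "em_estimate",
    "qc_min_mapped",
    "apply_noise_floor",
    "aggregate_strains",
]

#: Samples with fewer mapped reads than this display diminished profiling
#: accuracy and are dropped.
MIN_MAPPED_READS = 250_000

#: Relative abundances strictly below this are treated as statistical noise.
NOISE_FLOOR = 1e-5


@dataclass
class ReadCompatibilityTable:
    """Per-read candidate-genome lists for one sample, stored compactly.

    Reads sharing the same compatibility pattern (set of candidate
    genomes) are interchangeable for the mixture likelihood, so the
    table stores unique patterns with multiplicities rather than one row
    per read.

    Attributes
    ----------
    sample_id: identifier of the sample the reads belong to.
    genomes: the declared genome universe (sorted tuple).
    patterns: list of tuples of genome ids, each a compatibility set.
    counts: number of reads carrying each pattern.
    """

    sample_id: str
    genomes: tuple[str, ...]
    patterns: list[tuple[str, ...]]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.patterns) != len(self.counts):
            raise ValueError("patterns and counts must align")
        universe = set(self.genomes)
        for pat in self.patterns:
            if len(pat) == 0:
                raise ValueError("every read must list at least one genome")
            if not set(pat) <= universe:
                raise ValueError(f"pattern {pat} outside declared genome universe")

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_reads(
        cls,
        sample_id: str,
        reads: dict[str, list[str]] | list[list[str]],
        genomes: list[str] | None = None,
    ) -> "ReadCompatibilityTable":
        """Build from an explicit read -> candidate-genomes mapping."""
        if isinstance(reads, dict):
            candidate_lists = list(reads.values())
        else:
            candidate_lists = list(reads)
        counter: Counter[tuple[str, ...]] = Counter(
            tuple(sorted(set(c))) for c in candidate_lists
        )
        if genomes is None:
            genomes = sorted({g for pat in counter for g in pat})
        patterns = sorted(counter)
        counts = np.array([counter[p] for p in patterns], dtype=np.int64)
        return cls(sample_id, tuple(sorted(genomes)), patterns, counts)

    @classmethod
    def read_tsv(cls, path: str | Path, sample_id: str | None = None) -> "ReadCompatibilityTable":
        """Read a two-column TSV: read_id <TAB> comma-separated genome ids."""
        path = Path(path)
        df = pd.read_csv(path, sep="\t", header=None, names=["read_id", "genomes"], dtype=str)
        reads = {r.read_id: r.genomes.split(",") for r in df.itertuples()}
        return cls.from_reads(sample_id or path.stem, reads)

    def to_tsv(self, path: str | Path) -> None:
        """Write one row per read (read ids synthesised from patterns)."""
        with open(path, "w") as fh:
            idx = 0
            for pat, cnt in zip(self.patterns, self.counts):
                joined = ",".join(pat)
                for _ in range(int(cnt)):
                    fh.write(f"read_{idx:08d}\t{joined}\n")
                    idx += 1


@dataclass
class AbundanceEstimate:
    """Mixture proportions for one sample plus the EM convergence trace."""

    sample_id: str
    proportions: pd.Series
    n_mapped_reads: int
    log_likelihood_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy()
        if (p < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("proportions must sum to 1")


def em_estimate(
    table: ReadCompatibilityTable,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> AbundanceEstimate:
    """Maximum-likelihood mixture proportions via EM soft read assignment.

    The likelihood of proportions pi is prod_reads sum_{g in pattern}
    pi_g (flat compatibility weights).  The E-step computes per-read
    responsibilities proportional to pi_g; the M-step averages them.
    Initialisation is uniform — the log-likelihood is concave in pi, so
    the start only matters along flat (unidentified) directions.
    Iteration stops when ``max |delta pi| < tol`` or after ``max_iter``
    rounds.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if table.n_reads == 0:
        raise ValueError("empty read-compatibility table")

    genomes = list(table.genomes)
    G = len(genomes)
    gidx = {g: i for i, g in enumerate(genomes)}
    # pattern membership as a sparse indicator: P x G
    P = len(table.patterns)
    member = np.zeros((P, G), dtype=float)
    for p, pat in enumerate(table.patterns):
        for g in pat:
            member[p, gidx[g]] = 1.0
    counts = table.counts.astype(float)
    n = counts.sum()

    pi = np.full(G, 1.0 / G)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pattern_mass = member @ pi  # P
        trace.append(float((counts * np.log(pattern_mass)).sum()))
        # responsibilities summed over reads of each pattern
        resp = member * pi[None, :] / pattern_mass[:, None]
        pi_new = (counts[:, None] * resp).sum(axis=0) / n
        delta = np.abs(pi_new - pi).max()
        pi = pi_new
        if delta < tol:
            converged = True
            break
    trace.append(float((counts * np.log(member @ pi)).sum()))

    proportions = pd.Series(pi, index=genomes, name=table.sample_id)
    return AbundanceEstimate(
        sample_id=table.sample_id,
        proportions=proportions,
        n_mapped_reads=table.n_reads,
        log_likelihood_trace=trace,
        n_iterations=it,
        converged=converged,
    )


def qc_min_mapped(estimate: AbundanceEstimate, min_reads: int = MIN_MAPPED_READS) -> bool:
    """True (keep) iff the sample has at least ``min_reads`` mapped reads."""
    return estimate.n_mapped_reads >= min_reads


def apply_noise_floor(proportions: pd.Series, floor: float = NOISE_FLOOR) -> pd.Series:
    """Zero entries strictly below ``floor`` and re-close to sum 1.

    Values exactly at the floor are kept (the rule is strictly "below").
    """
    p = proportions.astype(float).copy()
    p[p < floor] = 0.0
    total = p.sum()
    if total <= 0:
        raise ValueError("all proportions fell below the noise floor")
    return p / total


def aggregate_strains(
    proportions: pd.Series, strain_to_species: dict[str, str]
) -> pd.Series:
    """Sum strain-level proportions into species-level proportions."""
    missing = [g for g in proportions.index if g not in strain_to_species]
    if missing:
        raise KeyError(f"strains without species assignment: {missing}")
    grouped = proportions.groupby(
        proportions.index.map(strain_to_species)
    ).sum()
    grouped.name = proportions.name
    return grouped.sort_index()
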