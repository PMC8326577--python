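"""Compositional data structures and diversity statistics.

The central object is the sample-taxa matrix: ``n`` samples by ``D``
species, each row a relative-abundance vector summing to one, annotated
with subject ids and diagnosis-group labels.  Because shotgun sequencing
only informs about relative (not absolute) abundances, downstream
statistics operate on the centered log-ratio (CLR) transform

    clr(x)_j = ln(x_j / G(x)),   G(x) = (prod_j x_j)^(1/D)

which maps a composition to a zero-sum vector in real space and removes
the spurious negative correlation induced by the unit-sum constraint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

__all__ = [
    "SampleTaxaMatrix",
    "ClrMatrix",
    "clr_transform",
    "clr_transform_values",
    "prevalence_filter",
    "cap_replicates",
    "shannon_entropy",
    "bray_curtis",
    "dissimilarity_profiles",
]

#: Pseudo-abundance substituted for zeros before taking logs: half the
#: noise floor used when profiling abundances, so imputed values always
#: sit below anything treated as real signal.
DEFAULT_ZERO_REPLACEMENT = 5e-6

_ROW_SUM_TOL = 1e-9


@dataclass
class SampleTaxaMatrix:
    """Relative-abundance matrix with sample annotations.

    Parameters
    ----------
    abundance:
        ``n x D`` DataFrame; index = sample ids, columns = species ids,
        every row sums to 1 (after closure) and all entries are >= 0.
    metadata:
        DataFrame indexed by sample id with at least ``subject_id`` and
        ``group`` columns; ``age`` and ``sex`` are carried when present.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.metadata.index):
            self.metadata = self.metadata.loc[self.abundance.index]
        self.validate()

    def validate(self) -> None:
        values = self.abundance.to_numpy()
        if (values < 0).any():
            raise ValueError("relative abundances must be non-negative")
        row_sums = values.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-6):
            raise ValueError("every abundance row must sum to 1")
        for col in ("subject_id", "group"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata must carry a '{col}' column")
        # each subject belongs to exactly one group
        per_subject = self.metadata.groupby("subject_id")["group"].nunique()
        if (per_subject > 1).any():
            bad = per_subject[per_subject > 1].index.tolist()
            raise ValueError(f"subjects mapped to multiple groups: {bad}")

    @property
    def samples(self) -> pd.Index:
        return self.abundance.index

    @property
    def species(self) -> pd.Index:
        return self.abundance.columns

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]

    @property
    def subjects(self) -> pd.Series:
        return self.metadata["subject_id"]

    def select_species(self, species: list[str]) -> "SampleTaxaMatrix":
        """Restrict to ``species`` and re-close each row to sum 1."""
        sub = self.abundance[list(species)]
        totals = sub.sum(axis=1)
        if (totals <= 0).any():
            raise ValueError("a sample has zero total abundance over the selection")
        return SampleTaxaMatrix(sub.div(totals, axis=0), self.metadata.copy())

    def select_samples(self, samples: list[str]) -> "SampleTaxaMatrix":
        return SampleTaxaMatrix(
            self.abundance.loc[list(samples)], self.metadata.loc[list(samples)]
        )


@dataclass
class ClrMatrix:
    """CLR-transformed counterpart of a :class:`SampleTaxaMatrix`.

    Rows sum to zero.  ``zero_policy`` records how zeros were imputed so
    the provenance of every downstream statistic is recoverable.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame
    zero_policy: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        row_sums = self.values.to_numpy().sum(axis=1)
        if not np.allclose(row_sums, 0.0, atol=1e-6):
            raise ValueError("CLR rows must sum to zero")

    @property
    def samples(self) -> pd.Index:
        return self.values.index

    @property
    def species(self) -> pd.Index:
        return self.values.columns

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]


def _multiplicative_replace(values: np.ndarray, delta: float) -> np.ndarray:
    """Impute zeros with ``delta`` and shrink nonzero entries to keep row sums.

    Standard multiplicative zero replacement for compositions: each zero
    becomes ``delta`` and the nonzero part of the row is scaled by
    ``1 - k*delta`` (k zeros in the row), preserving the ratios among
    observed taxa and the unit sum.
    """
    out = values.astype(float).copy()
    zero_mask = out == 0
    k = zero_mask.sum(axis=1, keepdims=True)
    if not zero_mask.any():
        return out
    scale = 1.0 - k * delta
    if (scale <= 0).any():
        raise ValueError("zero replacement delta too large for this row")
    out = out * scale
    out[zero_mask] = delta
    return out


def clr_transform_values(
    values: np.ndarray, zero_replacement: float = DEFAULT_ZERO_REPLACEMENT
) -> np.ndarray:
    """CLR-transform rows of a closed composition array (plain ndarray core)."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
        squeeze = True
    else:
        squeeze = False
    if (values.sum(axis=1) <= 0).any():
        raise ValueError("cannot CLR-transform an all-zero row")
    replaced = _multiplicative_replace(values, zero_replacement)
    logs = np.log(replaced)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return clr[0] if squeeze else clr


def clr_transform(
    matrix: SampleTaxaMatrix, zero_replacement: float = DEFAULT_ZERO_REPLACEMENT
) -> ClrMatrix:
    """CLR-transform a sample-taxa matrix.

    Zeros are imputed multiplicatively with ``zero_replacement`` (default
    half the profiling noise floor of 1e-5) before taking natural logs;
    the policy is recorded on the result.
    """
    clr = clr_transform_values(matrix.abundance.to_numpy(), zero_replacement)
    values = pd.DataFrame(clr, index=matrix.samples, columns=matrix.species)
    policy = {"method": "multiplicative", "zero_replacement": zero_replacement}
    return ClrMatrix(values, matrix.metadata.copy(), policy)


def prevalence_filter(
    matrix: SampleTaxaMatrix, threshold: float = 0.90
) -> list[str]:
    """Species present in at least ``threshold`` of samples of *some* group.

    Presence means nonzero post-noise-floor abundance.  The retained set
    is the union over diagnosis groups of the per-group >= 90% prevalent
    species, which keeps taxa that are core to any one group.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    retained: set[str] = set()
    for group, block in matrix.abundance.groupby(matrix.groups):
        n = len(block)
        if n == 0:
            raise ValueError(f"group {group!r} has no samples")
        prevalence = (block.to_numpy() > 0).sum(axis=0)
        keep = prevalence >= threshold * n - 1e-9
        retained.update(matrix.species[keep])
    return [s for s in matrix.species if s in retained]


def cap_replicates(
    matrix: SampleTaxaMatrix, max_per_subject: int = 5, seed: int | None = 0
) -> SampleTaxaMatrix:
    """Retain at most ``max_per_subject`` randomly chosen samples per subject."""
    if max_per_subject < 1:
        raise ValueError("max_per_subject must be >= 1")
    rng = np.random.default_rng(seed)
    keep: list[str] = []
    for _, block in matrix.metadata.groupby("subject_id", sort=True):
        ids = list(block.index)
        if len(ids) > max_per_subject:
            ids = list(rng.choice(ids, size=max_per_subject, replace=False))
        keep.extend(ids)
    keep = [s for s in matrix.samples if s in set(keep)]
    return matrix.select_samples(keep)


def shannon_entropy(row: np.ndarray | pd.Series) -> float:
    """Shannon entropy H = -sum p_i log2 p_i in bits, over nonzero entries.

    Computed on raw (untransformed) relative abundances.
    """
    p = np.asarray(row, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def bray_curtis(v1: np.ndarray, v2: np.ndarray) -> float:
    """Bray-Curtis dissimilarity BCD = 1 - 2*C_ij/(S_i + S_j).

    ``C_ij`` sums, per species, the lower of the two relative abundances;
    0 for identical vectors, 1 for disjoint supports.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal length")
    if (v1 < 0).any() or (v2 < 0).any():
        raise ValueError("abundances must be non-negative")
    s = v1.sum() + v2.sum()
    if s == 0:
        raise ValueError("both vectors are entirely zero")
    return float(1.0 - 2.0 * np.minimum(v1, v2).sum() / s)


def dissimilarity_profiles(matrix: SampleTaxaMatrix) -> dict:
    """Intrapersonal and interpersonal Bray-Curtis distributions per group.

    Intrapersonal pairs are replicate samples of the same subject;
    interpersonal pairs are samples from different subjects within the
    same diagnosis group.  Groups are compared pairwise with two-sided
    Mann-Whitney U tests on each distribution type.

    Returns a dict with ``intrapersonal`` and ``interpersonal`` mappings
    (group -> array of BCD values) and ``comparisons`` (list of dicts
    with the pairwise test results).
    """
    dist = squareform(pdist(matrix.abundance.to_numpy(), metric="braycurtis"))
    subjects = matrix.subjects.to_numpy()
    groups = matrix.groups.to_numpy()
    n = len(matrix.samples)

    intra: dict[str, list[float]] = {}
    inter: dict[str, list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if subjects[i] == subjects[j]:
                intra.setdefault(groups[i], []).append(dist[i, j])
            elif groups[i] == groups[j]:
                inter.setdefault(groups[i], []).append(dist[i, j])

    intra_arr = {g: np.asarray(v) for g, v in intra.items()}
    inter_arr = {g: np.asarray(v) for g, v in inter.items()}

    comparisons = []
    for kind, table in (("intrapersonal", intra_arr), ("interpersonal", inter_arr)):
        for a, b in itertools.combinations(sorted(table), 2):
            if len(table[a]) < 1 or len(table[b]) < 1:
                continue
            stat = mannwhitneyu(table[a], table[b], alternative="two-sided")
            comparisons.append(
                {
                    "type": kind,
                    "group_a": a,
                    "group_b": b,
                    "U": float(stat.statistic),
                    "p": float(stat.pvalue),
                }
            )
    return {
        "intrapersonal": intra_arr,
        "interpersonal": inter_arr,
        "comparisons": comparisons,
    }
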