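"""Synthetic cohort generation with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes about gut-metagenome cohorts:

* latent log absolute abundances are multivariate Gaussian with a known
  sparse precision matrix (the ground-truth association network);
* group effects are planted on designated species as shifts of the
  latent mean (in log2 units, so an effect of 1 is a twofold change);
* subjects contribute 1-5 replicate samples sharing a Gaussian random
  intercept, which makes within-subject pairs more similar than
  between-subject pairs;
* observed data are closed to relative abundances, noise-floored, and
  re-closed — the same order the profiling pipeline applies;
* read-compatibility tables and per-genome protein-family counts are
  generated with recorded truth for the estimation stages.

Every draw is deterministic under the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .composition import SampleTaxaMatrix
from .em import NOISE_FLOOR, ReadCompatibilityTable
from .functional import FamilyCountTable

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "SyntheticTruth",
    "sample_precision_matrix",
    "generate_cohort",
    "generate_read_compatibility",
    "generate_family_counts",
    "species_ids",
]

LN2 = float(np.log(2.0))


def species_ids(D: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(D)]


@dataclass
class GroupSpec:
    """One diagnosis group: its label, size, and replicate structure.

    ``replicate_weights`` gives the probability of a subject contributing
    1..5 replicate samples (the pipeline caps replicates at five).
    """

    label: str
    n_subjects: int
    replicate_weights: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0)
    age_range: tuple[float, float] = (18.0, 70.0)
    female_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("each group needs at least one subject")
        w = np.asarray(self.replicate_weights, dtype=float)
        if len(w) != 5 or (w < 0).any() or w.sum() <= 0:
            raise ValueError("replicate_weights must be 5 non-negative weights")
        self.replicate_weights = tuple(w / w.sum())


@dataclass
class CohortSpec:
    """Full recipe for a synthetic cohort."""

    groups: list[GroupSpec]
    D: int = 50
    sparsity: float = 0.1
    #: planted effects: (species id, group label, log2 effect size)
    da_spec: list[tuple[str, str, float]] = field(default_factory=list)
    noise_floor: float = NOISE_FLOOR
    #: s.d. of the per-species baseline log-mean across species
    base_mean_sd: float = 1.0
    #: s.d. of the shared per-subject random intercept (log scale)
    subject_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D < 5:
            raise ValueError("D must be at least 5")
        if not 0 < self.sparsity < 1:
            raise ValueError("sparsity must lie in (0, 1)")
        ids = set(species_ids(self.D))
        labels = {g.label for g in self.groups}
        for sp, grp, _ in self.da_spec:
            if sp not in ids:
                raise ValueError(f"da_spec names unknown species {sp!r}")
            if grp not in labels:
                raise ValueError(f"da_spec names unknown group {grp!r}")


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generator, used as the test oracle."""

    precision_support: np.ndarray
    edge_signs: np.ndarray
    da_species: list[tuple[str, float, str]]  # (species, log2 fc, direction)
    group_means: dict[str, np.ndarray]
    genome_proportions: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0
    #: drawn sparse precision matrix itself (inverse of the latent covariance)
    precision: np.ndarray | None = field(default=None, repr=False)
    #: latent log absolute abundances before closure (n x D); kept in
    #: memory for covariance checks, not serialized
    latent: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.precision_support)
        if not np.array_equal(s, s.T) or np.diag(s).any():
            raise ValueError("precision support must be symmetric with zero diagonal")
        for sp, lfc, _ in self.da_species:
            if abs(lfc) < 1.0:
                raise ValueError(
                    f"planted effect for {sp!r} is below the twofold detection threshold"
                )

    @property
    def true_edges(self) -> set[frozenset]:
        idx = np.argwhere(np.triu(self.precision_support, k=1))
        return {frozenset((int(i), int(j))) for i, j in idx}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "precision_support": self.precision_support.astype(int).tolist(),
            "edge_signs": self.edge_signs.astype(int).tolist(),
            "da_species": [list(t) for t in self.da_species],
            "group_means": {g: m.tolist() for g, m in self.group_means.items()},
            "genome_proportions": {
                k: v.tolist() for k, v in self.genome_proportions.items()
            },
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            precision_support=np.asarray(d["precision_support"]),
            edge_signs=np.asarray(d["edge_signs"]),
            da_species=[tuple(t) for t in d["da_species"]],
            group_means={g: np.asarray(m) for g, m in d["group_means"].items()},
            genome_proportions={
                k: np.asarray(v) for k, v in d["genome_proportions"].items()
            },
            seed=int(d["seed"]),
        )


def sample_precision_matrix(
    D: int,
    sparsity: float,
    seed: int | None = 0,
    support: set[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a sparse symmetric positive-definite precision matrix.

    Off-diagonal support is Bernoulli(``sparsity``) on the upper triangle
    (or forced to ``support`` when given); nonzero entries are uniform in
    magnitude on [0.1, 0.4] with random sign.  The diagonal starts at 1
    and is inflated until the minimum eigenvalue is at least 0.05, which
    guarantees invertibility without disturbing the support.

    Returns ``(omega, support_matrix, sign_matrix)``.
    """
    if D < 2:
        raise ValueError("D must be at least 2")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    sup = np.zeros((D, D), dtype=bool)
    iu = np.triu_indices(D, k=1)
    if support is not None:
        for i, j in support:
            sup[min(i, j), max(i, j)] = True
    else:
        sup[iu] = rng.random(len(iu[0])) < sparsity
    sup = sup | sup.T

    omega = np.zeros((D, D))
    magnitudes = rng.uniform(0.1, 0.4, size=(D, D))
    signs = rng.choice([-1.0, 1.0], size=(D, D))
    upper = np.triu(np.ones((D, D)), k=1).astype(bool) & sup
    omega[upper] = (magnitudes * signs)[upper]
    omega = omega + omega.T
    np.fill_diagonal(omega, 1.0)

    for _ in range(100):
        min_eig = float(np.linalg.eigvalsh(omega).min())
        if min_eig >= 0.05:
            break
        omega += (0.05 - min_eig + 0.01) * np.eye(D)
    else:  # pragma: no cover - diagonal boosting always terminates
        raise RuntimeError("failed to reach positive definiteness")

    sign_matrix = np.sign(omega) * sup
    return omega, sup.astype(int), sign_matrix.astype(int)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[SampleTaxaMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate a cohort of relative-abundance profiles with ground truth.

    Latent log abundances for a sample are ``mu_group + b_subject + eps``
    with ``eps ~ N(0, Omega^-1)`` for the drawn sparse precision matrix
    ``Omega`` and ``b_subject`` a shared random intercept.  Rows are
    exponentiated, closed to sum 1, noise-floored, and re-closed.
    """
    ss = np.random.SeedSequence(spec.seed)
    seeds = ss.spawn(4)
    rng_struct = np.random.default_rng(seeds[0])
    rng_sample = np.random.default_rng(seeds[1])
    rng_meta = np.random.default_rng(seeds[2])

    D = spec.D
    sp_ids = species_ids(D)
    omega, support, signs = sample_precision_matrix(
        D, spec.sparsity, seed=seeds[3]
    )
    sigma = np.linalg.inv(omega)
    chol = np.linalg.cholesky(sigma)

    base_mean = rng_struct.normal(0.0, spec.base_mean_sd, size=D)
    group_means: dict[str, np.ndarray] = {}
    for g in spec.groups:
        mu = base_mean.copy()
        for sp, grp, lfc in spec.da_spec:
            if grp == g.label:
                mu[sp_ids.index(sp)] += lfc * LN2
        group_means[g.label] = mu

    rows, sample_ids, meta_rows = [], [], []
    for g in spec.groups:
        mu = group_means[g.label]
        for s in range(g.n_subjects):
            subject = f"{g.label}_subj{s:03d}"
            n_rep = int(
                rng_sample.choice(np.arange(1, 6), p=np.asarray(g.replicate_weights))
            )
            intercept = rng_sample.normal(0.0, spec.subject_sd, size=D)
            age = float(rng_meta.uniform(*g.age_range))
            sex = "F" if rng_meta.random() < g.female_fraction else "M"
            for r in range(n_rep):
                eps = chol @ rng_sample.standard_normal(D)
                rows.append(mu + intercept + eps)
                sid = f"{subject}_rep{r}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "subject_id": subject, "group": g.label,
                     "age": age, "sex": sex}
                )

    latent = np.vstack(rows)
    rel = np.exp(latent)
    rel /= rel.sum(axis=1, keepdims=True)
    rel[rel < spec.noise_floor] = 0.0
    rel /= rel.sum(axis=1, keepdims=True)

    abundance = pd.DataFrame(rel, index=pd.Index(sample_ids, name="sample_id"),
                             columns=sp_ids)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    # truth records each planted species once, with its direction
    da_truth: list[tuple[str, float, str]] = []
    seen: set[str] = set()
    for sp, grp, lfc in spec.da_spec:
        if sp in seen:
            continue
        seen.add(sp)
        direction = "elevated" if lfc > 0 else "depleted"
        da_truth.append((sp, float(lfc), direction))

    truth = SyntheticTruth(
        precision_support=support,
        edge_signs=signs,
        da_species=da_truth,
        group_means=group_means,
        seed=spec.seed,
        precision=omega,
        latent=latent,
    )
    return SampleTaxaMatrix(abundance, metadata), metadata, truth


def generate_read_compatibility(
    proportions: pd.Series | np.ndarray,
    n_reads: int,
    ambiguity: float = 0.0,
    seed: int | None = 0,
    sample_id: str = "synthetic",
) -> tuple[ReadCompatibilityTable, pd.Series]:
    """Simulate a read-compatibility table from true genome proportions.

    Each read's true source genome is multinomial in ``proportions``;
    with probability ``ambiguity`` the read additionally lists one other
    genome (a conserved-region multi-mapper).  Returns the table and the
    truth proportions.
    """
    if isinstance(proportions, pd.Series):
        genomes = list(proportions.index.astype(str))
        p = proportions.to_numpy(dtype=float)
    else:
        p = np.asarray(proportions, dtype=float)
        genomes = [f"g{i}" for i in range(len(p))]
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= ambiguity <= 1:
        raise ValueError("ambiguity must lie in [0, 1]")
    G = len(genomes)
    rng = np.random.default_rng(seed)

    source = rng.choice(G, size=n_reads, p=p)
    ambiguous = rng.random(n_reads) < ambiguity
    # partner genome for ambiguous reads, uniform over the other genomes
    partner = rng.integers(0, G - 1, size=n_reads) if G > 1 else source.copy()
    if G > 1:
        partner[partner >= source] += 1
    partner[~ambiguous] = source[~ambiguous]

    pairs = np.stack([np.minimum(source, partner), np.maximum(source, partner)], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    patterns = []
    for a, b in uniq:
        patterns.append((genomes[a],) if a == b else tuple(sorted((genomes[a], genomes[b]))))
    table = ReadCompatibilityTable(
        sample_id=sample_id,
        genomes=tuple(sorted(genomes)),
        patterns=patterns,
        counts=counts,
    )
    return table, pd.Series(p, index=genomes, name="true_proportion")


def generate_family_counts(
    species: list[str] | int,
    n_families: int = 100,
    role_map_size: int = 10,
    planted_roles: list[tuple[str, str, int]] | None = None,
    seed: int | None = 0,
    base_rate: float = 3.0,
    family_presence: float = 0.7,
) -> FamilyCountTable:
    """Per-genome protein-family counts with a family-to-role map.

    Baseline counts are Poisson draws gated by a per-(species, family)
    presence coin, so genomes differ in which families they carry.
    ``planted_roles`` entries ``(species, family, count)`` overwrite the
    baseline with an elevated copy number, creating role-level shifts
    whenever the carrying species is abundant.
    """
    if isinstance(species, int):
        species = species_ids(species)
    if n_families < role_map_size or role_map_size < 1:
        raise ValueError("need n_families >= role_map_size >= 1")
    rng = np.random.default_rng(seed)
    families = [f"FAM{i:04d}" for i in range(n_families)]
    roles = pd.Series(
        [f"role{(i % role_map_size):02d}" for i in range(n_families)],
        index=families,
        name="role",
    )
    present = rng.random((len(species), n_families)) < family_presence
    counts = rng.poisson(base_rate, size=(len(species), n_families)) + 1
    counts = counts * present
    table = pd.DataFrame(counts, index=species, columns=families, dtype=int)

    for sp, fam, cnt in planted_roles or []:
        if fam not in table.columns:
            raise ValueError(f"planted role references unknown family {fam!r}")
        if sp not in table.index:
            raise ValueError(f"planted role references unknown species {sp!r}")
        table.loc[sp, fam] = int(cnt)

    return FamilyCountTable(counts=table, roles=roles)
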