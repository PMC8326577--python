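"""Functional-capacity profiles from per-genome protein-family counts.

Each reference genome carries a vector of protein-family counts (e.g.
TIGRFAM hits), and each family belongs to one functional role.  A
sample's functional profile is the abundance-weighted mixture of the
family counts of its prevalent species, closed to relative abundance and
CLR-transformed across families.  Family-level differential testing
reuses the consensus machinery; consensus families are then aggregated
by role.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .composition import DEFAULT_ZERO_REPLACEMENT, SampleTaxaMatrix, clr_transform_values
from . import da as _da

__all__ = [
    "FamilyCountTable",
    "FunctionalProfile",
    "weight_family_profile",
    "family_da",
    "aggregate_roles",
]


@dataclass
class FamilyCountTable:
    """Species-by-family nonnegative integer counts plus a role map."""

    counts: pd.DataFrame  # species x family
    roles: pd.Series  # family -> role label

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("family counts must be non-negative")
        missing = [f for f in self.counts.columns if f not in self.roles.index]
        if missing:
            raise ValueError(f"families without a role: {missing}")

    @property
    def species(self) -> pd.Index:
        return self.counts.index

    @property
    def families(self) -> pd.Index:
        return self.counts.columns

    def write_tsv(self, counts_path, roles_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="species")
        self.roles.rename_axis("family").to_csv(roles_path, sep="\t")

    @classmethod
    def read_tsv(cls, counts_path, roles_path) -> "FamilyCountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="species")
        roles = pd.read_csv(roles_path, sep="\t", index_col="family")["role"]
        return cls(counts=counts, roles=roles)


@dataclass
class FunctionalProfile:
    """Per-sample family relative abundances and their CLR transform."""

    relative: pd.DataFrame  # sample x family, rows sum to 1
    clr: pd.DataFrame  # sample x family, rows sum to 0
    groups: pd.Series
    roles: pd.Series
    weighting: str = "relative"
    zero_policy: dict = field(default_factory=dict)

    def role_sums(self) -> pd.DataFrame:
        """Per-sample role-level abundance: sum of member-family abundances."""
        return self.relative.T.groupby(self.roles).sum().T


def weight_family_profile(
    matrix: SampleTaxaMatrix,
    counts: FamilyCountTable,
    prevalent_species: list[str],
    weighting: str = "relative",
    zero_replacement: float = DEFAULT_ZERO_REPLACEMENT,
) -> FunctionalProfile:
    """Build sample-level functional profiles from prevalent species.

    For every sample, the abundance of family f is the species-abundance
    weighted sum of per-genome counts over the prevalent species; rows
    are closed to sum 1 and CLR-transformed across families.

    ``weighting='relative'`` (default) weights counts by plain relative
    abundance, which keeps the profile a nonnegative composition.
    ``weighting='clr'`` instead weights by the species' CLR value; this
    variant can produce negative totals (CLR values are negative for
    below-geometric-mean taxa), which are clipped to zero before
    closure, and is provided for comparison only.
    """
    missing = [s for s in prevalent_species if s not in counts.species]
    if missing:
        raise KeyError(f"species without annotation rows: {missing}")
    unknown = [s for s in prevalent_species if s not in matrix.species]
    if unknown:
        raise KeyError(f"prevalent species absent from matrix: {unknown}")

    rel = matrix.abundance[list(prevalent_species)]
    count_block = counts.counts.loc[list(prevalent_species)].to_numpy(dtype=float)

    if weighting == "relative":
        weights = rel.to_numpy(dtype=float)
    elif weighting == "clr":
        weights = clr_transform_values(
            rel.div(rel.sum(axis=1), axis=0).to_numpy(), zero_replacement
        )
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    profile = weights @ count_block  # sample x family
    if weighting == "clr":
        profile = np.clip(profile, 0.0, None)
    totals = profile.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("a sample has empty functional profile")
    profile = profile / totals

    relative = pd.DataFrame(profile, index=matrix.samples, columns=counts.families)
    clr = pd.DataFrame(
        clr_transform_values(profile, zero_replacement),
        index=matrix.samples,
        columns=counts.families,
    )
    return FunctionalProfile(
        relative=relative,
        clr=clr,
        groups=matrix.groups.copy(),
        roles=counts.roles.copy(),
        weighting=weighting,
        zero_policy={"method": "multiplicative", "zero_replacement": zero_replacement},
    )


def family_da(
    profile: FunctionalProfile,
    case_group: str,
    control_groups: list[str],
    q_thresh: float = 0.05,
    fold_thresh: float = 2.0,
) -> _da.DaResult:
    """Consensus differential abundance at the protein-family level."""
    return _da.consensus_da(
        profile.clr,
        profile.relative,
        profile.groups,
        case_group,
        control_groups,
        q_thresh=q_thresh,
        fold_thresh=fold_thresh,
    )


def aggregate_roles(
    result: _da.DaResult, roles: pd.Series
) -> pd.DataFrame:
    """Group consensus-differential families by functional role.

    Returns one row per (role, direction) with the member families, so a
    role shifted both ways appears twice rather than being averaged away.
    """
    cons = result.consensus[result.consensus["consensus"]]
    missing = [f for f in cons.index if f not in roles.index]
    if missing:
        raise KeyError(f"differential families without a role: {missing}")
    if cons.empty:
        return pd.DataFrame(columns=["role", "direction", "n_families", "families"])
    rows = []
    frame = cons.assign(role=[roles[f] for f in cons.index])
    for (role, direction), block in frame.groupby(["role", "direction"]):
        rows.append(
            {
                "role": role,
                "direction": direction,
                "n_families": len(block),
                "families": ",".join(block.index),
            }
        )
    return pd.DataFrame(rows).sort_values(["role", "direction"]).reset_index(drop=True)
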