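"""Consensus differential abundance on CLR-transformed profiles.

Each species is tested case-vs-control with a two-sided Mann-Whitney U
test on its CLR values, corrected across species with Benjamini-Hochberg
within each comparison.  A species is a *consensus* differentially
abundant species only if, against every control group, it is significant
(q below threshold), at least twofold different on the relative-abundance
scale, and shifted in the same direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .composition import DEFAULT_ZERO_REPLACEMENT

__all__ = [
    "DaResult",
    "mwu_per_species",
    "bh_adjust",
    "fold_change",
    "consensus_da",
    "significance_code",
]


def significance_code(q: float) -> str:
    """Conventional star codes: * q<0.05, ** q<0.01, *** q<0.001."""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


@dataclass
class DaResult:
    """Per-comparison tests plus the cross-control consensus call.

    ``per_comparison`` has one row per (species, control group) with the
    U statistic, p, BH q, fold change and direction; ``consensus`` has
    one row per species with the overall flag and direction.
    """

    case_group: str
    control_groups: list[str]
    per_comparison: pd.DataFrame
    consensus: pd.DataFrame
    q_threshold: float = 0.05
    fold_threshold: float = 2.0

    @property
    def consensus_species(self) -> list[str]:
        mask = self.consensus["consensus"]
        return list(self.consensus.index[mask])

    def validate(self) -> None:
        """Check the consensus invariant row by row."""
        for sp in self.consensus_species:
            rows = self.per_comparison.loc[
                self.per_comparison["species"] == sp
            ]
            assert (rows["q"] < self.q_threshold).all()
            assert (rows["fold"] >= self.fold_threshold).all()
            assert rows["direction"].nunique() == 1


def mwu_per_species(
    clr_values: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per species between two groups.

    Returns a DataFrame indexed by species with columns ``U`` (statistic
    for group_a) and ``p``.
    """
    a = clr_values.loc[groups == group_a]
    b = clr_values.loc[groups == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least two samples")
    res = mannwhitneyu(a.to_numpy(), b.to_numpy(), alternative="two-sided", axis=0)
    return pd.DataFrame(
        {"U": res.statistic, "p": res.pvalue}, index=clr_values.columns
    )


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(
    rel_values: pd.DataFrame,
    groups: pd.Series,
    species: str,
    group_a: str,
    group_b: str,
    method: str = "geometric",
    zero_replacement: float = DEFAULT_ZERO_REPLACEMENT,
) -> tuple[float, str | None]:
    """Fold difference of a species between two groups (>= 1 by convention).

    The default compares zero-replaced geometric means of relative
    abundance — the compositional analogue of a mean, consistent with
    testing on CLR values.  ``method='arithmetic'`` compares plain means.
    Returns ``(fold, direction)`` where direction names the higher group,
    or None when the means are equal.
    """
    x = rel_values.loc[groups == group_a, species].to_numpy(dtype=float)
    y = rel_values.loc[groups == group_b, species].to_numpy(dtype=float)
    if method == "geometric":
        mean_a = float(np.exp(np.log(np.maximum(x, zero_replacement)).mean()))
        mean_b = float(np.exp(np.log(np.maximum(y, zero_replacement)).mean()))
    elif method == "arithmetic":
        mean_a, mean_b = float(x.mean()), float(y.mean())
        if mean_a == 0 or mean_b == 0:
            mean_a = max(mean_a, zero_replacement)
            mean_b = max(mean_b, zero_replacement)
    else:
        raise ValueError(f"unknown fold-change method {method!r}")
    if mean_a == mean_b:
        return 1.0, None
    if mean_a > mean_b:
        return mean_a / mean_b, group_a
    return mean_b / mean_a, group_b


def consensus_da(
    clr_values: pd.DataFrame,
    rel_values: pd.DataFrame,
    groups: pd.Series,
    case_group: str,
    control_groups: list[str],
    q_thresh: float = 0.05,
    fold_thresh: float = 2.0,
    fold_method: str = "geometric",
) -> DaResult:
    """Run the multi-control consensus differential-abundance procedure.

    For each control group: Mann-Whitney per species on CLR values, BH
    across species *within* that comparison, and a fold change on the
    relative-abundance scale.  A species reaches consensus only when it
    is significant, at least ``fold_thresh``-fold different, and shifted
    the same way against every control.
    """
    if not control_groups:
        raise ValueError("need at least one control group")
    if case_group in control_groups:
        raise ValueError("case group cannot also be a control group")

    records = []
    for control in control_groups:
        tests = mwu_per_species(clr_values, groups, case_group, control)
        tests["q"] = bh_adjust(tests["p"])
        for sp in clr_values.columns:
            fold, higher = fold_change(
                rel_values, groups, sp, case_group, control, method=fold_method
            )
            direction = None
            if higher == case_group:
                direction = "elevated"
            elif higher == control:
                direction = "depleted"
            records.append(
                {
                    "species": sp,
                    "control": control,
                    "U": tests.loc[sp, "U"],
                    "p": tests.loc[sp, "p"],
                    "q": tests.loc[sp, "q"],
                    "code": significance_code(tests.loc[sp, "q"]),
                    "fold": fold,
                    "direction": direction,
                }
            )
    per_comparison = pd.DataFrame.from_records(records)

    cons_rows = []
    for sp, rows in per_comparison.groupby("species", sort=False):
        significant = (rows["q"] < q_thresh).all()
        big_enough = (rows["fold"] >= fold_thresh).all()
        directions = rows["direction"].dropna().unique()
        consistent = len(directions) == 1 and rows["direction"].notna().all()
        flag = bool(significant and big_enough and consistent)
        cons_rows.append(
            {
                "species": sp,
                "consensus": flag,
                "direction": directions[0] if flag else None,
                "max_q": float(rows["q"].max()),
                "min_fold": float(rows["fold"].min()),
            }
        )
    consensus = pd.DataFrame(cons_rows).set_index("species")
    consensus = consensus.loc[clr_values.columns]

    return DaResult(
        case_group=case_group,
        control_groups=list(control_groups),
        per_comparison=per_comparison,
        consensus=consensus,
        q_threshold=q_thresh,
        fold_threshold=fold_thresh,
    )
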