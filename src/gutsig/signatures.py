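"""Signature-species selection by noise-calibrated random-forest importance.

Random-forest feature importances rank features but carry no
significance.  To attach one, a fresh synthetic "noise" feature — drawn
from a normal distribution fitted to the pooled CLR values — is appended
before each of R forest fits.  A feature whose importance distribution
across the R runs is significantly above the noise feature's (two-sided
Mann-Whitney U, Benjamini-Hochberg q < 0.05, restricted to features
whose mean importance exceeds the noise mean) is a *signature* feature;
signature species feed the downstream network and functional stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import train_test_split

from .composition import ClrMatrix
from .da import bh_adjust

__all__ = [
    "FeatureTable",
    "SignatureSet",
    "NOISE_FEATURE",
    "build_feature_table",
    "make_noise_feature",
    "importance_runs",
    "significant_features",
    "evaluate_classifier",
]

NOISE_FEATURE = "__noise__"

#: Trees per forest; unstated by convention, chosen large enough that
#: impurity importances are stable across runs.
DEFAULT_N_TREES = 500


@dataclass
class FeatureTable:
    """Feature matrix (CLR species + label-encoded metadata) and labels."""

    X: pd.DataFrame
    y: pd.Series
    clr_mean: float = 0.0
    clr_sd: float = 1.0
    encodings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature table contains missing values")
        if not self.X.index.equals(self.y.index):
            raise ValueError("features and labels must share an index")

    @property
    def classes(self) -> list:
        return sorted(self.y.unique())


def _label_encode(series: pd.Series) -> tuple[pd.Series, dict]:
    """Deterministic lexicographic integer codes for a categorical column."""
    levels = sorted(series.astype(str).unique())
    mapping = {lvl: i for i, lvl in enumerate(levels)}
    return series.astype(str).map(mapping), mapping


def build_feature_table(
    clr: ClrMatrix,
    label_column: str = "group",
    label_merge: dict[str, str] | None = None,
    metadata_features: tuple[str, ...] = ("age", "sex", "subject_id"),
) -> FeatureTable:
    """Assemble the classifier input from CLR species values and metadata.

    Categorical metadata (sex, subject id) is label encoded with
    deterministic lexicographic codes; the subject id is included so the
    forest can account for replicate structure.  ``label_merge`` maps
    raw group labels onto classification labels (e.g. pooling external
    healthy cohorts under one "Healthy" label).
    """
    X = clr.values.copy()
    encodings: dict = {}
    for col in metadata_features:
        if col not in clr.metadata.columns:
            continue
        series = clr.metadata[col]
        if series.dtype == object or str(series.dtype) == "category":
            encoded, mapping = _label_encode(series)
            encodings[col] = mapping
            X[col] = encoded
        else:
            X[col] = series.astype(float)
    y = clr.metadata[label_column].astype(str)
    if label_merge:
        y = y.map(lambda g: label_merge.get(g, g))
    pooled = clr.values.to_numpy().ravel()
    return FeatureTable(
        X=X,
        y=y,
        clr_mean=float(pooled.mean()),
        clr_sd=float(pooled.std()),
        encodings=encodings,
    )


def make_noise_feature(
    table: FeatureTable, rng: np.random.Generator
) -> np.ndarray:
    """Draw a noise column from Normal(mu, sd) fitted to the pooled CLR data."""
    return rng.normal(table.clr_mean, table.clr_sd, size=len(table.X))


def importance_runs(
    table: FeatureTable,
    R: int = 100,
    seed: int | None = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> pd.DataFrame:
    """R forest fits, each with a fresh noise column; importances per run.

    Returns an ``R x (n_features + 1)`` DataFrame whose last column is
    :data:`NOISE_FEATURE`.  Importances are mean-decrease-in-impurity,
    which sum to 1 within a run.  Run-level seeds are spawned
    deterministically from the master seed.
    """
    if R < 2:
        raise ValueError("need at least two runs")
    if table.y.nunique() < 2:
        raise ValueError("labels must contain at least two classes")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(R)
    rows = np.empty((R, table.X.shape[1] + 1))
    for r in range(R):
        rng = np.random.default_rng(children[r])
        noise = make_noise_feature(table, rng)
        X = np.column_stack([table.X.to_numpy(dtype=float), noise])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(X, table.y.to_numpy())
        rows[r] = forest.feature_importances_
    columns = list(table.X.columns) + [NOISE_FEATURE]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class SignatureSet:
    """Selection outcome per feature.

    ``table`` is indexed by feature with mean importance, U, p, q and
    the selected flag; selection requires both q < alpha and a mean
    importance above the noise feature's mean.
    """

    table: pd.DataFrame
    alpha: float = 0.05
    noise_mean: float = 0.0

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    def selected_species(self, species_universe) -> list[str]:
        universe = set(species_universe)
        return [f for f in self.selected if f in universe]


def significant_features(
    importances: pd.DataFrame, alpha: float = 0.05
) -> SignatureSet:
    """Test candidate features' importance distributions against the noise's.

    Candidates are features with mean importance above the noise mean;
    only candidates enter the Mann-Whitney tests and the BH correction,
    mirroring the screening order of the selection procedure.
    """
    if NOISE_FEATURE not in importances.columns:
        raise ValueError("importance table lacks the noise feature column")
    noise = importances[NOISE_FEATURE].to_numpy()
    noise_mean = float(noise.mean())
    means = importances.mean(axis=0)

    features = [c for c in importances.columns if c != NOISE_FEATURE]
    candidates = [f for f in features if means[f] > noise_mean]

    stats = pd.DataFrame(
        index=pd.Index(features, name="feature"),
        columns=["mean_importance", "U", "p", "q", "selected"],
    )
    stats["mean_importance"] = means[features]
    stats["selected"] = False
    if candidates:
        u_vals, p_vals = [], []
        for f in candidates:
            res = mannwhitneyu(
                importances[f].to_numpy(), noise, alternative="two-sided"
            )
            u_vals.append(float(res.statistic))
            p_vals.append(float(res.pvalue))
        q_vals = bh_adjust(np.asarray(p_vals))
        stats.loc[candidates, "U"] = u_vals
        stats.loc[candidates, "p"] = p_vals
        stats.loc[candidates, "q"] = q_vals
        stats.loc[candidates, "selected"] = q_vals < alpha
    stats = stats.sort_values("mean_importance", ascending=False)
    return SignatureSet(table=stats, alpha=alpha, noise_mean=noise_mean)


def evaluate_classifier(
    table: FeatureTable,
    train_fraction: float = 0.70,
    seed: int | None = 0,
    n_trees: int = DEFAULT_N_TREES,
) -> dict:
    """Stratified train/test evaluation of the forest classifier.

    Splits 70/30 by default, fits on the training part, and reports the
    per-class F1 (harmonic mean of precision and recall), the
    support-weighted average F1, and the confusion table for
    misclassification analysis.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    X = table.X.to_numpy(dtype=float)
    y = table.y.to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        train_size=train_fraction,
        stratify=y,
        random_state=seed if seed is None else int(seed) % (2**31 - 1),
    )
    classes = sorted(np.unique(y))
    if sorted(np.unique(y_tr)) != classes or sorted(np.unique(y_te)) != classes:
        raise ValueError("a class is absent from one side of the split")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed if seed is None else int(seed) % (2**31 - 1),
        n_jobs=1,
    )
    forest.fit(X_tr, y_tr)
    pred = forest.predict(X_te)
    per_class = f1_score(y_te, pred, labels=classes, average=None, zero_division=0)
    weighted = f1_score(y_te, pred, labels=classes, average="weighted", zero_division=0)
    cm = confusion_matrix(y_te, pred, labels=classes)
    return {
        "classes": classes,
        "f1_per_class": {c: float(f) for c, f in zip(classes, per_class)},
        "f1_weighted": float(weighted),
        "confusion": pd.DataFrame(cm, index=classes, columns=classes),
    }
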