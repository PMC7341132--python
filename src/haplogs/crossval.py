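"""Validation schemes, predictive ability, and model-comparison statistics.

Three ways of splitting a panel into calibration and validation sets:

* ``make_kfold`` — random k-fold cross validation (default 4 folds,
  repeated 4 times), so every line is validated exactly once per
  repetition;
* ``make_stratified`` — training-population optimisation by stratified
  sampling: a fixed fraction (default 75%, 16 replicates) drawn from every
  cluster so all subpopulations are represented in the calibration set;
* ``leave_cluster_out`` — train on all clusters but one and predict the
  held-out cluster, exposing the cost of population structure.

Predictive ability is the Pearson correlation between observed (adjusted)
phenotypes and predicted additive values in the validation set.
Comparisons across models use the Fisher-Z transform, the
T = r·sqrt(n-2)/sqrt(1-r²) statistic against t with n-2 df, and a paired
t-test on per-replicate Fisher-Z differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CVScheme", "make_kfold", "make_stratified", "leave_cluster_out",
           "predictive_ability", "fisher_z", "t_statistic",
           "paired_comparison", "cross_validate"]


@dataclass
class CVScheme:
    scheme_type: str                       # kfold | stratified | leave_cluster_out
    replicates: list                       # list of (training ids, validation ids)
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for train, val in self.replicates:
            if set(train) & set(val):
                raise ValueError("training and validation sets overlap")

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (train, val) in enumerate(self.replicates):
            rows += [{"replicate": i, "role": "train", "line_id": l} for l in train]
            rows += [{"replicate": i, "role": "validation", "line_id": l} for l in val]
        return pd.DataFrame(rows)


def make_kfold(lines: list, k: int = 4, repetitions: int = 4,
               seed: int = 0) -> CVScheme:
    """Random k-fold splits: shuffle, cut into k near-equal folds, rotate.

    Fold sizes differ by at most one; within a repetition every line is
    validated exactly once.
    """
    lines = list(lines)
    n = len(lines)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds number of lines {n}")
    rng = np.random.default_rng(seed)
    replicates = []
    for _ in range(repetitions):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fold in folds:
            fold_set = set(fold.tolist())
            val = [lines[i] for i in fold]
            train = [lines[i] for i in perm if i not in fold_set]
            replicates.append((train, val))
    return CVScheme("kfold", replicates,
                    {"k": k, "repetitions": repetitions, "seed": seed})


def make_stratified(lines: list, cluster_labels: pd.Series,
                    train_fraction: float = 0.75, repetitions: int = 16,
                    seed: int = 0) -> CVScheme:
    """Stratified-sampling calibration sets: a fixed fraction per cluster.

    Per replicate, round-half-up(train_fraction x size_c) lines are drawn
    from each cluster c without replacement; the remainder validates.
    With clusters of 176/89/118 at 75% this yields the canonical 288-line
    calibration set (132 + 67 + 89) and 95 validation lines.
    """
    lines = list(lines)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    labels = cluster_labels.reindex(lines)
    if labels.isna().any():
        missing = labels.index[labels.isna()][:5].tolist()
        raise ValueError(f"lines without cluster labels: {missing}")
    rng = np.random.default_rng(seed)
    clusters = {c: [l for l in lines if labels[l] == c]
                for c in sorted(pd.unique(labels))}
    for c, members in clusters.items():
        if len(members) < 2:
            raise ValueError(f"cluster {c!r} has fewer than 2 lines")
    replicates = []
    for _ in range(repetitions):
        train: list = []
        for c, members in clusters.items():
            n_c = int(np.floor(train_fraction * len(members) + 0.5))
            n_c = min(max(n_c, 1), len(members) - 1)   # keep both sets nonempty
            pick = rng.choice(len(members), size=n_c, replace=False)
            train += [members[i] for i in pick]
        train_set = set(train)
        val = [l for l in lines if l not in train_set]
        replicates.append((train, val))
    return CVScheme("stratified", replicates,
                    {"train_fraction": train_fraction,
                     "repetitions": repetitions, "seed": seed})


def leave_cluster_out(lines: list, cluster_labels: pd.Series) -> CVScheme:
    """One replicate per cluster: train on the others, predict the held-out."""
    lines = list(lines)
    labels = cluster_labels.reindex(lines)
    if labels.isna().any():
        raise ValueError("every line needs a cluster label")
    clusters = sorted(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("leave-cluster-out needs at least 2 clusters")
    replicates = []
    for c in clusters:
        val = [l for l in lines if labels[l] == c]
        train = [l for l in lines if labels[l] != c]
        replicates.append((train, val))
    return CVScheme("leave_cluster_out", replicates,
                    {"clusters": [str(c) for c in clusters]})


def predictive_ability(y_val: np.ndarray, a_val: np.ndarray) -> float:
    """Pearson correlation between observed and predicted values."""
    y_val = np.asarray(y_val, dtype=float)
    a_val = np.asarray(a_val, dtype=float)
    if y_val.size != a_val.size:
        raise ValueError("vector length mismatch")
    if y_val.size < 3:
        raise ValueError("predictive ability needs at least 3 pairs")
    if np.std(y_val) == 0 or np.std(a_val) == 0:
        raise ValueError("predictive ability undefined for a constant vector")
    return float(np.corrcoef(y_val, a_val)[0, 1])


def fisher_z(r: float) -> float:
    """Variance-stabilising transform z = arctanh(r)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| must be < 1 for the Fisher Z transform")
    return np.arctanh(r) if r.ndim else float(np.arctanh(r))


def t_statistic(r: float, n: int) -> float:
    """T = r·sqrt(n-2)/sqrt(1-r²), referred to t with n-2 df.

    ``n`` is the validation-set size behind the correlation.
    """
    if n <= 2:
        raise ValueError("n must exceed 2")
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    return float(r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2))


def paired_comparison(r_single, r_hap) -> tuple[float, float]:
    """Percent change in mean r and a paired t-test on Fisher-Z differences.

    Both vectors must come from the same calibration/validation splits,
    one entry per replicate.  Returns (percent change, two-sided p).
    """
    r_single = np.asarray(r_single, dtype=float)
    r_hap = np.asarray(r_hap, dtype=float)
    if r_single.shape != r_hap.shape:
        raise ValueError("replicate vectors must have equal length")
    pct = 100.0 * (r_hap.mean() - r_single.mean()) / r_single.mean()
    dz = np.arctanh(r_hap) - np.arctanh(r_single)
    if np.allclose(dz, 0.0):
        return float(pct), 1.0
    if np.std(dz, ddof=1) == 0.0:
        # identical shift in every replicate: the paired t is unbounded
        return float(pct), 0.0
    _, p = stats.ttest_rel(np.arctanh(r_hap), np.arctanh(r_single))
    return float(pct), float(p)


def cross_validate(y: pd.Series, design, scheme: CVScheme,
                   model_name: str = "model") -> pd.DataFrame:
    """Run GBLUP over every replicate of a scheme; tidy per-replicate r.

    ``design`` is a :class:`~haplogs.gblup.DesignMatrix`; lines missing a
    phenotype are silently excluded from both roles.
    """
    from .gblup import gblup_predict

    rows = []
    for i, (train, val) in enumerate(scheme.replicates):
        train = [l for l in train if l in y.index and np.isfinite(y[l])]
        val = [l for l in val if l in y.index and np.isfinite(y[l])]
        fit = gblup_predict(y, design, training=train, validation=val)
        r = predictive_ability(y.reindex(val).to_numpy(),
                               fit.additive_values.reindex(val).to_numpy())
        rows.append({"model": model_name, "scheme": scheme.scheme_type,
                     "replicate": i, "r": r, "n_val": len(val)})
    return pd.DataFrame(rows)
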