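"""Spatial field adjustment, trial combination, and broad-sense heritability.

The moving-grid adjustment follows the classic field-trial recipe: for each
plot, the mean of its surrounding grid of neighbours is computed and used
as a covariate in a single-slope regression; the adjusted value removes
the fitted spatial component.  Variance components for the line (random) +
trial (fixed) model are estimated by REML, and broad-sense heritability on
an entry-mean basis is

    H = σg² / (σg² + σe²/n)

with n the number of trials.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["VarianceComponentsH", "moving_grid_adjust", "combine_trials",
           "estimate_variance_components", "heritability"]


@dataclass
class VarianceComponentsH:
    """Genetic and residual variance with entry-mean heritability."""

    sigma_g2: float
    sigma_e2: float
    n_trials: int
    H: float = None

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if self.H is None:
            self.H = heritability(self)


def heritability(vc: "VarianceComponentsH | tuple") -> float:
    """Entry-mean broad-sense heritability H = σg²/(σg² + σe²/n)."""
    if isinstance(vc, VarianceComponentsH):
        sg2, se2, n = vc.sigma_g2, vc.sigma_e2, vc.n_trials
    else:
        sg2, se2, n = vc
    if sg2 < 0 or se2 < 0:
        raise ValueError("variance components must be non-negative")
    if sg2 == 0 and se2 == 0:
        raise ValueError("H undefined when both variance components are zero")
    return sg2 / (sg2 + se2 / n)


def _ring_offsets(window: int) -> list:
    """Offsets of the surrounding grid for a given neighbour count.

    window=8 is the 3x3 ring around the centre plot; window=24 the 5x5
    ring.  The ring shrinks automatically at field edges.
    """
    radius = {8: 1, 24: 2}.get(window)
    if radius is None:
        raise ValueError("window must be 8 (3x3 ring) or 24 (5x5 ring)")
    return [(dr, dc)
            for dr in range(-radius, radius + 1)
            for dc in range(-radius, radius + 1)
            if not (dr == 0 and dc == 0)]


def moving_grid_adjust(pheno: pd.DataFrame, trait: str,
                       window: int = 8) -> pd.DataFrame:
    """Moving-grid spatial adjustment of one trait, per trial.

    For each plot the covariate is the mean of observed values in the
    surrounding ring of grid cells (shrinking at field edges).  A single
    slope b is fitted by regressing plot value on covariate, and the
    adjusted value is ``value - b*(covariate - mean(covariate))``, which
    preserves each trial's grand mean.  If the covariate has (near-)zero
    variance the trial is returned unchanged with a warning.
    """
    offsets = _ring_offsets(window)
    out = pheno.copy()
    for trial, sub in pheno.groupby("trial"):
        vals = sub[trait].to_numpy(float)
        rows = sub["row"].to_numpy(float)
        cols = sub["col"].to_numpy(float)
        if np.isnan(rows).any() or np.isnan(cols).any():
            raise ValueError(f"trial {trial!r}: row/col coordinates required")
        lookup = {(int(r), int(c)): v
                  for r, c, v in zip(rows, cols, vals) if np.isfinite(v)}
        cov = np.full(len(sub), np.nan)
        for i, (r, c) in enumerate(zip(rows, cols)):
            neigh = [lookup[(int(r) + dr, int(c) + dc)]
                     for dr, dc in offsets
                     if (int(r) + dr, int(c) + dc) in lookup]
            if neigh:
                cov[i] = float(np.mean(neigh))
        ok = np.isfinite(cov) & np.isfinite(vals)
        if ok.sum() < 3 or np.var(cov[ok]) < 1e-12:
            warnings.warn(
                f"trial {trial!r}: moving-grid covariate has no variance; "
                "adjustment skipped", stacklevel=2)
            continue
        b = float(np.polyfit(cov[ok], vals[ok], 1)[0])
        adj = vals.copy()
        adj[ok] = vals[ok] - b * (cov[ok] - cov[ok].mean())
        out.loc[sub.index, trait] = adj
    return out


def neighbor_covariate_counts(pheno: pd.DataFrame, trial: str,
                              window: int = 8) -> pd.Series:
    """Number of grid neighbours contributing to each plot's covariate."""
    offsets = _ring_offsets(window)
    sub = pheno[pheno["trial"] == trial]
    cells = {(int(r), int(c)) for r, c in zip(sub["row"], sub["col"])}
    counts = [sum((int(r) + dr, int(c) + dc) in cells for dr, dc in offsets)
              for r, c in zip(sub["row"], sub["col"])]
    return pd.Series(counts, index=sub.index)


def combine_trials(pheno: pd.DataFrame, trait: str) -> pd.Series:
    """Centre each trial at zero and average a line's values across trials.

    Lines absent from every trial are excluded (logged).  With one trial
    this is plain centring.
    """
    sub = pheno[["line_id", "trial", trait]].copy()
    n_before = sub["line_id"].nunique()
    sub = sub[np.isfinite(sub[trait])]
    n_after = sub["line_id"].nunique()
    if n_after < n_before:
        logger.info("combine_trials: %d lines had no finite %s record",
                    n_before - n_after, trait)
    if sub.empty:
        raise ValueError(f"no finite records for trait {trait!r}")
    centred = sub[trait] - sub.groupby("trial")[trait].transform("mean")
    return centred.groupby(sub["line_id"]).mean().rename(trait)


def estimate_variance_components(pheno: pd.DataFrame,
                                 trait: str) -> VarianceComponentsH:
    """REML fit of value = trial (fixed) + line (random) + residual.

    Fitted on plot-level (typically moving-grid adjusted) data with a
    random intercept per line; residual variance is identified by the
    replication of lines across trials, so at least two trials are
    required.  Negative working estimates are clipped at zero with a
    warning.
    """
    import statsmodels.formula.api as smf

    sub = pheno[["line_id", "trial", trait]].dropna()
    n_trials = sub["trial"].nunique()
    reps = sub.groupby(["line_id"]).size()
    if n_trials < 2 and (reps <= 1).all():
        raise ValueError(
            "residual variance is not estimable without >=2 trials or replicated lines")
    data = sub.rename(columns={trait: "_y"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("_y ~ C(trial)", data, groups=data["line_id"])
        # derivative-free search: the default lbfgs path can hit singular
        # information matrices when the genetic variance is small
        fit = model.fit(reml=True, method="powell")
    sg2 = float(np.asarray(fit.cov_re)[0, 0])
    se2 = float(fit.scale)
    if sg2 < 0:
        warnings.warn("negative genetic variance estimate clipped at 0", stacklevel=2)
        sg2 = 0.0
    return VarianceComponentsH(sigma_g2=sg2, sigma_e2=se2, n_trials=int(n_trials))
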