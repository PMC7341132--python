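"""Single-SNP and multi-allelic haplotype GBLUP with genomic REML.

Model
-----
    y = 1μ + Wα + e,   Var(α) = I σα²,   Var(e) = I σe²

where W is a centred additive model matrix: one column per SNP for the
single-marker model (entry x₁ - 2p₁, i.e. 2p₂ / p₂-p₁ / -2p₁ for the
three genotypes), or one column per (block, haplotype-allele) pair for
the multi-allelic haplotype model (entry x_k - 2p_k, with x_k the copies
of haplotype allele k carried and p_k its panel frequency; this matches
the conventional printed elements up to a global sign, which leaves all
additive values and predictions unchanged).

Equivalently Var(y) = G_W σα² + I σe² with G_W = WW', so the restricted
likelihood is profiled over the variance ratio on the eigen-spectrum of
G_W projected off the fixed effects — a 1-D optimisation that cannot
diverge and needs one symmetric eigendecomposition per fit.  Additive
values are a = Wα̂ with α̂ = σ̂α² W'V⁻¹(y - 1μ̂); validation lines are
scored by the same frequency-referenced W (train-then-project, identical
to the joint mixed-model equations with unobserved phenotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genio import GenotypeMatrix
from .hapblocks import HaplotypeBlockSet

logger = logging.getLogger(__name__)

__all__ = ["DesignMatrix", "VarianceComponents", "FitResult",
           "build_snp_design", "build_hap_design", "reml_fit", "gblup_predict"]


@dataclass
class DesignMatrix:
    """Centred additive model matrix with row (line) and column ids."""

    line_ids: list
    col_ids: list
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.line_ids), len(self.col_ids)):
            raise ValueError("W shape does not match ids")

    def rows(self, line_ids: list) -> np.ndarray:
        idx = [self.line_ids.index(l) for l in line_ids]
        return self.W[idx]


@dataclass
class VarianceComponents:
    sigma_marker2: float
    sigma_e2: float
    loglik: float
    n_iter: int
    converged: bool


@dataclass
class FitResult:
    mu: float
    effects: pd.Series              # column id -> α̂
    additive_values: pd.Series      # line_id -> a = Wα̂
    vc: VarianceComponents


def build_snp_design(g: GenotypeMatrix, freq_ref: list | None = None) -> DesignMatrix:
    """Centred single-SNP additive design: entry = dosage - 2p₁.

    p₁ is the A-allele frequency computed on ``freq_ref`` (default: all
    lines).  Columns monomorphic in the reference set are dropped with a
    logged count.
    """
    if freq_ref is not None and len(freq_ref) == 0:
        raise ValueError("freq_ref must be nonempty")
    if (g.dosages == -1).any():
        raise ValueError("design matrix requires imputed genotypes")
    p1 = g.allele_freqs(lines=freq_ref)
    poly = (p1 > 0) & (p1 < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("build_snp_design: dropped %d monomorphic-in-reference columns",
                    n_mono)
    W = g.dosages[:, poly].astype(float) - 2.0 * p1[poly]
    return DesignMatrix(line_ids=list(g.line_ids),
                        col_ids=[g.marker_ids[j] for j in np.flatnonzero(poly)],
                        W=W)


def build_hap_design(hbs: HaplotypeBlockSet,
                     freq_ref: list | None = None) -> DesignMatrix:
    """Centred multi-allelic haplotype design: entry = x_k - 2p_k.

    One column per (block, allele) pair; x_k is the number of copies of
    haplotype allele k a line carries (0 or 2 for inbreds) and p_k the
    allele frequency in ``freq_ref`` (default: all lines).  Alleles absent
    from the reference but carried by scored lines keep their columns with
    p_k = 0.
    """
    if hbs.n_blocks == 0:
        raise ValueError("empty haplotype block set")
    if freq_ref is not None and len(freq_ref) == 0:
        raise ValueError("freq_ref must be nonempty")
    if freq_ref is None:
        ref_rows = np.arange(len(hbs.line_ids))
    else:
        ref_rows = np.array([hbs.line_ids.index(l) for l in freq_ref])
    cols = []
    col_ids = []
    codes = hbs.allele_codes
    n = codes.shape[0]
    for b, block_id in enumerate(hbs.blocks.index):
        cb = codes[:, b]
        for k in range(1, cb.max() + 1):
            x_k = 2.0 * (cb == k)
            p_k = float((cb[ref_rows] == k).mean())
            cols.append(x_k - 2.0 * p_k)
            col_ids.append((block_id, k))
    return DesignMatrix(line_ids=list(hbs.line_ids), col_ids=col_ids,
                        W=np.column_stack(cols))


def _spectral_reml(y: np.ndarray, K: np.ndarray,
                   tol: float = 1e-12) -> VarianceComponents:
    """Profiled REML for Var(y) = K σ² + I σe² with an intercept.

    Projects the intercept out with an orthonormal complement Q, eigen-
    decomposes Q'KQ, and maximises the restricted likelihood over
    log λ (λ = σ²/σe²) by bounded scalar optimisation.
    """
    n = y.size
    X = np.ones((n, 1))
    Qfull, _ = np.linalg.qr(X, mode="complete")
    Q = Qfull[:, 1:]
    Kr = Q.T @ K @ Q
    theta, U = np.linalg.eigh((Kr + Kr.T) / 2.0)
    theta = np.maximum(theta, 0.0)
    eta = U.T @ (Q.T @ y)
    df = n - 1

    ss_total = float(eta @ eta)
    if ss_total < 1e-30 * max(1, n):
        # y constant: both components collapse to zero (degenerate)
        return VarianceComponents(0.0, 0.0, loglik=0.0, n_iter=0, converged=False)

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = theta * lam + 1.0
        s = float(np.sum(eta ** 2 / w))
        return 0.5 * (df * np.log(s / df) + float(np.sum(np.log(w))))

    def d_neg_ll(log_lam: float) -> float:
        # analytic d/d(log lam); used to polish the optimum to the precision
        # of the score equation rather than of likelihood comparisons
        lam = np.exp(log_lam)
        w = theta * lam + 1.0
        s = float(np.sum(eta ** 2 / w))
        s_prime = -lam * float(np.sum(theta * eta ** 2 / w ** 2))
        return 0.5 * (df * s_prime / s + lam * float(np.sum(theta / w)))

    res = minimize_scalar(neg_restricted_ll, bounds=(-20.0, 20.0),
                          method="bounded", options={"xatol": tol})
    x_opt = float(res.x)
    lo, hi = x_opt - 0.5, x_opt + 0.5
    if d_neg_ll(lo) < 0.0 < d_neg_ll(hi):
        from scipy.optimize import brentq
        x_opt = float(brentq(d_neg_ll, lo, hi, xtol=1e-14))
    lam = float(np.exp(x_opt))
    w = theta * lam + 1.0
    sigma_e2 = float(np.sum(eta ** 2 / w) / df)
    sigma2 = lam * sigma_e2
    loglik = -neg_restricted_ll(x_opt) - 0.5 * df * (1.0 + np.log(2.0 * np.pi))
    at_bound = abs(x_opt) > 20.0 - 1e-3
    return VarianceComponents(
        sigma_marker2=max(sigma2, 0.0),
        sigma_e2=max(sigma_e2, 0.0),
        loglik=loglik,
        n_iter=int(getattr(res, "nit", 0) or getattr(res, "nfev", 0)),
        converged=bool(res.success and not at_bound),
    )


def reml_fit(y: pd.Series, W: DesignMatrix,
             training: list | None = None) -> VarianceComponents:
    """REML estimates of (σα², σe²) on the training lines.

    ``y`` maps line id to the (adjusted, trial-combined) phenotype; the
    fit uses the kernel G_W = W_train W_train', whose variance parameter
    is σα² directly.
    """
    if training is None:
        training = [l for l in W.line_ids if l in y.index]
    if len(training) <= 2:
        raise ValueError("need more than 2 training lines")
    Wt = W.rows(training)
    yt = y.reindex(training).to_numpy(float)
    if np.isnan(yt).any():
        raise ValueError("phenotype missing for some training lines")
    K = Wt @ Wt.T
    c = float(np.trace(K)) / len(training)
    if c <= 0 or np.allclose(K, 0.0):
        raise ValueError("G_W has rank 0 (all-zero design rows)")
    # normalise the kernel to mean diagonal 1: conditions the 1-D search and
    # makes the fit exactly invariant to rescaling W -> cW
    vc = _spectral_reml(yt, K / c)
    return VarianceComponents(
        sigma_marker2=vc.sigma_marker2 / c,
        sigma_e2=vc.sigma_e2,
        loglik=vc.loglik,
        n_iter=vc.n_iter,
        converged=vc.converged,
    )


def gblup_predict(y: pd.Series, W: DesignMatrix, training: list,
                  validation: list | None = None,
                  vc: VarianceComponents | None = None) -> FitResult:
    """Fit GBLUP on the training lines and score every line in W.

    μ̂ is the GLS intercept under V = G_W σ̂α² + I σ̂e²; marker/haplotype
    effects are α̂ = σ̂α² W_train' V⁻¹ (y_train - 1μ̂) and additive values
    a = Wα̂ for all lines (training and validation alike, through the same
    frequency-referenced design).
    """
    if validation:
        overlap = set(training) & set(validation)
        if overlap:
            raise ValueError(f"training and validation overlap: {sorted(overlap)[:5]}")
        missing_rows = [l for l in validation if l not in W.line_ids]
        if missing_rows:
            raise ValueError(f"validation lines absent from design: {missing_rows[:5]}")
    if vc is None:
        vc = reml_fit(y, W, training)
    Wt = W.rows(training)
    yt = y.reindex(training).to_numpy(float)
    n_t = len(training)
    K = Wt @ Wt.T
    V = K * vc.sigma_marker2 + np.eye(n_t) * vc.sigma_e2
    if vc.sigma_e2 < 1e-10 * max(1.0, vc.sigma_marker2):
        Vinv = np.linalg.pinv(V, hermitian=True)
    else:
        Vinv = np.linalg.inv(V)
    ones = np.ones(n_t)
    mu = float(ones @ Vinv @ yt) / float(ones @ Vinv @ ones)
    alpha = vc.sigma_marker2 * (Wt.T @ (Vinv @ (yt - mu)))
    a = W.W @ alpha
    return FitResult(
        mu=mu,
        effects=pd.Series(alpha, index=pd.Index(W.col_ids, tupleize_cols=False)),
        additive_values=pd.Series(a, index=pd.Index(W.line_ids, name="line_id")),
        vc=vc,
    )
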