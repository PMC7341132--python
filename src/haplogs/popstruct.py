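"""Population structure: GRM, IBS distance, K-means, PCA, and adjacent LD.

The genomic relationship matrix follows VanRaden's first method,

    A = ZZ' / (2 Σ p_i (1 - p_i)),   Z = M - P,

with M the lines x markers matrix coded -1/0/1 (dosage - 1) and
P_i = 2(p_i - 0.5) built from the A-allele frequency p_i of each marker.
Clustering operates on principal coordinates of the 1 - IBS distance
matrix; for inbred (0/2) dosages the adjacent-marker r² computed from
two-locus haplotype frequencies equals the squared Pearson correlation of
the dosage vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GeneticMap, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["GRM", "ClusterAssignment", "LDTable", "grm_vanraden",
           "ibs_distance", "kmeans_cluster", "pca", "cluster_relationships",
           "adjacent_ld", "cluster_trait_summary"]


@dataclass
class GRM:
    line_ids: list
    A: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.line_ids, columns=self.line_ids)


@dataclass
class ClusterAssignment:
    labels: pd.Series      # line_id -> 1..K
    K: int
    inertia: float


@dataclass
class LDTable:
    pairs: pd.DataFrame            # chrom, marker_a, marker_b, r2
    per_chromosome: pd.Series      # chrom -> mean r2
    genome_mean: float             # mean of per-chromosome means


def grm_vanraden(g: GenotypeMatrix) -> GRM:
    """VanRaden genomic additive relationship matrix from dosages."""
    if (g.dosages == -1).any():
        raise ValueError("GRM requires fully imputed genotypes")
    p = g.allele_freqs()
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM denominator is zero")
    M = g.dosages.astype(float) - 1.0
    Z = M - 2.0 * (p - 0.5)
    A = (Z @ Z.T) / denom
    return GRM(line_ids=list(g.line_ids), A=A)


def ibs_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """1 - IBS genetic distance; IBS = mean shared-allele proportion."""
    if (g.dosages == -1).any():
        raise ValueError("IBS distance requires fully imputed genotypes")
    d = g.dosages.astype(float)
    # |d_i - d_j| / 2 averaged over markers = 1 - IBS for dosage data
    n = g.n_lines
    dist = np.zeros((n, n))
    for i in range(n):
        dist[i] = np.abs(d - d[i]).mean(axis=1) / 2.0
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=g.line_ids, columns=g.line_ids)


def _principal_coordinates(dist: np.ndarray, n_components: int) -> np.ndarray:
    """Classical MDS (Torgerson) embedding of a distance matrix."""
    n = dist.shape[0]
    d2 = dist ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = min(n_components, int((vals > 1e-10).sum()))
    keep = max(keep, 1)
    return vecs[:, :keep] * np.sqrt(np.maximum(vals[:keep], 0.0))


def kmeans_cluster(dist: pd.DataFrame, K: int = 3, n_components: int = 10,
                   restarts: int = 100, seed: int = 0) -> ClusterAssignment:
    """K-means on principal coordinates of a distance matrix.

    K-means needs coordinates, so the distance matrix is first embedded by
    classical multidimensional scaling; the clustering itself is a local
    search (Lloyd iterations) restarted from ``restarts`` seeded
    initializations, keeping the lowest within-cluster sum of squares —
    operationally equivalent to repeated Hartigan-Wong runs.  Labels are
    1..K, deterministic for a fixed seed.
    """
    from sklearn.cluster import KMeans

    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    n = D.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds number of lines {n}")
    coords = _principal_coordinates(D, n_components)
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed,
                algorithm="lloyd").fit(coords)
    # relabel clusters by decreasing size for a stable 1..K convention
    sizes = np.bincount(km.labels_, minlength=K)
    remap = {old: new + 1 for new, old in enumerate(np.argsort(-sizes, kind="stable"))}
    labels = pd.Series([remap[l] for l in km.labels_],
                       index=pd.Index(dist.index, name="line_id"), name="cluster")
    return ClusterAssignment(labels=labels, K=K, inertia=float(km.inertia_))


def pca(g: GenotypeMatrix, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the column-centred (unscaled) dosage matrix.

    Returns line coordinates and the fraction of total variance explained
    by each returned component.  Sign convention: within each component
    the largest-magnitude marker loading is positive.
    """
    if g.n_lines < 2:
        raise ValueError("PCA needs at least 2 lines")
    X = g.dosages.astype(float)
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = float(np.sum(S ** 2))
    if total_var == 0:
        raise ValueError("no genotypic variance")
    keep = min(n_components, S.size)
    flip = np.sign(Vt[np.arange(keep), np.abs(Vt[:keep]).argmax(axis=1)])
    flip[flip == 0] = 1.0
    coords = (U[:, :keep] * S[:keep]) * flip
    fractions = S[:keep] ** 2 / total_var
    frame = pd.DataFrame(coords, index=pd.Index(g.line_ids, name="line_id"),
                         columns=[f"PC{i + 1}" for i in range(keep)])
    return frame, fractions


def cluster_relationships(grm: GRM, assignment: ClusterAssignment) -> pd.DataFrame:
    """Mean within- and between-cluster relationship per cluster, with SEs.

    A_within(c) averages off-diagonal A_ij over pairs inside cluster c;
    A_between(c) over pairs with exactly one member in c.  Singleton
    clusters have no within pairs and report NaN.
    """
    labels = assignment.labels.reindex(grm.line_ids)
    if labels.isna().any():
        raise ValueError("cluster labels do not cover all GRM lines")
    lab = labels.to_numpy()
    A = grm.A
    iu = np.triu_indices(len(lab), k=1)
    pair_vals = A[iu]
    same = lab[iu[0]] == lab[iu[1]]
    rows = []
    for c in sorted(pd.unique(lab)):
        in_c = (lab[iu[0]] == c) | (lab[iu[1]] == c)
        w = pair_vals[in_c & same]
        b = pair_vals[in_c & ~same]
        rows.append({
            "cluster": c,
            "n_lines": int((lab == c).sum()),
            "A_within": float(w.mean()) if w.size else np.nan,
            "A_within_se": float(w.std(ddof=1) / np.sqrt(w.size)) if w.size > 1 else np.nan,
            "A_between": float(b.mean()) if b.size else np.nan,
            "A_between_se": float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("cluster")


def adjacent_ld(g: GenotypeMatrix, gmap: GeneticMap) -> LDTable:
    """Adjacent-marker r² per chromosome from two-locus haplotype frequencies.

    Lines are inbred, so the gametic phase is observed directly: each line
    contributes one two-locus haplotype read off its homozygous dosages.
    r² = D²/(p_A p_a p_B p_b); monomorphic pairs are skipped.  The genome
    mean is the mean of per-chromosome means.
    """
    if (g.dosages == -1).any() or (g.dosages == 1).any():
        raise ValueError("adjacent LD requires imputed, homozygous genotypes")
    chrom_of = np.array([gmap.chrom(mk) for mk in g.marker_ids], dtype=object)
    h = g.dosages / 2.0    # haplotype alleles in {0,1}
    records = []
    seen = []
    for c in chrom_of:
        if c not in seen:
            seen.append(c)
    for chrom in seen:
        idx = np.flatnonzero(chrom_of == chrom)
        if idx.size < 2:
            logger.info("adjacent_ld: chromosome %s has <2 markers; skipped", chrom)
            continue
        for a, b in zip(idx[:-1], idx[1:]):
            pA, pB = h[:, a].mean(), h[:, b].mean()
            if pA in (0.0, 1.0) or pB in (0.0, 1.0):
                continue
            pAB = (h[:, a] * h[:, b]).mean()
            D = pAB - pA * pB
            r2 = D ** 2 / (pA * (1 - pA) * pB * (1 - pB))
            records.append({"chrom": chrom, "marker_a": g.marker_ids[a],
                            "marker_b": g.marker_ids[b], "r2": float(r2)})
    pairs = pd.DataFrame.from_records(
        records, columns=["chrom", "marker_a", "marker_b", "r2"])
    per_chrom = pairs.groupby("chrom", sort=False)["r2"].mean()
    genome_mean = float(per_chrom.mean()) if len(per_chrom) else float("nan")
    return LDTable(pairs=pairs, per_chromosome=per_chrom, genome_mean=genome_mean)


def cluster_trait_summary(values: pd.Series,
                          assignment: ClusterAssignment) -> tuple[pd.Series, float]:
    """Per-cluster trait means and a one-way ANOVA F-test across clusters."""
    labels = assignment.labels.reindex(values.index)
    groups = [values[labels == c].to_numpy(float)
              for c in sorted(pd.unique(labels.dropna()))]
    if len(groups) < 2 or any(len(gr) < 2 for gr in groups):
        raise ValueError("ANOVA needs >=2 clusters with >=2 lines each")
    if all(np.var(gr) == 0 for gr in groups):
        raise ValueError("trait is constant within every cluster; F undefined")
    means = values.groupby(labels).mean()
    _, p = stats.f_oneway(*groups)
    return means, float(p)
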