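"""Synthetic structured inbred populations for genomic-selection analyses.

The generator emulates a spring-wheat style breeding panel: a few hundred
fully homozygous lines falling into pedigree-driven clusters, dense mapped
biallelic SNPs with strong adjacent-marker LD, polygenic traits at chosen
entry-mean heritabilities, and multi-trial field layouts with smooth
spatial trends.

Mechanics
---------
* A panel-wide pool of founder haplotypes (``n_clusters x
  founder_count_per_cluster``) is generated by a distance-dependent
  allele-copying chain around ancestral frequencies, so adjacent founder
  alleles correlate as ``exp(-ld_decay * d_cM)``.
* Each cluster owns a block of ``founder_count_per_cluster`` founders and
  draws mosaic segments from the pool with weights ``(1 - divergence)``
  uniform over all founders plus ``divergence`` concentrated on its own
  block: ``divergence`` 0 makes the clusters statistically identical,
  1 gives them disjoint founder sets (pedigree-style stratification).
* Lines are simulated directly as homozygous founder mosaics (dosages in
  {0, 2}); the mosaic switch intensity is a small fixed fraction of
  ``ld_decay`` per cM, keeping recombinant haplotype alleles rare the way
  long IBD segments do in an inbreeding programme.
* Traits: additive QTL effects at mapped marker positions (``qtl_mode
  "snp"``), or effects attached to distinct local haplotype alleles over
  short marker windows (``qtl_mode "haplotype"``), which single-SNP models
  can only partially capture.  True additive values are scaled to unit
  variance per trait so residual noise and spatial-trend amplitudes are in
  genetic-SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GeneticMap, GenotypeMatrix, write_hapmap, write_pheno

__all__ = ["SimConfig", "SimPopulation", "simulate_population",
           "simulate_phenotypes", "apply_field_layout", "write_dataset"]


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    Defaults reproduce the study conditions the package targets: 383 lines
    in three clusters of 176/89/118, 21 chromosomes of 100 mapped markers
    over 150 cM each, adjacent-marker r² in the 0.5–0.7 band, two trials,
    and traits at entry-mean heritabilities 0.3 (yield-like) and 0.7
    (protein-like).
    """

    seed: int = 0
    n_clusters: int = 3
    cluster_sizes: tuple = (176, 89, 118)
    n_chromosomes: int = 21
    markers_per_chromosome: tuple = ()          # empty -> 100 per chromosome
    map_length_cM: float = 150.0
    founder_count_per_cluster: int = 4
    divergence: float = 0.5
    ld_decay: float = 0.3                       # per-cM decay of founder allele correlation
    n_qtl: int = 60
    heritability_targets: dict = field(
        default_factory=lambda: {"yield": 0.3, "protein": 0.7})
    n_trials: int = 2
    field_rows: int = 20
    field_cols: int = 20
    spatial_trend_amplitude: float = 1.0        # genetic-SD units
    qtl_mode: str = "snp"                       # "snp" | "haplotype"
    hap_qtl_span: int = 5                       # window width for haplotype QTL

    def __post_init__(self) -> None:
        if not self.markers_per_chromosome:
            self.markers_per_chromosome = (100,) * self.n_chromosomes
        self.cluster_sizes = tuple(int(s) for s in self.cluster_sizes)
        self.markers_per_chromosome = tuple(int(m) for m in self.markers_per_chromosome)
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")
        if len(self.markers_per_chromosome) != self.n_chromosomes:
            raise ValueError("markers_per_chromosome length must equal n_chromosomes")
        if min(self.cluster_sizes) <= 0 or min(self.markers_per_chromosome) <= 0:
            raise ValueError("all counts must be positive")
        if self.founder_count_per_cluster < 1 or self.n_trials < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        for trait, h in self.heritability_targets.items():
            if not 0.0 < h <= 1.0:
                raise ValueError(f"heritability target for {trait!r} must be in (0, 1]")
        if sum(self.markers_per_chromosome) < self.n_qtl:
            raise ValueError("n_qtl exceeds total marker count")
        if self.qtl_mode not in ("snp", "haplotype"):
            raise ValueError("qtl_mode must be 'snp' or 'haplotype'")

    @property
    def n_lines(self) -> int:
        return sum(self.cluster_sizes)


@dataclass
class SimPopulation:
    """A simulated panel with its generating truth."""

    genotypes: GenotypeMatrix
    gmap: GeneticMap
    true_cluster_labels: pd.Series          # line_id -> 1..K
    qtl_positions: np.ndarray               # marker column indices (window starts for haplotype QTL)
    qtl_effects: dict                       # trait -> effects (per QTL, or per-window allele tables)
    true_additive_values: pd.DataFrame      # line_id x trait


def _founder_haplotypes(rng, freqs, positions, n_founders, ld_decay):
    """Founder pool with distance-decaying allele correlation along a chromosome."""
    m = len(freqs)
    hap = np.empty((n_founders, m), dtype=np.int8)
    hap[:, 0] = rng.random(n_founders) < freqs[0]
    keep_p = np.exp(-ld_decay * np.diff(positions))
    for j in range(1, m):
        copy = rng.random(n_founders) < keep_p[j - 1]
        fresh = (rng.random(n_founders) < freqs[j]).astype(np.int8)
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    return hap


#: mosaic switch intensity per cM, as a fraction of ld_decay.  Small, so
#: recombinant haplotype alleles stay rare (long shared IBD segments).
MOSAIC_SWITCH_FACTOR = 0.02


def _mosaic_lines(rng, founders, weights, positions, n_lines, switch_rate):
    """Homozygous mosaic lines copying from a weighted founder pool."""
    n_f, m = founders.shape
    switch_p = 1.0 - np.exp(-switch_rate * np.diff(positions))
    idx = np.empty((n_lines, m), dtype=np.int32)
    idx[:, 0] = rng.choice(n_f, size=n_lines, p=weights)
    for j in range(1, m):
        sw = rng.random(n_lines) < switch_p[j - 1]
        idx[:, j] = np.where(sw, rng.choice(n_f, size=n_lines, p=weights),
                             idx[:, j - 1])
    return founders[idx, np.arange(m)]    # (n_lines, m) alleles in {0,1}


def simulate_population(config: SimConfig) -> SimPopulation:
    """Simulate genotypes, map, cluster labels and trait architecture.

    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_lines
    K = config.n_clusters

    marker_ids, chroms, positions = [], [], []
    per_chrom_slices = []
    start = 0
    for c in range(config.n_chromosomes):
        mc = config.markers_per_chromosome[c]
        chrom_name = f"chr{c + 1}"
        pos = np.sort(rng.uniform(0.0, config.map_length_cM, size=mc)).round(4)
        # enforce strictly increasing positions after rounding
        pos = np.maximum.accumulate(pos + np.arange(mc) * 1e-4)
        marker_ids += [f"{chrom_name}_m{j + 1}" for j in range(mc)]
        chroms += [chrom_name] * mc
        positions.append(pos)
        per_chrom_slices.append(slice(start, start + mc))
        start += mc
    m_total = start

    labels = np.repeat(np.arange(1, K + 1), config.cluster_sizes)

    alleles = np.empty((n, m_total), dtype=np.int8)
    d = config.divergence
    n_f_cluster = config.founder_count_per_cluster
    n_f_total = K * n_f_cluster
    switch_rate = MOSAIC_SWITCH_FACTOR * config.ld_decay
    for sl, pos in zip(per_chrom_slices, positions):
        mc = sl.stop - sl.start
        ancestral = rng.uniform(0.1, 0.9, size=mc)
        founders = _founder_haplotypes(
            rng, ancestral, pos, n_f_total, config.ld_decay)
        row0 = 0
        for k in range(K):
            weights = np.full(n_f_total, (1.0 - d) / n_f_total)
            own = slice(k * n_f_cluster, (k + 1) * n_f_cluster)
            weights[own] += d / n_f_cluster
            weights /= weights.sum()
            nk = config.cluster_sizes[k]
            alleles[row0:row0 + nk, sl] = _mosaic_lines(
                rng, founders, weights, pos, nk, switch_rate=switch_rate)
            row0 += nk

    line_ids = [f"L{i + 1:04d}" for i in range(n)]
    allele_labels = [("A", "T")] * m_total
    g = GenotypeMatrix(line_ids, marker_ids, alleles * 2, allele_labels)
    gmap = GeneticMap.from_arrays(marker_ids, chroms, np.concatenate(positions))

    # trait architecture
    if config.qtl_mode == "snp":
        qtl_positions = np.sort(rng.choice(m_total, size=config.n_qtl, replace=False))
    else:
        # window starts aligned to hap_qtl_span so fixed-length blocks of the
        # same width capture each window exactly
        span = config.hap_qtl_span
        starts = []
        for sl in per_chrom_slices:
            n_windows = (sl.stop - sl.start) // span
            starts.extend(sl.start + span * np.arange(n_windows))
        starts = np.asarray(starts)
        qtl_positions = np.sort(rng.choice(
            starts, size=min(config.n_qtl, starts.size), replace=False))

    qtl_effects: dict = {}
    tav = {}
    for trait in config.heritability_targets:
        if config.qtl_mode == "snp":
            eff = rng.normal(0.0, 1.0, size=qtl_positions.size)
            a_true = (g.dosages[:, qtl_positions].astype(float) - 1.0) @ eff
            qtl_effects[trait] = eff
        else:
            a_true = np.zeros(n)
            tables = []
            span = config.hap_qtl_span
            for s in qtl_positions:
                vecs = g.dosages[:, s:s + span]
                _, codes = np.unique(vecs, axis=0, return_inverse=True)
                n_all = codes.max() + 1
                eff = rng.normal(0.0, 1.0, size=n_all)
                a_true += eff[codes]
                tables.append(eff)
            qtl_effects[trait] = tables
        sd = a_true.std(ddof=1)
        if sd > 0:
            scale = 1.0 / sd
            a_true = (a_true - a_true.mean()) * scale
            if config.qtl_mode == "snp":
                qtl_effects[trait] = qtl_effects[trait] * scale
            else:
                qtl_effects[trait] = [t * scale for t in qtl_effects[trait]]
        tav[trait] = a_true

    return SimPopulation(
        genotypes=g,
        gmap=gmap,
        true_cluster_labels=pd.Series(labels, index=pd.Index(line_ids, name="line_id")),
        qtl_positions=qtl_positions,
        qtl_effects=qtl_effects,
        true_additive_values=pd.DataFrame(tav, index=pd.Index(line_ids, name="line_id")),
    )


def simulate_phenotypes(pop: SimPopulation, config: SimConfig) -> pd.DataFrame:
    """Per-trial phenotypes at the configured entry-mean heritabilities.

    For each trait, residual variance is set so the expected entry-mean
    heritability H = σg² / (σg² + σe²/n_trials) matches the target, with
    σg² the realized variance of the true additive values.  Trial effects
    are fixed offsets.  Row/col are left unassigned until
    :func:`apply_field_layout`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    line_ids = list(pop.true_additive_values.index)
    n = len(line_ids)
    rows = []
    trial_effects = rng.normal(0.0, 0.5, size=config.n_trials)
    for t in range(config.n_trials):
        frame = pd.DataFrame({
            "line_id": line_ids,
            "trial": f"trial{t + 1}",
            "row": np.nan,
            "col": np.nan,
        })
        for trait, h in config.heritability_targets.items():
            a_true = pop.true_additive_values[trait].to_numpy()
            sg2 = float(np.var(a_true, ddof=1))
            if sg2 == 0.0 and h < 1.0:
                raise ValueError(f"trait {trait!r} has zero genetic variance")
            se2 = sg2 * config.n_trials * (1.0 - h) / h
            noise = rng.normal(0.0, np.sqrt(se2), size=n) if se2 > 0 else 0.0
            frame[trait] = a_true + trial_effects[t] + noise
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def apply_field_layout(pheno: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Assign row/column plot coordinates and add a smooth spatial trend.

    Each trial is laid out on the same ``field_rows`` x ``field_cols`` grid
    (serpentine fill, trial-specific random plot order) and receives a
    trial-specific quadratic surface plus row/column gradients with overall
    amplitude ``spatial_trend_amplitude`` (half-range, trait units).
    """
    n_per_trial = pheno.groupby("trial").size().max()
    if config.field_rows * config.field_cols < n_per_trial:
        raise ValueError(
            f"field grid {config.field_rows}x{config.field_cols} too small "
            f"for {n_per_trial} lines per trial")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    out = pheno.copy()
    traits = [c for c in pheno.columns if c not in ("line_id", "trial", "row", "col")]
    for t_idx, (trial, idx) in enumerate(out.groupby("trial").groups.items()):
        idx = np.asarray(idx)
        n_t = idx.size
        order = rng.permutation(n_t)
        cells = np.arange(n_t)
        r = cells // config.field_cols
        c = cells % config.field_cols
        c = np.where(r % 2 == 1, config.field_cols - 1 - c, c)   # serpentine
        out.loc[idx[order], "row"] = r.astype(float)
        out.loc[idx[order], "col"] = c.astype(float)
        if config.spatial_trend_amplitude > 0:
            coef = rng.normal(0.0, 1.0, size=5)
            rr = out.loc[idx, "row"].to_numpy(float) / max(config.field_rows - 1, 1)
            cc = out.loc[idx, "col"].to_numpy(float) / max(config.field_cols - 1, 1)
            surface = (coef[0] * rr + coef[1] * cc + coef[2] * rr * cc
                       + coef[3] * rr ** 2 + coef[4] * cc ** 2)
            span = surface.max() - surface.min()
            if span > 0:
                surface = (surface - surface.mean()) / span * 2.0 \
                    * config.spatial_trend_amplitude
            for trait in traits:
                out.loc[idx, trait] = out.loc[idx, trait] + surface
    return out


def write_dataset(pop: SimPopulation, pheno: pd.DataFrame, out_dir) -> dict:
    """Write the panel as HapMap + phenotype CSV; returns the file paths."""
    import os

    if pop.genotypes.n_lines == 0:
        raise ValueError("cannot write a dataset with 0 lines")
    os.makedirs(out_dir, exist_ok=True)
    geno_path = os.path.join(str(out_dir), "genotypes.hmp.txt")
    pheno_path = os.path.join(str(out_dir), "phenotypes.csv")
    labels_path = os.path.join(str(out_dir), "true_clusters.csv")
    write_hapmap(pop.genotypes, pop.gmap, geno_path)
    write_pheno(pheno, pheno_path)
    pop.true_cluster_labels.rename("cluster").to_csv(labels_path)
    return {"genotypes": geno_path, "phenotypes": pheno_path,
            "clusters": labels_path}
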