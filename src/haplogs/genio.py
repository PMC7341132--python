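"""Genotype and phenotype I/O, marker QC, kNN imputation, map ordering.

Genotypes live in a :class:`GenotypeMatrix`: lines x markers A-allele
dosages in {0, 1, 2} with ``-1`` as the missing sentinel.  The panel this
package targets is near-fully inbred, so dosage 1 (residual heterozygotes)
is carried through QC but resolved to the nearest homozygote during
imputation.  Files are TASSEL-style HapMap text (``hmp.txt``): 11 metadata
columns (rs#, alleles, chrom, pos, ...) followed by one genotype column per
line; readers accept gzip.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: IUPAC ambiguity codes used for heterozygous single-letter calls.
IUPAC_HET = {
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
}

HAPMAP_META_COLS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


class HapmapFormatError(ValueError):
    """Raised when a HapMap file or genotype call cannot be decoded."""


@dataclass
class GeneticMap:
    """Marker -> (chromosome, position in cM).

    Stored as a DataFrame indexed by marker id with columns ``chrom`` and
    ``pos_cM``.  Every mapped marker appears once; positions are finite.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate marker ids in genetic map")
        if not np.isfinite(self.table["pos_cM"].to_numpy(float)).all():
            raise ValueError("non-finite map positions")

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def chrom(self, marker_id: str) -> str:
        return self.table.at[marker_id, "chrom"]

    def pos(self, marker_id: str) -> float:
        return float(self.table.at[marker_id, "pos_cM"])

    @classmethod
    def from_arrays(cls, marker_ids, chroms, positions) -> "GeneticMap":
        return cls(pd.DataFrame(
            {"chrom": np.asarray(chroms, dtype=object),
             "pos_cM": np.asarray(positions, dtype=float)},
            index=pd.Index(marker_ids, name="marker_id"),
        ))


@dataclass
class GenotypeMatrix:
    """Lines x markers matrix of A-allele dosages.

    ``dosages[i, j]`` counts copies of the A allele (the first allele listed
    in the HapMap ``alleles`` column) carried by line ``i`` at marker ``j``;
    ``-1`` marks a missing call.  ``allele_labels[j]`` is the (A, B)
    nucleotide pair for marker ``j``.
    """

    line_ids: list
    marker_ids: list
    dosages: np.ndarray
    allele_labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("dosage matrix shape does not match ids")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        if not self.allele_labels:
            self.allele_labels = [("A", "T")] * len(self.marker_ids)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def allele_freqs(self, lines: list | None = None) -> np.ndarray:
        """A-allele frequency per marker over non-missing calls.

        ``lines`` restricts the computation to a subset of line ids (the
        frequency reference set for model matrices).
        """
        d = self.dosages
        if lines is not None:
            idx = [self.line_ids.index(l) for l in lines]
            d = d[idx]
        obs = d != MISSING
        with np.errstate(invalid="ignore"):
            p = np.where(
                obs.sum(axis=0) > 0,
                np.where(d == MISSING, 0, d).sum(axis=0) / (2.0 * np.maximum(obs.sum(axis=0), 1)),
                np.nan,
            )
        return p

    def maf(self) -> np.ndarray:
        p = self.allele_freqs()
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            marker_ids=[self.marker_ids[j] for j in keep],
            dosages=self.dosages[:, keep].copy(),
            allele_labels=[self.allele_labels[j] for j in keep],
        )

    def subset_lines(self, keep_ids: list) -> "GenotypeMatrix":
        idx = [self.line_ids.index(l) for l in keep_ids]
        return GenotypeMatrix(
            line_ids=list(keep_ids),
            marker_ids=list(self.marker_ids),
            dosages=self.dosages[idx].copy(),
            allele_labels=list(self.allele_labels),
        )


# ---------------------------------------------------------------------------
# HapMap reading / writing
# ---------------------------------------------------------------------------

def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _decode_call(call: str, a: str, b: str, marker: str, line: str) -> int:
    """Decode one genotype call to an A-allele dosage."""
    call = call.strip().upper()
    if call in ("N", "NN", "", "NA", "./.", "-"):
        return MISSING
    if len(call) == 1:
        if call == a:
            return 2
        if call == b:
            return 0
        het = IUPAC_HET.get(call)
        if het is not None and het == frozenset((a, b)):
            return 1
    elif len(call) == 2:
        dose = 0
        for ch in call:
            if ch == a:
                dose += 1
            elif ch != b:
                break
        else:
            return dose
    raise HapmapFormatError(
        f"cannot decode genotype call {call!r} at marker {marker!r}, "
        f"line {line!r} (alleles {a}/{b})"
    )


def read_hapmap(path) -> tuple[GenotypeMatrix, GeneticMap]:
    """Read a TASSEL-dialect HapMap file.

    Returns the genotype matrix plus a genetic map built from the chrom/pos
    columns.  Markers with missing or non-finite positions are kept in the
    matrix but flagged by omission from the map.
    """
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 12 or header[0] not in ("rs#", "rs"):
        raise HapmapFormatError(
            f"{path}: not a HapMap header (expected 'rs#' first, 11 metadata columns)"
        )
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    line_ids = list(df.columns[11:])
    marker_ids = df.iloc[:, 0].tolist()

    allele_labels = []
    for mk, al in zip(marker_ids, df["alleles"]):
        parts = al.replace("|", "/").split("/")
        if len(parts) != 2 or not all(len(p) == 1 for p in parts):
            raise HapmapFormatError(f"marker {mk!r}: unsupported alleles field {al!r}")
        allele_labels.append((parts[0].upper(), parts[1].upper()))

    n, m = len(line_ids), len(marker_ids)
    dosages = np.empty((n, m), dtype=np.int8)
    calls = df.iloc[:, 11:].to_numpy(dtype=object)
    for j in range(m):
        a, b = allele_labels[j]
        lut = {a: 2, b: 0, a + a: 2, a + b: 1, b + a: 1, b + b: 0,
               "N": MISSING, "NN": MISSING, "": MISSING, "NA": MISSING}
        for code, pair in IUPAC_HET.items():
            if pair == frozenset((a, b)):
                lut[code] = 1
        row = calls[j]
        for i in range(n):
            dose = lut.get(str(row[i]).strip().upper())
            if dose is None:
                # slow path re-raises with a precise message
                dose = _decode_call(str(row[i]), a, b, marker_ids[j], line_ids[i])
            dosages[i, j] = dose

    mapped, chroms, poss = [], [], []
    for mk, c, p in zip(marker_ids, df["chrom"], df["pos"]):
        try:
            pos = float(p)
        except ValueError:
            continue
        if np.isfinite(pos) and c not in ("", "NA", "UN", "Un"):
            mapped.append(mk)
            chroms.append(c)
            poss.append(pos)
    n_unmapped = m - len(mapped)
    if n_unmapped:
        logger.info("read_hapmap: %d of %d markers lack map positions", n_unmapped, m)
    gmap = GeneticMap.from_arrays(mapped, chroms, poss)
    g = GenotypeMatrix(line_ids, marker_ids, dosages, allele_labels)
    return g, gmap


_DOSE_TO_CALL = {2: lambda a, b: a + a, 1: lambda a, b: a + b, 0: lambda a, b: b + b,
                 MISSING: lambda a, b: "NN"}


def write_hapmap(g: GenotypeMatrix, gmap: GeneticMap, path) -> None:
    """Write genotypes + map as TASSEL-dialect HapMap (two-letter diplotypes)."""
    if g.n_lines == 0:
        raise ValueError("refusing to write a HapMap file with 0 lines")
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(HAPMAP_META_COLS + [str(l) for l in g.line_ids]) + "\n")
        for j, mk in enumerate(g.marker_ids):
            a, b = g.allele_labels[j]
            if mk in gmap:
                chrom, pos = gmap.chrom(mk), f"{gmap.pos(mk):.4f}"
            else:
                chrom, pos = "UN", "NA"
            meta = [str(mk), f"{a}/{b}", str(chrom), pos, "+", "NA",
                    "NA", "NA", "NA", "NA", "NA"]
            calls = [_DOSE_TO_CALL[int(d)](a, b) for d in g.dosages[:, j]]
            fh.write("\t".join(meta + calls) + "\n")


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

PHENO_KEY_COLS = ["line_id", "trial", "row", "col"]


def read_pheno(path) -> pd.DataFrame:
    """Read a phenotype CSV (line_id, trial, row, col, <traits...>)."""
    df = pd.read_csv(path)
    missing = [c for c in PHENO_KEY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {missing}")
    return df


def write_pheno(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def trait_columns(pheno: pd.DataFrame) -> list:
    return [c for c in pheno.columns if c not in PHENO_KEY_COLS]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def filter_markers(g: GenotypeMatrix, maf_min: float = 0.05,
                   miss_max: float = 0.10) -> GenotypeMatrix:
    """Drop markers with MAF < ``maf_min`` or missing fraction > ``miss_max``.

    Both statistics are computed on the raw matrix in a single pass (MAF on
    non-missing calls only).  Boundaries: MAF exactly equal to ``maf_min``
    is retained; missingness exactly equal to ``miss_max`` is retained.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= miss_max <= 1.0:
        raise ValueError("miss_max must be in [0, 1]")
    miss_frac = g.missing_mask().mean(axis=0)
    maf = g.maf()
    all_missing = ~np.isfinite(maf)
    keep = (~all_missing) & (maf >= maf_min) & (miss_frac <= miss_max)
    if not keep.any():
        raise ValueError("all markers removed by QC filters")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_markers: removed %d of %d markers", n_drop, g.n_markers)
    return g.subset_markers(keep)


def impute_knn(g: GenotypeMatrix, k: int = 5, l: int = 30) -> GenotypeMatrix:
    """LD-informed k-nearest-neighbour imputation (LD-kNNi style).

    For each marker ``m`` with missing calls, the ``l`` markers most
    correlated with ``m`` (complete pairs only) define a local similarity
    space.  For each line missing at ``m``, lines are ranked by mean
    absolute dosage difference over those markers and the ``k`` nearest
    lines with observed calls vote, weighted by 1/(distance + eps).  The
    imputed dosage is rounded to {0, 2}: the panel is inbred, so residual
    heterozygotes resolve to the nearest homozygote.  Observed calls are
    never altered.
    """
    if k < 1 or l < 1:
        raise ValueError("k and l must be >= 1")
    if g.n_lines < k + 1:
        raise ValueError(f"need at least k+1={k + 1} lines")
    miss = g.missing_mask()
    if not miss.any():
        return g

    d = g.dosages.astype(float)
    d[miss] = np.nan
    # pairwise marker correlations on complete pairs, via masked arrays
    dm = np.ma.masked_invalid(d)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.ma.corrcoef(dm, rowvar=False)
    corr = np.ma.filled(corr, 0.0)
    np.fill_diagonal(corr, 0.0)

    out = g.dosages.copy()
    eps = 1e-6
    for j in np.flatnonzero(miss.any(axis=0)):
        observed_j = ~miss[:, j]
        if not observed_j.any():
            raise ValueError(
                f"marker {g.marker_ids[j]!r} is missing in every line; cannot impute"
            )
        order = np.argsort(-np.abs(corr[:, j]), kind="stable")
        support = order[: min(l, g.n_markers - 1)]
        sub = d[:, support]
        for i in np.flatnonzero(miss[:, j]):
            diff = np.abs(sub - sub[i])
            with np.errstate(invalid="ignore"):
                dist = np.nanmean(diff, axis=1)
            dist[i] = np.inf
            dist[~observed_j] = np.inf
            dist[~np.isfinite(dist)] = np.inf
            nn = np.argsort(dist, kind="stable")[:k]
            nn = nn[np.isfinite(dist[nn])]
            if nn.size == 0:
                # no line shares observed support markers; fall back to all
                # lines observed at j
                nn = np.flatnonzero(observed_j)[:k]
                w = np.ones(nn.size)
            else:
                w = 1.0 / (dist[nn] + eps)
            mean_dose = float(np.sum(w * d[nn, j]) / np.sum(w))
            out[i, j] = 2 if mean_dose >= 1.0 else 0
    return replace(g, dosages=out)


def order_by_map(g: GenotypeMatrix, gmap: GeneticMap) -> GenotypeMatrix:
    """Sort markers by (chromosome, cM position, marker id); drop unmapped.

    Ties at identical cM break lexicographically on marker id.  Unmapped
    markers are dropped with a logged count, not an error.
    """
    mapped = [j for j, mk in enumerate(g.marker_ids) if mk in gmap]
    n_drop = g.n_markers - len(mapped)
    if n_drop:
        logger.info("order_by_map: dropping %d unmapped markers", n_drop)
    keys = sorted(
        mapped,
        key=lambda j: (str(gmap.chrom(g.marker_ids[j])),
                       gmap.pos(g.marker_ids[j]),
                       str(g.marker_ids[j])),
    )
    return g.subset_markers(np.array(keys, dtype=int))
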