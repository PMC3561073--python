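"""Hi-C contact matrices, per-locus bias covariates, and domain intervals.

All genomic coordinates are 0-based half-open (BED convention).  Bin order
defines matrix index.  Counts are symmetric non-negative integers; the
diagonal is read and stored but never used by any likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomicBin",
    "ContactMatrix",
    "LocusFeatures",
    "DomainSet",
    "FilterThresholds",
    "read_bins",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_locus_features",
    "write_locus_features",
    "read_domains",
    "filter_loci",
    "extract_submatrix",
]


@dataclass(frozen=True)
class GenomicBin:
    """One genomic bin (chrom, 0-based start, exclusive end)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"bin end must exceed start: {self}")

    @property
    def size(self) -> int:
        return self.end - self.start


def _check_bins(bins: list[GenomicBin]) -> None:
    if len(bins) == 0:
        raise ValueError("empty bin list")
    chroms = {b.chrom for b in bins}
    if len(chroms) != 1:
        raise ValueError(f"bins span multiple chromosomes: {sorted(chroms)}")
    for a, b in zip(bins, bins[1:]):
        if b.start < a.end:
            raise ValueError(f"bins overlap or are unsorted: {a} then {b}")


@dataclass
class ContactMatrix:
    """Symmetric matrix of Hi-C read counts over ordered genomic bins."""

    bins: list[GenomicBin]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {n} bins"
            )
        if n < 3:
            raise ValueError("a contact matrix needs at least 3 bins")
        _check_bins(self.bins)
        if np.any(self.counts < 0):
            raise ValueError("negative contact counts")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact matrix is not symmetric")

    @property
    def n_loci(self) -> int:
        return len(self.bins)

    @property
    def chrom(self) -> str:
        return self.bins[0].chrom


@dataclass
class LocusFeatures:
    """Per-bin bias covariates: fragment-end count, GC content, mappability.

    All three must be strictly positive so their logarithms are finite in
    the Poisson rate model.
    """

    frag_ends: np.ndarray
    gc: np.ndarray
    mappability: np.ndarray

    def __post_init__(self) -> None:
        self.frag_ends = np.asarray(self.frag_ends, dtype=float)
        self.gc = np.asarray(self.gc, dtype=float)
        self.mappability = np.asarray(self.mappability, dtype=float)
        n = len(self.frag_ends)
        if len(self.gc) != n or len(self.mappability) != n:
            raise ValueError("feature arrays have unequal length")
        for name, arr in (("frag_ends", self.frag_ends), ("gc", self.gc),
                          ("mappability", self.mappability)):
            if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} must be finite and strictly positive")

    def __len__(self) -> int:
        return len(self.frag_ends)

    def subset(self, idx: np.ndarray) -> "LocusFeatures":
        return LocusFeatures(self.frag_ends[idx], self.gc[idx], self.mappability[idx])


@dataclass
class DomainSet:
    """Ordered, non-overlapping labelled intervals (e.g. topological domains)."""

    intervals: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        df = self.intervals
        required = ["chrom", "start", "end", "label"]
        if list(df.columns[:4]) != required:
            df = df.copy()
            df.columns = required + list(df.columns[4:])
            self.intervals = df
        for _, grp in df.groupby("chrom"):
            s = grp.sort_values("start")
            if (s["end"].values[:-1] > s["start"].values[1:]).any():
                raise ValueError("domain intervals overlap")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        for row in self.intervals.itertuples(index=False):
            yield row


@dataclass(frozen=True)
class FilterThresholds:
    """Loci at or below any threshold are removed."""

    frag_ends: float = 5.0
    gc: float = 0.3
    mappability: float = 0.8


# ---------------------------------------------------------------------------
# I/O


def read_bins(path: str | Path) -> list[GenomicBin]:
    """Read a BED3 bin table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    return [GenomicBin(str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples(index=False)]


def read_contact_matrix(path: str | Path, bins_path: str | Path,
                        fmt: str = "dense") -> ContactMatrix:
    """Read a contact matrix from dense TSV or sparse triplet TSV.

    Dense: N rows x N tab-separated integer columns.  Sparse: three columns
    (bin_i, bin_j, count) with bin indices into the companion bin table;
    entries are mirrored and missing pairs are zero.
    """
    bins = read_bins(bins_path)
    n = len(bins)
    if fmt == "dense":
        mat = pd.read_csv(path, sep="\t", header=None).values.astype(float)
        if mat.shape != (n, n):
            raise ValueError(f"dense matrix shape {mat.shape}, expected ({n},{n})")
        if not np.allclose(mat, mat.T, atol=0.5):
            raise ValueError("dense matrix asymmetric beyond integer tolerance")
        counts = np.rint((mat + mat.T) / 2).astype(np.int64)
    elif fmt == "triplet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["i", "j", "count"])
        counts = np.zeros((n, n), dtype=np.int64)
        for i, j, c in df.itertuples(index=False):
            i, j, c = int(i), int(j), int(c)
            if c < 0:
                raise ValueError(f"negative count at ({i},{j}): {c}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"triplet index ({i},{j}) out of range for {n} bins")
            counts[i, j] = c
            counts[j, i] = c
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return ContactMatrix(bins, counts)


def write_contact_matrix(cm: ContactMatrix, path: str | Path,
                         bins_path: str | Path, fmt: str = "dense") -> None:
    pd.DataFrame([(b.chrom, b.start, b.end) for b in cm.bins]).to_csv(
        bins_path, sep="\t", header=False, index=False)
    if fmt == "dense":
        pd.DataFrame(cm.counts).to_csv(path, sep="\t", header=False, index=False)
    elif fmt == "triplet":
        iu = np.triu_indices(cm.n_loci)
        mask = cm.counts[iu] != 0
        df = pd.DataFrame({"i": iu[0][mask], "j": iu[1][mask],
                           "count": cm.counts[iu][mask]})
        df.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_locus_features(path: str | Path) -> LocusFeatures:
    """Read features as BED3 + frag_ends, gc, mappability columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "frag_ends", "gc",
                            "mappability"])
    return LocusFeatures(df["frag_ends"].values, df["gc"].values,
                         df["mappability"].values)


def write_locus_features(lf: LocusFeatures, bins: list[GenomicBin],
                         path: str | Path) -> None:
    df = pd.DataFrame({
        "chrom": [b.chrom for b in bins],
        "start": [b.start for b in bins],
        "end": [b.end for b in bins],
        "frag_ends": lf.frag_ends,
        "gc": lf.gc,
        "mappability": lf.mappability,
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def read_domains(path: str | Path) -> DomainSet:
    """Read a BED4 domain table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "label"])
    return DomainSet(df)


# ---------------------------------------------------------------------------
# Filtering and subsetting


def filter_loci(cm: ContactMatrix, lf: LocusFeatures,
                thresholds: FilterThresholds = FilterThresholds(),
                ) -> tuple[ContactMatrix, LocusFeatures, np.ndarray]:
    """Drop unreliable loci: few restriction fragment ends, low GC, or low
    mappability.  A locus equal to a threshold is removed.

    Returns the reduced matrix and features plus an index map giving, for
    each kept locus, its position in the original matrix.
    """
    if len(lf) != cm.n_loci:
        raise ValueError("features do not match matrix size")
    keep = ((lf.frag_ends > thresholds.frag_ends)
            & (lf.gc > thresholds.gc)
            & (lf.mappability > thresholds.mappability))
    kept_idx = np.flatnonzero(keep)
    if len(kept_idx) < 3:
        raise ValueError(
            f"only {len(kept_idx)} loci pass filtering; region unusable")
    bins = [cm.bins[i] for i in kept_idx]
    counts = cm.counts[np.ix_(kept_idx, kept_idx)]
    return ContactMatrix(bins, counts), lf.subset(kept_idx), kept_idx


def extract_submatrix(cm: ContactMatrix, lf: LocusFeatures,
                      chrom: str, start: int, end: int,
                      ) -> tuple[ContactMatrix, LocusFeatures]:
    """Keep the bins fully inside [start, end) on chrom, preserving order."""
    if len(lf) != cm.n_loci:
        raise ValueError("features do not match matrix size")
    idx = np.array([i for i, b in enumerate(cm.bins)
                    if b.chrom == chrom and b.start >= start and b.end <= end],
                   dtype=int)
    if len(idx) == 0:
        raise ValueError(f"no bins inside {chrom}:{start}-{end}")
    bins = [cm.bins[i] for i in idx]
    counts = cm.counts[np.ix_(idx, idx)]
    return ContactMatrix(bins, counts), lf.subset(idx)
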