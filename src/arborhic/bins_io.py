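"""Binned Hi-C matrix and 1D-signal input/output.

The bin table is the single source of region identity: a 4-column TSV
(chrom, start, end, index) with 0-based half-open coordinates, sorted by
(chrom, start), indices contiguous from 0.  Contact matrices come either as
a dense whitespace-separated numeric grid or as a sparse 3-column triple
file (bin_i, bin_j, count); triples are mirrored so the in-memory matrix is
always symmetric.

Besides plain reading/writing this module provides ICE matrix balancing
(iterative correction of per-bin multiplicative biases), aggregation of a
matrix onto larger intervals (e.g. TADs), and the three per-bin summaries
of 1D genomic tracks used to interpret clusters: peak counts, covered-base
fractions (e.g. LADs) and length-weighted mean values (e.g. replication
timing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9

BIN_COLUMNS = ["chrom", "start", "end", "index"]


@dataclass(frozen=True)
class BinTable:
    """Ordered genomic bins: 0-based half-open, sorted, indices 0..n-1."""

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        if list(df.columns) != BIN_COLUMNS:
            raise ValueError(f"bin table must have columns {BIN_COLUMNS}")
        if (df["start"] >= df["end"]).any():
            raise ValueError("bin start must be < end")
        if not (df["index"].to_numpy() == np.arange(len(df))).all():
            raise ValueError("bin indices must be contiguous 0..n-1")
        key = df[["chrom", "start"]]
        if not key.equals(key.sort_values(["chrom", "start"], kind="stable")):
            raise ValueError("bins must be sorted by (chrom, start)")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chroms(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    @property
    def starts(self) -> np.ndarray:
        return self.frame["start"].to_numpy()

    @property
    def ends(self) -> np.ndarray:
        return self.frame["end"].to_numpy()

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts


@dataclass
class ContactMatrix:
    """Symmetric nonnegative contact-count matrix over a bin table."""

    bins: BinTable
    counts: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        n = len(self.bins)
        if c.shape != (n, n):
            raise ValueError(
                f"matrix shape {c.shape} does not match {n} bins"
            )
        if (c < 0).any():
            raise ValueError("contact counts must be nonnegative")
        if not np.allclose(c, c.T, atol=SYMMETRY_TOL, rtol=0):
            raise ValueError("contact matrix is not symmetric")
        self.counts = c

    @property
    def n(self) -> int:
        return len(self.bins)

    def log2p1(self) -> np.ndarray:
        """log2(counts + 1); the pseudocount handles the zeros that a
        sparse Hi-C map always contains."""
        return np.log2(self.counts + 1.0)


@dataclass
class SignalTrack:
    """One value per bin summarising a 1D genomic track.

    kind is one of 'peak_count', 'coverage_fraction', 'mean_value'.
    Missing values (bins with no overlapping record) are NaN and are
    dropped pairwise by downstream statistics.
    """

    bins: BinTable
    values: np.ndarray
    kind: str = "mean_value"
    name: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.bins),):
            raise ValueError("signal length must equal number of bins")
        if self.kind == "coverage_fraction":
            ok = np.isnan(v) | ((v >= 0) & (v <= 1))
            if not ok.all():
                raise ValueError("coverage fractions must lie in [0, 1]")
        self.values = v


# ---------------------------------------------------------------------------
# readers / writers


def read_bin_table(path) -> BinTable:
    df = pd.read_csv(path, sep="\t", header=None, names=BIN_COLUMNS)
    return BinTable(df)


def write_bin_table(bins: BinTable, path) -> None:
    bins.frame.to_csv(path, sep="\t", header=False, index=False)


def read_contact_matrix(path, bins: BinTable, format: str = "triples",
                        normalized: bool = False) -> ContactMatrix:
    """Read a contact matrix in dense-grid or sparse-triple text form.

    Triples are mirrored: a row (i, j, c) sets both (i, j) and (j, i).
    Unlisted cells are zero.
    """
    n = len(bins)
    if format == "dense":
        m = np.loadtxt(path, dtype=float)
        m = np.atleast_2d(m)
        if m.shape != (n, n):
            raise ValueError(f"dense matrix shape {m.shape}, expected {(n, n)}")
        return ContactMatrix(bins, m, normalized=normalized)
    if format == "triples":
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["i", "j", "count"])
        m = np.zeros((n, n))
        i = df["i"].to_numpy(dtype=int)
        j = df["j"].to_numpy(dtype=int)
        if len(i) and (i.min() < 0 or i.max() >= n or j.min() < 0 or j.max() >= n):
            raise ValueError("triple index out of range for bin table")
        c = df["count"].to_numpy(dtype=float)
        m[i, j] = c
        m[j, i] = c
        return ContactMatrix(bins, m, normalized=normalized)
    raise ValueError(f"unknown format {format!r}")


def write_contact_matrix(m: ContactMatrix, path, format: str = "triples") -> None:
    if format == "dense":
        np.savetxt(path, m.counts, delimiter="\t")
        return
    if format == "triples":
        iu, ju = np.nonzero(np.triu(m.counts))
        df = pd.DataFrame({"i": iu, "j": ju, "count": m.counts[iu, ju]})
        df.to_csv(path, sep="\t", header=False, index=False,
                  float_format="%.17g")
        return
    raise ValueError(f"unknown format {format!r}")


def read_bed(path) -> pd.DataFrame:
    """BED3+ records, 0-based half-open; extra columns ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def read_bedgraph(path) -> pd.DataFrame:
    """4-column bedGraph (chrom, start, end, value)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "value"]
    return df


# ---------------------------------------------------------------------------
# ICE normalization


def ice_normalize(m: ContactMatrix, max_iter: int = 200,
                  tol: float = 1e-6) -> tuple[ContactMatrix, np.ndarray]:
    """Iterative correction (ICE) matrix balancing.

    Divides the counts by the outer product of per-bin biases, updated from
    the row marginals, until the coefficient of variation of the nonzero-row
    sums drops below ``tol``.  Bins whose raw marginal is zero are excluded
    from balancing (their bias is NaN and their rows stay zero).  The
    diagonal is retained.

    Returns the balanced matrix (scaled so included row sums equal the mean
    raw marginal of included rows) and the bias vector.
    """
    w = m.counts.copy()
    n = m.n
    marg = w.sum(axis=1)
    included = marg > 0
    if not included.any():
        raise ValueError("cannot balance an all-zero matrix")
    bias = np.ones(n)
    for _ in range(max_iter):
        s = w.sum(axis=1)
        sub = s[included]
        cv = sub.std() / sub.mean()
        if cv < tol:
            break
        d = np.ones(n)
        d[included] = sub / sub.mean()
        w /= np.outer(d, d)
        bias *= d
    bias_out = np.where(included, bias, np.nan)
    out = ContactMatrix(m.bins, w, normalized=True)
    return out, bias_out


# ---------------------------------------------------------------------------
# aggregation


def aggregate_to_intervals(m: ContactMatrix,
                           intervals: pd.DataFrame) -> ContactMatrix:
    """Sum counts over all bin pairs within interval pairs (e.g. TADs).

    ``intervals`` is a BED-like frame of non-overlapping intervals; a bin
    belongs to an interval when its midpoint falls inside it.  Output has
    one bin per interval.
    """
    chroms = m.bins.chroms
    mid = (m.bins.starts + m.bins.ends) // 2
    groups = []
    for row in intervals.itertuples(index=False):
        members = np.flatnonzero(
            (chroms == row.chrom) & (mid >= row.start) & (mid < row.end)
        )
        if len(members) == 0:
            raise ValueError(
                f"interval {row.chrom}:{row.start}-{row.end} covers no bin"
            )
        groups.append(members)
    p = len(groups)
    agg = np.zeros((p, p))
    for a in range(p):
        for b in range(a, p):
            v = m.counts[np.ix_(groups[a], groups[b])].sum()
            agg[a, b] = v
            agg[b, a] = v
    new_bins = BinTable(pd.DataFrame({
        "chrom": intervals["chrom"].to_numpy(),
        "start": intervals["start"].to_numpy(),
        "end": intervals["end"].to_numpy(),
        "index": np.arange(p),
    }))
    return ContactMatrix(new_bins, agg, normalized=m.normalized)


def _bin_lookup(bins: BinTable):
    """Per-chromosome sorted (starts, ends, indices) for interval queries."""
    table = {}
    df = bins.frame
    for chrom, sub in df.groupby("chrom", sort=False):
        table[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                        sub["index"].to_numpy())
    return table


def aggregate_peaks(peaks: pd.DataFrame, bins: BinTable,
                    name: str = "") -> SignalTrack:
    """Count peaks per bin; each peak is assigned to the bin containing its
    midpoint, so every peak is counted exactly once."""
    lookup = _bin_lookup(bins)
    counts = np.zeros(len(bins))
    for row in peaks.itertuples(index=False):
        if row.chrom not in lookup:
            logger.warning("peak chromosome %s absent from bin table; skipped",
                           row.chrom)
            continue
        starts, ends, idx = lookup[row.chrom]
        midpoint = (row.start + row.end) // 2
        pos = np.searchsorted(starts, midpoint, side="right") - 1
        if pos >= 0 and midpoint < ends[pos]:
            counts[idx[pos]] += 1
    return SignalTrack(bins, counts, kind="peak_count", name=name)


def coverage_fraction(intervals: pd.DataFrame, bins: BinTable,
                      name: str = "") -> SignalTrack:
    """Fraction of each bin covered by the union of the intervals."""
    covered = np.zeros(len(bins))
    df = intervals.sort_values(["chrom", "start"], kind="stable")
    lookup = _bin_lookup(bins)
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in lookup:
            logger.warning("interval chromosome %s absent from bin table; "
                           "skipped", chrom)
            continue
        # merge overlapping intervals so double coverage is not double counted
        merged = []
        for s, e in zip(sub["start"], sub["end"]):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts, ends, idx = lookup[chrom]
        for s, e in merged:
            for b in range(len(starts)):
                ov = min(e, ends[b]) - max(s, starts[b])
                if ov > 0:
                    covered[idx[b]] += ov
    frac = covered / bins.lengths()
    return SignalTrack(bins, frac, kind="coverage_fraction", name=name)


def mean_signal(records: pd.DataFrame, bins: BinTable,
                name: str = "") -> SignalTrack:
    """Length-weighted mean of bedGraph values per bin; NaN when nothing
    overlaps a bin."""
    num = np.zeros(len(bins))
    den = np.zeros(len(bins))
    lookup = _bin_lookup(bins)
    for row in records.itertuples(index=False):
        if row.chrom not in lookup:
            continue
        starts, ends, idx = lookup[row.chrom]
        for b in range(len(starts)):
            ov = min(row.end, ends[b]) - max(row.start, starts[b])
            if ov > 0:
                num[idx[b]] += ov * row.value
                den[idx[b]] += ov
    with np.errstate(invalid="ignore"):
        values = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return SignalTrack(bins, values, kind="mean_value", name=name)


def make_bins(chrom_sizes: dict[str, int], bin_size: int) -> BinTable:
    """Tile chromosomes with fixed-size bins (last bin may be short)."""
    rows = []
    idx = 0
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_size):
            rows.append((chrom, start, min(start + bin_size, size), idx))
            idx += 1
    return BinTable(pd.DataFrame(rows, columns=BIN_COLUMNS))
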