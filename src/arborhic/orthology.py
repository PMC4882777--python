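"""One-to-one orthologous-bin mapping between two genomes.

Two evidence sources are supported: UCSC chain files (whole-genome
alignment) and 12-column tabular alignment summaries in the blastn
``-outfmt 6`` layout.  Both are reduced to an aligned-base-pair table
A(h_bin, m_bin); reciprocal-best-hit selection then yields a one-to-one
map, optionally filtered so each retained pair has at least ``frac * r``
aligned bases (``r`` being the bin size), and maps from the two sources
can be intersected for a stringent final set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bins_io import BinTable

logger = logging.getLogger(__name__)


@dataclass
class AlignedBpTable:
    """Sparse (h_bin, m_bin) -> aligned base pairs."""

    cells: dict[tuple[int, int], float] = field(default_factory=dict)

    def add(self, h: int, m: int, bp: float) -> None:
        if bp <= 0:
            return
        self.cells[(h, m)] = self.cells.get((h, m), 0.0) + bp

    def total(self) -> float:
        return sum(self.cells.values())

    def __len__(self) -> int:
        return len(self.cells)


@dataclass
class OrthologyMap:
    """One-to-one list of (h_bin, m_bin) pairs."""

    pairs: list[tuple[int, int]]
    source: str = ""

    def __post_init__(self):
        hs = [h for h, _ in self.pairs]
        ms = [m for _, m in self.pairs]
        if len(set(hs)) != len(hs) or len(set(ms)) != len(ms):
            raise ValueError("orthology map must be one-to-one")
        self.pairs = sorted(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["h_bin", "m_bin"])


# ---------------------------------------------------------------------------
# bin coordinate helpers


def _bin_index_map(bins: BinTable):
    """chrom -> (starts, ends, indices) arrays for locating positions."""
    out = {}
    for chrom, sub in bins.frame.groupby("chrom", sort=False):
        out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy(),
                      sub["index"].to_numpy())
    return out


def _split_by_bins(chrom_bins, chrom: str, start: int, end: int):
    """Split [start, end) on the chromosome's bin grid.

    Yields (piece_start, piece_end, bin_index); positions outside every
    bin are dropped.
    """
    if chrom not in chrom_bins:
        return
    starts, ends, idx = chrom_bins[chrom]
    b = max(0, int(np.searchsorted(starts, start, side="right")) - 1)
    for i in range(b, len(starts)):
        if starts[i] >= end:
            break
        lo = max(start, starts[i])
        hi = min(end, ends[i])
        if hi > lo:
            yield lo, hi, int(idx[i])


def _credit_block(table: AlignedBpTable, chrom_bins_h, chrom_bins_m,
                  h_chrom: str, h_start: int,
                  m_chrom: str, m_start: int, m_reverse: bool,
                  size: int) -> None:
    """Credit one ungapped colinear block of ``size`` bases to every
    (h_bin, m_bin) cell it overlaps, splitting at bin boundaries of both
    genomes.  ``m_reverse`` maps h offset o to m position
    m_start + size - 1 - o (reverse-strand chain blocks after coordinate
    conversion)."""
    for h_lo, h_hi, h_bin in _split_by_bins(chrom_bins_h, h_chrom,
                                            h_start, h_start + size):
        o_lo = h_lo - h_start
        o_hi = h_hi - h_start
        if not m_reverse:
            seg_start, seg_end = m_start + o_lo, m_start + o_hi
            for mm_lo, mm_hi, m_bin in _split_by_bins(chrom_bins_m, m_chrom,
                                                      seg_start, seg_end):
                table.add(h_bin, m_bin, mm_hi - mm_lo)
        else:
            seg_start = m_start + size - o_hi
            seg_end = m_start + size - o_lo
            for mm_lo, mm_hi, m_bin in _split_by_bins(chrom_bins_m, m_chrom,
                                                      seg_start, seg_end):
                table.add(h_bin, m_bin, mm_hi - mm_lo)


# ---------------------------------------------------------------------------
# chain files


def parse_chain(path):
    """Iterate UCSC chain records.

    Yields dicts with target (t*) and query (q*) fields plus a list of
    (size, dt, dq) block tuples; query coordinates on '-' strand are kept
    as stated (reverse-complement coordinates) and converted by the
    aggregator.
    """
    with open(path) as fh:
        header = None
        blocks = []
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("chain"):
                if header is not None:
                    yield {**header, "blocks": blocks}
                parts = line.split()
                if len(parts) < 12:
                    raise ValueError(f"malformed chain header: {line!r}")
                header = {
                    "score": float(parts[1]),
                    "t_name": parts[2], "t_size": int(parts[3]),
                    "t_strand": parts[4],
                    "t_start": int(parts[5]), "t_end": int(parts[6]),
                    "q_name": parts[7], "q_size": int(parts[8]),
                    "q_strand": parts[9],
                    "q_start": int(parts[10]), "q_end": int(parts[11]),
                }
                if header["t_strand"] != "+":
                    raise ValueError("chain target strand must be '+'")
                blocks = []
            else:
                parts = line.split()
                if len(parts) == 1:
                    blocks.append((int(parts[0]), 0, 0))
                elif len(parts) == 3:
                    blocks.append((int(parts[0]), int(parts[1]),
                                   int(parts[2])))
                else:
                    raise ValueError(f"malformed chain block line: {line!r}")
        if header is not None:
            yield {**header, "blocks": blocks}


def aggregate_chain(path, bins_h: BinTable, bins_m: BinTable) -> AlignedBpTable:
    """Sum aligned block lengths from a chain file into (h_bin, m_bin)
    cells, splitting blocks proportionally at bin boundaries.

    The chain target is the h genome and the query the m genome.  Query
    blocks on the '-' strand are converted to forward coordinates per the
    chain spec (pos_forward = q_size - pos_reverse).
    """
    table = AlignedBpTable()
    chrom_h = _bin_index_map(bins_h)
    chrom_m = _bin_index_map(bins_m)
    for chain in parse_chain(path):
        t_pos = chain["t_start"]
        q_pos = chain["q_start"]
        reverse = chain["q_strand"] == "-"
        for size, dt, dq in chain["blocks"]:
            if reverse:
                # block covers reverse coords [q_pos, q_pos+size);
                # forward-strand start:
                fwd_start = chain["q_size"] - (q_pos + size)
            else:
                fwd_start = q_pos
            _credit_block(table, chrom_h, chrom_m,
                          chain["t_name"], t_pos,
                          chain["q_name"], fwd_start, reverse, size)
            t_pos += size + dt
            q_pos += size + dq
    return table


# ---------------------------------------------------------------------------
# tabular alignments (blastn -outfmt 6 layout)

TAB_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def aggregate_alignment_tab(path, bins_h: BinTable, bins_m: BinTable,
                            max_evalue: float = 1e-5) -> AlignedBpTable:
    """Credit aligned base pairs from a 12-column alignment table.

    Query coordinates refer to the h genome and subject coordinates to the
    m genome; both are 1-based inclusive.  Hits above ``max_evalue`` are
    skipped.  Each hit is treated as one colinear block whose aligned
    length is the query span; subject spans with sstart > send indicate a
    reverse-strand hit.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=TAB_COLUMNS,
                     comment="#")
    table = AlignedBpTable()
    chrom_h = _bin_index_map(bins_h)
    chrom_m = _bin_index_map(bins_m)
    known_h = set(chrom_h)
    known_m = set(chrom_m)
    for row in df.itertuples(index=False):
        if row.evalue > max_evalue:
            continue
        if row.qseqid not in known_h or row.sseqid not in known_m:
            logger.warning("alignment on unknown chromosome (%s, %s) skipped",
                           row.qseqid, row.sseqid)
            continue
        h_start = int(row.qstart) - 1          # to 0-based half-open
        size = int(row.qend) - h_start
        reverse = row.sstart > row.send
        s_lo = int(min(row.sstart, row.send)) - 1
        _credit_block(table, chrom_h, chrom_m, row.qseqid, h_start,
                      row.sseqid, s_lo, reverse, size)
    return table


# ---------------------------------------------------------------------------
# reciprocal best hits and filters


def reciprocal_best(t: AlignedBpTable) -> OrthologyMap:
    """Keep (h, m) iff m is h's best-aligned partner and vice versa; ties
    in aligned bases break to the lower bin index."""
    best_m: dict[int, tuple[float, int]] = {}
    best_h: dict[int, tuple[float, int]] = {}
    for (h, m), bp in sorted(t.cells.items()):
        if h not in best_m or bp > best_m[h][0]:
            best_m[h] = (bp, m)
        elif bp == best_m[h][0] and m < best_m[h][1]:
            logger.warning("aligned-bp tie for h bin %d; keeping lower index", h)
            best_m[h] = (bp, m)
        if m not in best_h or bp > best_h[m][0]:
            best_h[m] = (bp, h)
        elif bp == best_h[m][0] and h < best_h[m][1]:
            logger.warning("aligned-bp tie for m bin %d; keeping lower index", m)
            best_h[m] = (bp, h)
    pairs = [(h, m) for h, (_, m) in best_m.items()
             if best_h[m][1] == h]
    return OrthologyMap(pairs, source="rbh")


def filter_min_fraction(omap: OrthologyMap, t: AlignedBpTable, r: int,
                        frac: float = 0.1) -> OrthologyMap:
    """Drop pairs with fewer than frac*r aligned bases (boundary kept)."""
    threshold = frac * r
    pairs = [(h, m) for h, m in omap.pairs
             if t.cells.get((h, m), 0.0) >= threshold]
    return OrthologyMap(pairs, source=omap.source)


def intersect_maps(a: OrthologyMap, b: OrthologyMap) -> OrthologyMap:
    """Pairs present in both maps."""
    common = sorted(set(a.pairs) & set(b.pairs))
    return OrthologyMap(common, source="intersection")


def write_map(omap: OrthologyMap, path) -> None:
    omap.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_map(path) -> OrthologyMap:
    df = pd.read_csv(path, sep="\t", header=None,
                     usecols=[0, 1], names=["h_bin", "m_bin"])
    return OrthologyMap(list(zip(df["h_bin"].astype(int),
                                 df["m_bin"].astype(int))))
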