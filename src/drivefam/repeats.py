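"""Quantifying degenerate intragenic tandem repeats by wraparound alignment.

Family genes carry two unstable repeat regions: a well-conserved 33-bp unit
near the start of exon 3 and a less-conserved 21-bp unit at the start of
exon 6.  Units are degenerate and the terminal units are routinely
truncated, so exact matching undercounts; instead the region is locally
aligned against the infinitely repeated consensus unit (wraparound dynamic
programming).  The aligned span is the repeat-derived sequence; the path's
crossings of the consensus origin decompose it into full and truncated
units, from which position-frequency matrices are built.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

_STOP, _DIAG, _VERT, _HORIZ = 0, 1, 2, 3


@dataclass(frozen=True)
class RepeatConsensus:
    """A consensus repeat unit (33 bp for exon 3, 21 bp for exon 6)."""

    unit: str
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("empty repeat unit")


@dataclass
class RepeatQuant:
    """Decomposition of a region into repeat-derived units.

    ``unit_intervals`` are half-open (start, end) spans in region
    coordinates; ``unit_paths`` carries the per-base consensus column for
    each interval (used to build PFMs for truncated/gapped units).
    """

    total_bp: int
    n_full_units: int
    first_trunc_len: int
    last_trunc_len: int
    unit_intervals: list[tuple[int, int]] = field(default_factory=list)
    unit_paths: list[list[tuple[int, int]]] = field(default_factory=list)
    score: float = 0.0


def quantify_repeat(region: str, consensus: RepeatConsensus, match: int = 1,
                    mismatch: int = -1, gap: int = -2,
                    min_score: int = 8) -> RepeatQuant:
    """Align a region against the infinitely repeated consensus unit.

    Local alignment with wraparound over the unit columns; returns the
    aligned span (total repeat-derived bp) and its decomposition into unit
    intervals at consensus-origin crossings.  If the best local score falls
    below ``min_score`` the region is called repeat-free (all-zero quant).
    """
    if not region:
        raise ValueError("empty region")
    u = consensus.unit
    n, m = len(region), len(u)
    H = np.zeros((n + 1, m), dtype=np.int64)
    P = np.zeros((n + 1, m), dtype=np.int8)
    for i in range(1, n + 1):
        ri = region[i - 1]
        prev = H[i - 1]
        row = H[i]
        ptr = P[i]
        for j in range(m):
            s = match if ri == u[j] else mismatch
            best, p = 0, _STOP
            d = prev[j - 1] + s  # j-1 wraps to m-1 via python indexing
            if d > best:
                best, p = d, _DIAG
            v = prev[j] + gap
            if v > best:
                best, p = v, _VERT
            row[j] = best
            ptr[j] = p
        # horizontal moves with wraparound: two propagation passes
        for _ in range(2):
            for j in range(m):
                h = row[j - 1] + gap
                if h > row[j]:
                    row[j] = h
                    ptr[j] = _HORIZ

    best_score = int(H.max())
    if best_score < min_score:
        return RepeatQuant(0, 0, 0, 0, score=best_score)
    # deterministic end cell: smallest i, then smallest j among maxima
    i, j = np.argwhere(H == best_score)[0]
    i, j = int(i), int(j)

    # traceback; record (region_pos, consensus_col) for base-consuming steps
    path: list[tuple[int, int]] = []
    while H[i][j] > 0 and P[i][j] != _STOP:
        p = P[i][j]
        if p == _DIAG:
            path.append((i - 1, j))
            i, j = i - 1, (j - 1) % m
        elif p == _VERT:
            path.append((i - 1, -1))  # region base vs gap: no column
            i = i - 1
        else:
            j = (j - 1) % m
    path.reverse()
    if not path:
        return RepeatQuant(0, 0, 0, 0, score=best_score)

    start = path[0][0]
    end = path[-1][0] + 1
    # split into units at diagonal entries to column 0
    units: list[list[tuple[int, int]]] = [[]]
    for pos, col in path:
        if col == 0 and units[-1]:
            units.append([])
        units[-1].append((pos, col))
    intervals = [(seg[0][0], seg[-1][0] + 1) for seg in units]

    def cols(seg):
        return [c for _, c in seg if c >= 0]

    n_full = sum(1 for seg in units
                 if cols(seg) and cols(seg)[0] == 0 and cols(seg)[-1] == m - 1)
    first_cols = cols(units[0])
    last_cols = cols(units[-1])
    first_trunc = (intervals[0][1] - intervals[0][0]) \
        if first_cols and first_cols[0] != 0 else 0
    last_trunc = (intervals[-1][1] - intervals[-1][0]) \
        if len(units) > 1 and last_cols and last_cols[-1] != m - 1 else 0
    return RepeatQuant(
        total_bp=end - start, n_full_units=n_full,
        first_trunc_len=first_trunc, last_trunc_len=last_trunc,
        unit_intervals=intervals, unit_paths=units, score=best_score)


# --- position frequency matrices ---------------------------------------------

_BASE_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


def build_pfm(quant: RepeatQuant, region: str, unit_len: int) -> np.ndarray:
    """Column-normalised 4 x unit_len base-frequency matrix.

    Full units contribute every column; truncated terminal units only the
    columns they cover.  Columns are normalised by their own observation
    counts, so each observed column sums to 1.
    """
    if quant.n_full_units < 1:
        raise ValueError("no full repeat units to build a PFM from")
    counts = np.zeros((4, unit_len))
    for seg in quant.unit_paths:
        for pos, col in seg:
            if col >= 0:
                row = _BASE_ROW.get(region[pos])
                if row is not None:
                    counts[row, col] += 1
    totals = counts.sum(axis=0)
    pfm = np.divide(counts, totals, out=np.zeros_like(counts),
                    where=totals > 0)
    return pfm


def amino_acid_pfm(quant: RepeatQuant, region: str, unit_len: int,
                   frame: int = 0) -> dict[int, dict[str, float]]:
    """Per-codon-column amino-acid frequencies from full units only."""
    from .diversity import translate_codon

    if unit_len % 3:
        raise ValueError("unit length must be divisible by 3 for translation")
    counts: dict[int, dict[str, float]] = {
        c: {} for c in range(unit_len // 3)}
    for seg, (s, e) in zip(quant.unit_paths, quant.unit_intervals):
        cols = [c for _, c in seg if c >= 0]
        if not cols or cols[0] != 0 or cols[-1] != unit_len - 1 \
                or e - s != unit_len:
            continue  # full, ungapped units only
        unit_seq = region[s:e]
        for c in range(unit_len // 3):
            codon = unit_seq[3 * c + frame:3 * c + frame + 3]
            if len(codon) == 3:
                aa = translate_codon(codon)
                counts[c][aa] = counts[c].get(aa, 0) + 1
    for c, d in counts.items():
        tot = sum(d.values())
        if tot:
            counts[c] = {aa: v / tot for aa, v in d.items()}
    return counts


def consensus_from_regions(regions: Sequence[str], unit_len: int
                           ) -> RepeatConsensus:
    """Majority-base consensus unit from exemplar repeat regions.

    Regions are assumed to start on a unit boundary (as the exemplar gene
    models define them); only whole units are stacked.  Ties go to the
    alphabetically first base.
    """
    counts = np.zeros((4, unit_len))
    for r in regions:
        for k in range(len(r) // unit_len):
            unit = r[k * unit_len:(k + 1) * unit_len]
            for col, b in enumerate(unit):
                row = _BASE_ROW.get(b)
                if row is not None:
                    counts[row, col] += 1
    if not counts.sum():
        raise ValueError("no unit-length sequence in exemplar regions")
    bases = "ACGT"
    unit = "".join(bases[int(np.argmax(counts[:, c]))]
                   for c in range(unit_len))
    return RepeatConsensus(unit, name=f"consensus{unit_len}")
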