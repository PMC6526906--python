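"""Locating family loci and calling gene copy number from mate-pair pileups.

The procedure mirrors the mate-pair strategy for repetitive gene families:

1. classify read pairs against a FASTA panel of family genes by shared
   k-mers (tolerant of the high divergence between paralogs);
2. take the *partner* reads -- the mates that did not match the panel --
   and place them on the reference with a unique-k-mer-anchor mapper,
   discarding ambiguous (repeat-derived) reads;
3. call maximal >=min_depth runs of partner coverage ("pileups");
4. pair adjacent pileups into loci and read the per-locus gene copy number
   off the widest flanking pileup via a width calibration.

For uniform inserts on [a, b], read length L and a locus whose
panel-matching span is S, the expected pileup width is S + (b - a) + 2L;
copy-number decision boundaries sit at midpoints between the widths
expected for 1, 2 and 3 tandem genes.  Loci embedded in larger segmental
duplications are caught separately by a 2x coverage scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import Interval, SeqRecord, revcomp

log = logging.getLogger("drivefam")

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def encode_bases(seq: str) -> np.ndarray:
    """2-bit base codes (255 for non-ACGT)."""
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all k-mers of ``seq`` plus a validity mask.

    Positions whose window contains a non-ACGT base are invalid.
    """
    c = encode_bases(seq)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, bool)
    codes = np.zeros(n, np.int64)
    for j in range(k):
        codes = (codes << 2) | c[j:j + n].astype(np.int64)
    bad = (c > 3).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[k:] - cum[:-k]) == 0
    return codes, valid


def kmer_set(seqs: Iterable[str], k: int, both_strands: bool = True) -> np.ndarray:
    """Sorted unique k-mer codes over sequences (optionally both strands)."""
    chunks = []
    for s in seqs:
        for t in ((s, revcomp(s)) if both_strands else (s,)):
            codes, valid = kmer_codes(t, k)
            chunks.append(codes[valid])
    if not chunks:
        return np.empty(0, np.int64)
    return np.unique(np.concatenate(chunks))


# --- read-pair classification ----------------------------------------------

@dataclass
class ReadPairClass:
    pair_id: str
    r1_is_family: bool
    r2_is_family: bool
    partner_reads: list[SeqRecord] = field(default_factory=list)


def _match_fractions(seqs: list[str], panel: np.ndarray, k: int) -> np.ndarray:
    """Fraction of each read's valid k-mers found in the panel k-mer set."""
    out = np.zeros(len(seqs))
    if panel.size == 0:
        return out
    lens = {len(s) for s in seqs}
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for L, idx in by_len.items():
        n = L - k + 1
        if n <= 0:
            continue
        mat = np.zeros((len(idx), L), np.uint8)
        for row, i in enumerate(idx):
            mat[row] = encode_bases(seqs[i])
        codes = np.zeros((len(idx), n), np.int64)
        for j in range(k):
            codes = (codes << 2) | mat[:, j:j + n].astype(np.int64)
        bad = (mat > 3).astype(np.int64)
        cum = np.concatenate([np.zeros((len(idx), 1), np.int64),
                              np.cumsum(bad, axis=1)], axis=1)
        valid = (cum[:, k:] - cum[:, :-k]) == 0
        hit = np.isin(codes, panel) & valid
        nvalid = valid.sum(axis=1)
        frac = np.divide(hit.sum(axis=1), nvalid,
                         out=np.zeros(len(idx)), where=nvalid > 0)
        out[idx] = frac
    return out


def match_reads_to_family(pairs: Sequence[tuple[SeqRecord, SeqRecord]],
                          panel: Sequence[SeqRecord], k: int = 15,
                          min_kmer_frac: float = 0.05) -> list[ReadPairClass]:
    """Classify read pairs against the family panel by shared k-mers.

    A read matches when at least ``min_kmer_frac`` of its k-mers occur in
    the panel k-mer set (both strands).  Pairs with at least one matching
    read are retained; their non-matching mates become partner reads.
    """
    if not (11 <= k <= 31 and k % 2 == 1):
        raise ValueError("k must be odd and in [11, 31]")
    if not panel:
        raise ValueError("empty family panel")
    panel_arr = kmer_set([p.sequence for p in panel], k)
    r1 = [a.sequence for a, _ in pairs]
    r2 = [b.sequence for _, b in pairs]
    f1 = _match_fractions(r1, panel_arr, k) >= min_kmer_frac
    f2 = _match_fractions(r2, panel_arr, k) >= min_kmer_frac
    out = []
    for i, (a, b) in enumerate(pairs):
        if not (f1[i] or f2[i]):
            continue
        partners = []
        if not f1[i]:
            partners.append(a)
        if not f2[i]:
            partners.append(b)
        out.append(ReadPairClass(
            pair_id=a.id[:-2] if a.id.endswith("/1") else a.id,
            r1_is_family=bool(f1[i]), r2_is_family=bool(f2[i]),
            partner_reads=partners))
    return out


# --- unique-anchor read placement -------------------------------------------

_DUP = -1


class ReferenceIndex:
    """Unique-k-mer anchor index of a reference for exact-ish read placement.

    A read is placed at a position iff its anchor k-mers that are unique in
    the reference agree on a single placement and the full read matches
    there with at most ``max_mismatches`` substitutions; reads whose
    anchors support multiple placements (repeats) are discarded.
    """

    def __init__(self, reference: SeqRecord | str, k: int = 21):
        if isinstance(reference, SeqRecord):
            self.chrom, self.seq = reference.id, reference.sequence
        else:
            self.chrom, self.seq = "genome", reference
        self.k = k
        codes, valid = kmer_codes(self.seq, k)
        index: dict[int, int] = {}
        for pos in np.flatnonzero(valid):
            code = int(codes[pos])
            if code in index:
                index[code] = _DUP
            else:
                index[code] = int(pos)
        self.index = index

    def place(self, read: str, max_mismatches: int = 2,
              anchor_step: int = 10) -> Optional[tuple[int, str]]:
        """Place a read; returns (position, strand) or None."""
        k = self.k
        L = len(read)
        if L < k:
            return None
        candidates: set[tuple[int, str]] = set()
        saw_dup = False
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            codes, valid = kmer_codes(oriented, k)
            offsets = list(range(0, L - k, anchor_step)) + [L - k]
            for off in offsets:
                if not valid[off]:
                    continue
                hit = self.index.get(int(codes[off]))
                if hit is None:
                    continue
                if hit == _DUP:
                    saw_dup = True
                    continue
                start = hit - off
                if 0 <= start <= len(self.seq) - L:
                    candidates.add((start, strand))
        if len(candidates) != 1:
            if len(candidates) > 1 or saw_dup:
                return None  # ambiguous / repeat-derived
            return None
        (start, strand), = candidates
        oriented = read if strand == "+" else revcomp(read)
        mism = sum(1 for a, b in zip(oriented, self.seq[start:start + L])
                   if a != b)
        if mism > max_mismatches:
            return None
        return start, strand


@dataclass
class CoverageTrack:
    """Per-base read coverage per chromosome."""

    cov: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def zeros(cls, chrom_lengths: dict[str, int]) -> "CoverageTrack":
        return cls({c: np.zeros(n, np.int32) for c, n in chrom_lengths.items()})

    def add_span(self, chrom: str, start: int, end: int) -> None:
        a = self.cov[chrom]
        a[start:end] += 1

    def total_covered_bases(self) -> int:
        return int(sum(a.sum() for a in self.cov.values()))


def map_partner_reads(reads: Sequence[SeqRecord],
                      reference: SeqRecord | str | ReferenceIndex,
                      k: int = 21, max_mismatches: int = 2
                      ) -> tuple[CoverageTrack, dict[str, tuple[int, str]]]:
    """Place reads with the unique-anchor mapper and build a coverage track.

    Returns the track and the placements (read id -> (start, strand)).
    Ambiguous and unplaceable reads are dropped; a warning is logged if
    nothing places.
    """
    idx = reference if isinstance(reference, ReferenceIndex) \
        else ReferenceIndex(reference, k=k)
    track = CoverageTrack.zeros({idx.chrom: len(idx.seq)})
    diff = np.zeros(len(idx.seq) + 1, np.int64)
    placements: dict[str, tuple[int, str]] = {}
    for r in reads:
        hit = idx.place(r.sequence, max_mismatches=max_mismatches)
        if hit is None:
            continue
        start, strand = hit
        placements[r.id] = (start, strand)
        diff[start] += 1
        diff[start + len(r.sequence)] -= 1
    track.cov[idx.chrom] = np.cumsum(diff[:-1]).astype(np.int32)
    if not placements:
        log.warning("no reads placed on the reference")
    return track, placements


def read_sam_coverage(sam_path: str, chrom_lengths: Optional[dict[str, int]]
                      = None) -> CoverageTrack:
    """Coverage track from a SAM file (real-data input path)."""
    import pysam

    with pysam.AlignmentFile(sam_path, "r") as sam:
        lengths = chrom_lengths or dict(zip(sam.references, sam.lengths))
        track = CoverageTrack.zeros(lengths)
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name not in track.cov:
                continue
            track.add_span(aln.reference_name, aln.reference_start,
                           aln.reference_end)
    return track


# --- pileups and loci --------------------------------------------------------

@dataclass
class Pileup:
    interval: Interval
    max_depth: int
    mean_depth: float

    @property
    def width(self) -> int:
        return len(self.interval)


def _threshold_runs(a: np.ndarray, min_depth: int, merge_gap: int
                    ) -> list[list[int]]:
    mask = np.concatenate([[False], a >= min_depth, [False]])
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    merged: list[list[int]] = []
    for s, e in zip(edges[::2], edges[1::2]):
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    return merged


def call_pileups(track: CoverageTrack, min_depth: int = 3,
                 merge_gap: int = 200,
                 extend_to_support: bool = True) -> list[Pileup]:
    """Maximal runs of coverage >= min_depth, merging runs < merge_gap apart.

    With ``extend_to_support`` (the default) each detected run is widened to
    the contiguous coverage>=1 cluster containing it (still bridging gaps
    below ``merge_gap``): min_depth acts as the detection threshold while
    the reported width reflects the full read support of the mound, which
    is the quantity the analytic width model S + (b - a) + 2L predicts.
    Thresholded-run boundaries alone would systematically undershoot it by
    the edge taper.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    out = []
    for chrom in sorted(track.cov):
        a = track.cov[chrom]
        runs = _threshold_runs(a, min_depth, merge_gap)
        if extend_to_support and min_depth > 1:
            support = _threshold_runs(a, 1, merge_gap)
            kept = []
            for s1, e1 in support:
                if any(s1 <= s and e <= e1 for s, e in runs):
                    kept.append([s1, e1])
            runs = kept
        for s, e in runs:
            seg = a[s:e]
            out.append(Pileup(Interval(chrom, s, e, "pileup"),
                              int(seg.max()), float(seg.mean())))
    return out


@dataclass
class CopyNumberCalibration:
    """Expected pileup width per tandem gene count, with midpoint boundaries.

    ``anchors`` are the expected widths for 1, 2 and 3 genes; a width below
    half the one-gene anchor is called as zero genes, and widths above
    ``flag_width`` are capped at 3 with a flag (wider tandem arrays exceed
    the mate-pair insert and cannot be resolved).
    """

    anchors: tuple[float, float, float]
    flag_width: Optional[float] = None

    def __post_init__(self) -> None:
        w1, w2, w3 = self.anchors
        if not (0 < w1 < w2 < w3):
            raise ValueError("calibration anchors must be increasing")
        if self.flag_width is None:
            self.flag_width = w3 + (w3 - w2) / 2

    @property
    def boundaries(self) -> tuple[float, float, float]:
        w1, w2, w3 = self.anchors
        return (w1 / 2, (w1 + w2) / 2, (w2 + w3) / 2)

    @classmethod
    def paper_default(cls) -> "CopyNumberCalibration":
        """Anchors as printed for the real mate-pair dataset (~2.2/4.4/7.5 kb)."""
        return cls((2200.0, 4400.0, 7500.0))

    @classmethod
    def from_mate_pair_params(cls, insert_min: int, insert_max: int,
                              read_len: int, gene_len: float = 1200.0,
                              spacer_len: float = 350.0
                              ) -> "CopyNumberCalibration":
        """Analytic anchors W(n) = S(n) + (b - a) + 2L for tandem arrays.

        S(n) is the panel-matching span of n tandem genes separated by
        ``spacer_len`` (the inter-gene LTR).
        """
        spread = insert_max - insert_min
        anchors = tuple(
            n * gene_len + (n - 1) * spacer_len + spread + 2 * read_len
            for n in (1, 2, 3))
        return cls(anchors)  # type: ignore[arg-type]

    def recalibrated(self, control_widths: Sequence[float]
                     ) -> "CopyNumberCalibration":
        """Rescale anchors so W(1) matches measured single-gene control loci."""
        if not control_widths:
            raise ValueError("no control widths supplied")
        scale = float(np.mean(control_widths)) / self.anchors[0]
        return CopyNumberCalibration(tuple(a * scale for a in self.anchors))

    def estimate(self, width: float) -> tuple[int, bool]:
        """Copy number for a widest-pileup width; bool flags possible >3."""
        if width < 0:
            raise ValueError("negative pileup width")
        b0, b1, b2 = self.boundaries
        if width < b0:
            return 0, False
        if width < b1:
            return 1, False
        if width < b2:
            return 2, False
        return 3, width > self.flag_width


def estimate_copy_number(widest_width: float,
                         calibration: CopyNumberCalibration) -> int:
    n, _ = calibration.estimate(widest_width)
    return n


@dataclass
class LocusCall:
    """A called family locus: the gap between a pair of flanking pileups."""

    interval: Interval
    left_pileup: Optional[Pileup]
    right_pileup: Optional[Pileup]
    flags: set[str] = field(default_factory=set)
    copy_number: Optional[int] = None

    @property
    def widest_width(self) -> int:
        return max((p.width for p in (self.left_pileup, self.right_pileup)
                    if p is not None), default=0)


def call_loci(pileups: Sequence[Pileup], max_pair_span: int = 6000,
              calibration: Optional[CopyNumberCalibration] = None,
              asym_delta: int = 500, complicated_delta: int = 1500
              ) -> list[LocusCall]:
    """Pair adjacent pileups into locus calls, greedily left to right.

    Adjacent pileups whose inner gap is below ``max_pair_span`` flank one
    locus; leftover pileups become single_flank calls.  Flank widths
    disagreeing by more than ``complicated_delta`` raise the complicated
    flag (mirrors manually flagged misleading patterns).
    """
    pileups = sorted(pileups, key=lambda p: (p.interval.chrom, p.interval.start))
    calls: list[LocusCall] = []
    i = 0
    while i < len(pileups):
        p = pileups[i]
        q = pileups[i + 1] if i + 1 < len(pileups) else None
        if (q is not None and q.interval.chrom == p.interval.chrom
                and 0 < q.interval.start - p.interval.end < max_pair_span):
            gap = Interval(p.interval.chrom, p.interval.end, q.interval.start,
                           f"locus{len(calls):02d}")
            delta = abs(p.width - q.width)
            flags = {"symmetric"} if delta <= asym_delta else {"asymmetric"}
            if delta > complicated_delta:
                flags.add("complicated")
            if (i + 2 < len(pileups)
                    and pileups[i + 2].interval.chrom == p.interval.chrom
                    and pileups[i + 2].interval.start - p.interval.end
                    < max_pair_span):
                # a second right-flank candidate within pairing range of the
                # same left pileup: the locus pattern is crowded
                flags.add("complicated")
            calls.append(LocusCall(gap, p, q, flags))
            i += 2
        else:
            calls.append(LocusCall(p.interval, p, None, {"single_flank"}))
            i += 1
    if calibration is not None:
        for c in calls:
            n, over = calibration.estimate(c.widest_width)
            c.copy_number = n
            if over:
                c.flags.add("gt3_possible")
    return calls


# --- coverage-based duplication detection ------------------------------------

def detect_duplicated_regions(track: CoverageTrack, window: int = 1000,
                              family_loci: Sequence[Interval] = (),
                              fold: float = 1.75
                              ) -> tuple[list[Interval], list[Interval]]:
    """Find regions whose median coverage is ~2x the genome median.

    A single extra copy doubles expected coverage; the decision threshold
    ``fold`` sits below 2.0 so that sampling noise and mapping losses at
    junction/repeat positions inside the duplicated copy do not mask true
    duplications.  Windows are merged into regions; returns (regions
    overlapping a family locus, all regions).  Raises on an all-zero track.
    """
    if window < 1000:
        raise ValueError("window must be >= 1 kb")
    allcov = np.concatenate([a for a in track.cov.values()])
    if allcov.max() == 0:
        raise ValueError("zero-coverage genome")
    genome_median = float(np.median(allcov))
    all_regions: list[Interval] = []
    for chrom in sorted(track.cov):
        a = track.cov[chrom]
        nwin = len(a) // window
        if nwin == 0:
            continue
        med = np.median(a[:nwin * window].reshape(nwin, window), axis=1)
        hot = med >= fold * genome_median
        start = None
        for w in range(nwin + 1):
            if w < nwin and hot[w]:
                if start is None:
                    start = w
            elif start is not None:
                all_regions.append(Interval(chrom, start * window, w * window,
                                            "dup"))
                start = None
    fam = [r for r in all_regions
           if any(r.overlaps(loc) for loc in family_loci)]
    return fam, all_regions
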