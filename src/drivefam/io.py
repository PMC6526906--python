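"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere.  Conversion to and
from 1-based closed coordinates happens only at the GFF3 boundary.  FASTA and
FASTQ parsing is delegated to Biopython; newick parsing to dendropy.  Records
are normalised into the small dataclasses below so downstream modules never
depend on a third-party record type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

log = logging.getLogger("drivefam")

VALID_BASES = frozenset("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class SeqRecord:
    """A named DNA sequence with optional per-base Phred quality scores."""

    id: str
    sequence: str
    description: str = ""
    quality: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "Interval":
        return Interval(self.chrom, self.start + offset, self.end + offset,
                        self.name, self.strand)


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _validate_sequence(rec_id: str, seq: str, path: Path) -> str:
    """Uppercase a sequence and reject non-{A,C,G,T,N} characters.

    On failure, rescans the file to report the 1-based line number of the
    first offending character.
    """
    upper = seq.upper()
    bad = set(upper) - VALID_BASES
    if bad:
        lineno = _find_bad_line(path, bad)
        raise ParseError(
            f"{path}:{lineno}: non-IUPAC character(s) {sorted(bad)} "
            f"in record {rec_id!r} (only A/C/G/T/N accepted)"
        )
    if upper != seq:
        log.info("record %s: lowercase bases uppercased on read", rec_id)
    return upper


def _find_bad_line(path: Path, bad: set[str]) -> int:
    bad_any = {c for b in bad for c in (b.upper(), b.lower())}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith((">", "@", "+")):
                continue
            if set(line.strip()) & bad_any:
                return i
    return 0


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into SeqRecords; sequences are uppercased.

    Raises ParseError (with a line number) on malformed headers or
    non-IUPAC characters.  An empty file yields an empty list.
    """
    path = Path(path)
    out: list[SeqRecord] = []
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ParseError(f"{path}:1: expected FASTA header starting with '>'")
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _validate_sequence(rec.id, str(rec.seq), path)
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append(SeqRecord(id=rec.id, sequence=seq, description=rec.description))
    return out


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    bio = [
        _BioRecord(Seq(r.sequence), id=r.id,
                   description=r.description if r.description != r.id else "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write FASTQ with Sanger (Phred+33) qualities; default quality 40."""
    with open(path, "w") as fh:
        for r in records:
            qual = r.quality if r.quality is not None else [40] * len(r.sequence)
            qline = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qline}\n")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    path = Path(path)
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            SeqRecord(
                id=rec.id,
                sequence=_validate_sequence(rec.id, str(rec.seq), path),
                description=rec.description,
                quality=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def _strip_mate_suffix(read_id: str) -> str:
    if read_id.endswith(("/1", "/2")):
        return read_id[:-2]
    return read_id


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path
                     ) -> list[tuple[SeqRecord, SeqRecord]]:
    """Read two FASTQ files of mated reads, paired by order.

    Read ids stripped of their /1 and /2 suffixes must agree pairwise;
    a record-count mismatch between the files is an error.
    """
    r1 = read_fastq(path_r1)
    r2 = read_fastq(path_r2)
    if len(r1) != len(r2):
        raise ParseError(
            f"mate files differ in record count: {len(r1)} vs {len(r2)}"
        )
    pairs = []
    for a, b in zip(r1, r2):
        ka, kb = _strip_mate_suffix(a.id), _strip_mate_suffix(b.id)
        if ka != kb:
            raise ParseError(f"mate id mismatch: {a.id!r} vs {b.id!r}")
        pairs.append((a, b))
    return pairs


# --- BED / GFF3 ------------------------------------------------------------

def read_bed(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 lines as 0-based half-open Intervals."""
    path = Path(path)
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{i}: BED line has fewer than 3 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer BED coordinate") from exc
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 else "."
            try:
                out.append(Interval(f[0], start, end, name, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def read_gff3(path: str | Path, feature_types: Optional[set[str]] = None
              ) -> list[Interval]:
    """Read GFF3 features as Intervals, converting 1-based closed coordinates
    to the internal 0-based half-open convention (start-1, end).

    The returned Interval name carries the ID attribute when present, else
    the feature type.  Optionally restrict to a set of feature types.
    """
    path = Path(path)
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ParseError(f"{path}:{i}: GFF3 line has fewer than 8 fields")
            ftype = f[2]
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start1, end1 = int(f[3]), int(f[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{i}: non-integer GFF3 coordinate") from exc
            start, end = start1 - 1, end1
            if start >= end:
                raise ParseError(
                    f"{path}:{i}: start >= end after coordinate conversion"
                )
            name = ftype
            if len(f) > 8:
                for kv in f[8].split(";"):
                    if kv.startswith("ID="):
                        name = kv[3:]
                        break
            strand = f[6] if f[6] in ("+", "-") else "."
            out.append(Interval(f[0], start, end, name, strand))
    return out


def write_gff3(intervals: Iterable[tuple[Interval, str, dict]], path: str | Path,
               source: str = "drivefam") -> None:
    """Write (Interval, feature_type, attributes) triples as GFF3 (1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, ftype, attrs in intervals:
            attrs = dict(attrs)
            attrs.setdefault("ID", iv.name)
            astr = ";".join(f"{k}={v}" for k, v in attrs.items())
            strand = iv.strand if iv.strand in ("+", "-") else "."
            fh.write(
                f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{strand}\t.\t{astr}\n"
            )


# --- newick ----------------------------------------------------------------

def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a newick string into a dendropy Tree.

    Missing branch lengths default to 0.  Unbalanced parentheses raise
    ParseError.
    """
    if newick.count("(") != newick.count(")"):
        raise ParseError("unbalanced parentheses in newick string")
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:  # dendropy raises several parse exception types
        raise ParseError(f"newick parse failure: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    return tree


def leaf_names(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}


# --- configuration ----------------------------------------------------------

#: top-level config keys the pipeline understands, with value type
CONFIG_SCHEMA: dict[str, type] = {
    "seed": int,
    "out_dir": str,
    "family": dict,
    "mate_pairs": dict,
    "discovery": dict,
    "assembly": dict,
    "stages": list,
}


def load_config(path: str | Path) -> dict:
    """Load and validate a YAML pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config root must be a mapping")
    for key, val in cfg.items():
        if key not in CONFIG_SCHEMA:
            raise ParseError(f"{path}: unknown config key {key!r}")
        if not isinstance(val, CONFIG_SCHEMA[key]):
            raise ParseError(
                f"{path}: config key {key!r} must be {CONFIG_SCHEMA[key].__name__}"
            )
    return cfg
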