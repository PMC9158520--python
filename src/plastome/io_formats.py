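"""Readers/writers for the external formats the pipeline touches.

Coordinate conventions used throughout the package:

* All internal coordinates are 0-based, half-open ``[start, end)``.
  GenBank's 1-based inclusive locations are converted on read.
* Genomes are circular unless stated otherwise.  A feature that spans the
  origin of a *rotated* working copy may carry ``end > len(seq)``; the span
  is interpreted modulo the genome length and is never split into two
  features.
* Nucleotide ambiguity codes other than ``N`` are mapped to ``N`` with a
  warning; downstream statistics treat ``N`` like a gap (invalid).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AnnotatedGenome",
    "Feature",
    "AlignmentMatrix",
    "FormatError",
    "AlignmentError",
    "read_genbank",
    "read_fasta",
    "write_fasta",
    "read_alignment",
    "read_newick",
    "write_regions",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_DNA = frozenset("ACGTN")
_FEATURE_KINDS = {"gene": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "CDS": "CDS"}


class FormatError(ValueError):
    """A file does not conform to the expected external format."""


class AlignmentError(FormatError):
    """An alignment is ragged or otherwise malformed."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def _clean_dna(seq: str, context: str = "") -> str:
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= _VALID_DNA:
        bad = sorted(set(seq) - _VALID_DNA)
        warnings.warn(
            f"ambiguity codes {bad} mapped to N{' in ' + context if context else ''}"
        )
        seq = re.sub("[^ACGTN]", "N", seq)
    return seq


@dataclass
class Feature:
    """A gene-level annotation on a genome.

    ``intervals`` is an ordered list of 0-based half-open ``(start, end)``
    pairs (multi-exon features keep one pair per exon).  ``kind`` is one of
    ``gene``, ``tRNA``, ``rRNA``, ``CDS`` or ``pseudogene``.
    """

    name: str
    kind: str
    strand: str
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"feature {self.name}: empty interval list")
        for s, e in self.intervals:
            if s >= e:
                raise ValueError(f"feature {self.name}: empty interval [{s},{e})")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name}: bad strand {self.strand!r}")

    @property
    def start(self) -> int:
        return min(s for s, _ in self.intervals)

    @property
    def end(self) -> int:
        return max(e for _, e in self.intervals)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)


@dataclass
class AnnotatedGenome:
    """A (usually circular) plastid genome with its gene features."""

    id: str
    seq: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"genome {self.id}: empty sequence")
        self.seq = _clean_dna(self.seq, context=self.id)

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; ``end`` may exceed ``len`` on a
        circular genome (wraps past the origin)."""
        n = len(self.seq)
        if end <= n:
            return self.seq[start:end]
        if not self.circular:
            raise IndexError("interval beyond the end of a linear genome")
        return (self.seq + self.seq)[start:end]

    def feature_seq(self, feature: Feature) -> str:
        """Biological sequence of a feature.  Intervals are stored 5'->3'
        with respect to the feature (minus-strand compound locations keep
        the order GenBank parsers emit), so each part is complemented
        individually and the parts concatenated in order."""
        if feature.strand == "-":
            return "".join(revcomp(self.subseq(s, e))
                           for s, e in feature.intervals)
        return "".join(self.subseq(s, e) for s, e in feature.intervals)

    def rotate(self, offset: int) -> "AnnotatedGenome":
        """Return a copy with the origin moved to ``offset`` (circular only).

        Features are shifted accordingly; a feature that ends up spanning
        the new origin keeps a single interval with ``end > len(seq)``.
        """
        n = len(self.seq)
        offset %= n
        if offset == 0:
            return AnnotatedGenome(self.id, self.seq, self.circular,
                                   [Feature(f.name, f.kind, f.strand, list(f.intervals))
                                    for f in self.features])
        if not self.circular:
            raise ValueError("cannot rotate a linear genome")
        seq = self.seq[offset:] + self.seq[:offset]
        feats = []
        for f in self.features:
            ivs = []
            for s, e in f.intervals:
                length = e - s
                s2 = (s - offset) % n
                ivs.append((s2, s2 + length))
            feats.append(Feature(f.name, f.kind, f.strand, ivs))
        return AnnotatedGenome(self.id, seq, True, feats)

    def gene(self, name: str) -> Feature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None


class AlignmentMatrix:
    """A sample x aligned-column character matrix over ``{A,C,G,T,N,-}``.

    Rows are stored as a uint8 matrix of ASCII codes; ``codes`` exposes the
    numeric encoding used by the diversity estimator (A,C,G,T -> 0..3,
    everything else -> 4 = invalid).
    """

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        ids = list(ids)
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids in alignment")
        if not rows:
            raise AlignmentError("empty alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        clean = []
        for rid, row in zip(ids, rows):
            row = row.upper().replace(".", "-").replace("U", "T")
            if not set(row) <= _VALID_DNA | {"-"}:
                bad = sorted(set(row) - _VALID_DNA - {"-"})
                warnings.warn(f"ambiguity codes {bad} mapped to N in row {rid}")
                row = re.sub("[^ACGTN-]", "N", row)
            clean.append(row)
        self.ids = ids
        self.data = np.frombuffer("".join(clean).encode(), dtype=np.uint8).reshape(
            len(clean), -1
        )
        self._codes: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    @property
    def codes(self) -> np.ndarray:
        if self._codes is None:
            lut = np.full(256, 4, dtype=np.int8)
            for i, b in enumerate(b"ACGT"):
                lut[b] = i
            self._codes = lut[self.data]
        return self._codes

    def row(self, rid: str) -> str:
        i = self.ids.index(rid)
        return self.data[i].tobytes().decode()

    def column(self, j: int) -> str:
        return self.data[:, j].tobytes().decode()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, AlignmentMatrix)
            and self.ids == other.ids
            and np.array_equal(self.data, other.data)
        )


# ---------------------------------------------------------------------------
# readers


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    Gene/tRNA/rRNA/CDS features are kept; ``/pseudo``-flagged features are
    marked ``pseudogene``.  Compound (``join``) locations keep one interval
    per part, already normalized to within-genome coordinates, so
    origin-spanning features come out as their in-range parts.  A feature
    whose location cannot be interpreted is skipped with a warning.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: not a readable GenBank record ({exc})") from exc
    seq = str(record.seq)
    if not seq or set(seq.upper()) <= {"N"}:
        raise FormatError(f"{path}: record has no usable ORIGIN sequence")
    circular = record.annotations.get("topology", "circular") != "linear"
    features: list[Feature] = []
    for feat in record.features:
        if feat.type not in _FEATURE_KINDS:
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or [""])[0]
        if not name:
            continue
        kind = _FEATURE_KINDS[feat.type]
        if "pseudo" in quals or "pseudogene" in quals:
            kind = "pseudogene"
        try:
            strand = "-" if feat.location.strand == -1 else "+"
            intervals = [(int(p.start), int(p.end)) for p in feat.location.parts]
            features.append(Feature(name, kind, strand, intervals))
        except (TypeError, ValueError, AttributeError) as exc:
            warnings.warn(f"{path}: skipping feature {name}: bad location ({exc})")
    return AnnotatedGenome(record.id or record.name, seq, circular, features)


def read_fasta(path: str | Path) -> list[AnnotatedGenome]:
    """Read a (multi-)FASTA of genomes; no features are attached."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return [AnnotatedGenome(r.id, str(r.seq)) for r in records]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment(path: str | Path) -> AlignmentMatrix:
    """Read an aligned multi-FASTA into an :class:`AlignmentMatrix`."""
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    if not rows:
        raise AlignmentError(f"{path}: no sequences")
    return AlignmentMatrix(ids, rows)


def read_newick(path_or_string: str | Path):
    """Read a newick tree (file path or literal string) as a dendropy Tree."""
    import dendropy

    s = str(path_or_string)
    if Path(s).exists():
        return dendropy.Tree.get(path=s, schema="newick",
                                 preserve_underscores=True)
    return dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)


# ---------------------------------------------------------------------------
# writers

_REGION_HEADER = "Start\tEnd\tLength\t#SVS\t#PIP\tPi\tGene name"


def write_regions(regions, path: str | Path, dialect: str = "tsv",
                  chrom: str = "alignment") -> None:
    """Write hypervariable regions as a TSV table or BED6.

    The TSV mirrors the marker-table layout (Start, End, Length, #SVS,
    #PIP, Pi, Gene name) with 0-based starts; BED6 is standard 0-based
    half-open with the Pi value in the score column scaled by 1e4.
    """
    regions = list(regions)
    for a, b in zip(regions, regions[1:]):
        if b.start < a.end:
            raise ValueError(
                f"overlapping regions [{a.start},{a.end}) and [{b.start},{b.end})"
            )
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write(_REGION_HEADER + "\n")
            for r in regions:
                fh.write(
                    f"{r.start}\t{r.end}\t{r.length}\t{r.n_svs}\t{r.n_pip}\t"
                    f"{r.pi:.8f}\t{r.name or 'unplaced'}\n"
                )
        elif dialect == "bed":
            for r in regions:
                score = min(1000, int(round(r.pi * 1e4)))
                fh.write(
                    f"{chrom}\t{r.start}\t{r.end}\t{r.name or 'unplaced'}\t{score}\t+\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
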