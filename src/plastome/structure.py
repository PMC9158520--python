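"""Quadripartite plastome architecture: IR detection, per-region GC, junctions.

A typical plastid genome is a circle of four regions in the fixed order
LSC (large single copy) -> IRb (inverted repeat b) -> SSC (small single
copy) -> IRa, where IRa is the exact reverse complement of IRb.  The IR
pair is located directly from the raw sequence by exact seed-and-extend
matching of the genome against its own reverse complement; the longer of
the two inter-IR segments is labelled LSC.  Coordinates are then rotated
so that LSC starts at position 0 (the canonical orientation used by all
downstream tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .io_formats import AnnotatedGenome, Feature, revcomp

__all__ = [
    "QuadripartitePartition",
    "GCReport",
    "JunctionOffset",
    "NoQuadripartiteStructureError",
    "detect_inverted_repeats",
    "canonicalize",
    "region_gc",
    "junction_report",
    "DEFAULT_TRACKED_GENES",
]

DEFAULT_TRACKED_GENES = ("rps19", "rpl2", "trnH", "ycf1", "trnN", "ndhF")


class NoQuadripartiteStructureError(ValueError):
    """No inverted-repeat pair of the required length exists."""


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals on the canonical rotation.

    The four half-open intervals tile ``[0, n)`` in that order;
    ``rotation`` is the offset of the canonical origin on the input
    sequence (``canonical_seq = seq[rotation:] + seq[:rotation]``).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    rotation: int = 0

    @property
    def n(self) -> int:
        return self.ira[1]

    @property
    def ir_len(self) -> int:
        return self.irb[1] - self.irb[0]

    def lengths(self) -> tuple[int, int, int]:
        """(LSC, SSC, IR) lengths, the genome-table triple."""
        return (
            self.lsc[1] - self.lsc[0],
            self.ssc[1] - self.ssc[0],
            self.ir_len,
        )

    def region_of(self, pos: int) -> str:
        pos %= self.n
        for name, (s, e) in (("LSC", self.lsc), ("IRb", self.irb),
                             ("SSC", self.ssc), ("IRa", self.ira)):
            if s <= pos < e:
                return name
        raise ValueError(f"position {pos} outside [0,{self.n})")

    def validate(self, canonical_seq: str) -> None:
        n = len(canonical_seq)
        if (self.lsc, self.irb, self.ssc, self.ira) != (
            (0, self.lsc[1]),
            (self.lsc[1], self.irb[1]),
            (self.irb[1], self.ssc[1]),
            (self.ssc[1], n),
        ):
            raise ValueError("partition does not tile the genome in order")
        irb = canonical_seq[self.irb[0]: self.irb[1]]
        ira = canonical_seq[self.ira[0]: self.ira[1]]
        if revcomp(irb) != ira:
            raise ValueError("IRa is not the reverse complement of IRb")


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _circular_overlap(a: int, b: int, L: int, n: int) -> bool:
    """Do circular intervals [a,a+L) and [b,b+L) (mod n) intersect?"""
    d = (b - a) % n
    return d < L or (n - d) < L


def _find_max_inverted_pair(seq: str, min_len: int):
    """All longest exact inverted-repeat pairs (a, b, L) on the circle.

    ``seq[(b+m) % n] == complement(seq[(a+L-1-m) % n])`` for m in [0, L):
    the copy at ``b`` is the reverse complement of the copy at ``a``.
    """
    n = len(seq)
    k = max(8, min(20, min_len))
    rc = revcomp(seq)
    # index k-mers of the circular reverse complement
    rc2 = rc + rc[: k - 1]
    table: dict[str, list[int]] = {}
    for p in range(n):
        table.setdefault(rc2[p : p + k], []).append(p)
    seq2 = seq + seq[: k - 1]
    covered: dict[int, list[tuple[int, int]]] = {}  # diagonal -> covered a-spans
    best: list[tuple[int, int, int]] = []
    best_len = min_len - 1
    max_half = n // 2
    for i in range(n):
        hits = table.get(seq2[i : i + k])
        if not hits or len(hits) > 5000:
            continue
        for p in hits:
            b = (n - p - k) % n
            diag = (i + b + k) % n
            spans = covered.get(diag)
            if spans and any(s <= i < s + m or s <= i + n < s + m for s, m in spans):
                continue
            # extend right of copy a / left of copy b
            a, L = i, k
            while L < max_half:
                if seq[(b - 1) % n] != _COMP[seq[(a + L) % n]]:
                    break
                nb = (b - 1) % n
                if _circular_overlap(a, nb, L + 1, n):
                    break
                b, L = nb, L + 1
            # extend left of copy a / right of copy b
            while L < max_half:
                if seq[(b + L) % n] != _COMP[seq[(a - 1) % n]]:
                    break
                na = (a - 1) % n
                if _circular_overlap(na, b, L + 1, n):
                    break
                a, L = na, L + 1
            covered.setdefault(diag, []).append((a, L))
            if L > best_len:
                best, best_len = [(a, b, L)], L
            elif L == best_len and L >= min_len:
                best.append((a, b, L))
    if not best:
        raise NoQuadripartiteStructureError(
            f"no inverted repeat of length >= {min_len} found"
        )
    return best, best_len


def detect_inverted_repeats(genome: AnnotatedGenome,
                            min_ir_len: int = 1000) -> QuadripartitePartition:
    """Locate the IR pair and return the canonical quadripartite partition.

    The maximal-length pair of exact inverted repeats is found by seeding
    on shared k-mers between the sequence and its reverse complement and
    extending each seed maximally on the circle; the longer inter-IR
    segment becomes LSC and coordinates are rotated so LSC starts at 0.
    Raises :class:`NoQuadripartiteStructureError` when no pair of length
    at least ``min_ir_len`` exists.  When several distinct maximal pairs
    tie, the one yielding the smallest canonical rotation wins (with a
    warning).
    """
    seq = genome.seq
    n = len(seq)
    pairs, L = _find_max_inverted_pair(seq, min_ir_len)
    # each pair is found from both copies; dedupe (a,b)/(b,a) and seed echoes
    unique = {}
    for a, b, length in pairs:
        key = (min(a, b), max(a, b))
        unique[key] = (a, b, length)
    candidates = []
    for a, b, length in unique.values():
        for c1, c2 in ((a, b), (b, a)):
            # treat c1 as IRb candidate: LSC would be the gap ending at c1
            gap_after = ((c2 - (c1 + length)) % n)  # c1-end -> c2-start
            gap_before = ((c1 - (c2 + length)) % n)  # c2-end -> c1-start
            if gap_before < gap_after:
                continue  # the segment before c1 must be the longer one (LSC)
            rotation = (c2 + length) % n
            lsc_len, ssc_len = gap_before, gap_after
            candidates.append((rotation, lsc_len, ssc_len, length))
    if not candidates:
        raise NoQuadripartiteStructureError(
            "inverted repeat found but the flanking segments are degenerate"
        )
    if len(unique) > 1:
        warnings.warn(
            f"{len(unique)} maximal inverted-repeat pairs of length {L}; "
            "tie-broken by smallest canonical rotation"
        )
    rotation, lsc_len, ssc_len, length = min(candidates)
    part = QuadripartitePartition(
        lsc=(0, lsc_len),
        irb=(lsc_len, lsc_len + length),
        ssc=(lsc_len + length, lsc_len + length + ssc_len),
        ira=(lsc_len + length + ssc_len, n),
        rotation=rotation,
    )
    canonical = seq[rotation:] + seq[:rotation]
    part.validate(canonical)
    return part


def canonicalize(genome: AnnotatedGenome,
                 part: QuadripartitePartition) -> AnnotatedGenome:
    """Rotate a genome (sequence and features) onto the canonical frame."""
    return genome.rotate(part.rotation)


@dataclass(frozen=True)
class GCReport:
    total: float
    lsc: float | None
    ssc: float | None
    ir: float | None

    def rounded(self) -> tuple[float, ...]:
        return tuple(
            round(v, 2) if v is not None else float("nan")
            for v in (self.total, self.lsc, self.ssc, self.ir)
        )


def _gc_pct(seq: str) -> float | None:
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return None
    return 100.0 * gc / (gc + at)


def region_gc(genome: AnnotatedGenome,
              part: QuadripartitePartition) -> GCReport:
    """GC% overall and per region (both IR copies pooled); N excluded from
    the denominator.  Values are full precision; round to 2 dp on output."""
    seq = genome.seq[part.rotation:] + genome.seq[: part.rotation]
    lsc = seq[part.lsc[0]: part.lsc[1]]
    ssc = seq[part.ssc[0]: part.ssc[1]]
    ir = seq[part.irb[0]: part.irb[1]] + seq[part.ira[0]: part.ira[1]]
    return GCReport(
        total=_gc_pct(seq),
        lsc=_gc_pct(lsc),
        ssc=_gc_pct(ssc),
        ir=_gc_pct(ir),
    )


@dataclass(frozen=True)
class JunctionOffset:
    """Nearest tracked gene at one junction and its signed distance.

    Positive offsets are the gap in bp between the junction and the gene;
    a negative offset means the gene straddles the junction and gives the
    number of its bases lying inside the IR (the IRscope convention: e.g.
    rps19 crossing JLB with 40 bp inside IRb is reported as -40).
    """

    junction: str
    position: int
    gene: str | None
    offset: int | None


_JUNCTION_IR = {"JLB": "irb", "JSB": "irb", "JSA": "ira", "JLA": "ira"}


def _circ_gap(a: int, b: int, n: int) -> int:
    """Minimal circular distance between positions a and b."""
    d = (a - b) % n
    return min(d, n - d)


def junction_report(part: QuadripartitePartition,
                    features: list[Feature],
                    tracked: tuple[str, ...] = DEFAULT_TRACKED_GENES
                    ) -> list[JunctionOffset]:
    """Signed junction-to-gene offsets for the four SC/IR junctions.

    Features must be in canonical coordinates (see :func:`canonicalize`).
    For each junction the nearest tracked gene is reported; tracked genes
    absent from the annotation yield a ``gene=None`` entry for any
    junction they would otherwise win.
    """
    n = part.n
    junctions = {
        "JLB": part.irb[0],
        "JSB": part.irb[1],
        "JSA": part.ssc[1],
        "JLA": part.ira[1] % n,
    }
    # prefer 'gene'-kind features; fall back to anything with the name
    by_name: dict[str, Feature] = {}
    for f in features:
        base = f.name.split("-")[0]
        for key in {f.name, base}:
            if key not in by_name or (f.kind in ("gene", "pseudogene")
                                      and by_name[key].kind not in ("gene", "pseudogene")):
                by_name[key] = f
    out = []
    for jname, jpos in junctions.items():
        ir_interval = getattr(part, _JUNCTION_IR[jname])
        best: tuple[int, str, int] | None = None  # (|offset|, gene, signed)
        for gname in tracked:
            f = by_name.get(gname)
            if f is None:
                continue
            s, e = f.start % n, f.end  # e may exceed n for origin spanners
            # overlap with the junction's IR, on the circle
            inside = _interval_overlap(s, e, ir_interval[0], ir_interval[1], n)
            spans = _contains_circular(s, e, jpos, n)
            if spans and inside > 0:
                cand = (inside, gname, -inside)
            else:
                gap = min(_circ_gap(s, jpos, n), _circ_gap(e % n, jpos, n))
                cand = (gap, gname, gap)
            if best is None or cand[0] < best[0]:
                best = cand
        if best is None:
            out.append(JunctionOffset(jname, jpos, None, None))
        else:
            out.append(JunctionOffset(jname, jpos, best[1], best[2]))
    return out


def _contains_circular(s: int, e: int, pos: int, n: int) -> bool:
    """Does the circular interval [s, e) (e may exceed n) contain pos?"""
    length = e - s
    return (pos - s) % n < length


def _interval_overlap(s: int, e: int, rs: int, re_: int, n: int) -> int:
    """Overlap length between circular interval [s,e) and in-range [rs,re)."""
    total = 0
    a = s % n
    b = a + (e - s)  # unrolled onto [0, 2n)
    for shift in (0, n):
        lo = max(a, rs + shift)
        hi = min(b, re_ + shift)
        if hi > lo:
            total += hi - lo
    return total
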