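"""Repeat landscapes: microsatellites (SSRs) and dispersed long repeats.

SSRs are maximal perfect tandem repeats of a 1-6 bp unit meeting a
per-unit-length minimum copy number (the MISA-style thresholds
``{1: 11, 2: 6, 3: 5, 4: 4, 5: 3, 6: 3}``); nearby SSRs are merged into
compound records.  Dispersed repeats are maximal exact repeat pairs of at
least ``min_len`` bp in four orientation classes — forward (copy2 equals
copy1), reverse (copy2 is copy1 reversed), complement (copy2 is the
base-wise complement) and palindromic (copy2 is the reverse complement) —
found by k-mer seeding and maximal extension, REPuter-style but at zero
mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import AnnotatedGenome, complement, revcomp
from .structure import QuadripartitePartition

__all__ = [
    "SSRRecord",
    "RepeatRecord",
    "DEFAULT_SSR_THRESHOLDS",
    "REPEAT_CLASSES",
    "find_ssrs",
    "find_long_repeats",
    "count_ssrs",
]

DEFAULT_SSR_THRESHOLDS = {1: 11, 2: 6, 3: 5, 4: 4, 5: 3, 6: 3}
REPEAT_CLASSES = ("forward", "reverse", "complement", "palindromic")


@dataclass(frozen=True)
class SSRRecord:
    """One microsatellite (or compound microsatellite) locus."""

    motif: str
    unit_len: int  # 0 for compound records
    copies: int
    start: int
    end: int
    ssr_type: str  # p1..p6 or "compound"
    region: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RepeatRecord:
    """One dispersed exact repeat pair."""

    repeat_class: str
    length: int
    pos1: int
    pos2: int
    regions: tuple[str | None, str | None] = (None, None)

    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.pos1, self.pos1 + self.length),
                (self.pos2, self.pos2 + self.length))


def _min_period(motif: str) -> int:
    for d in range(1, len(motif)):
        if len(motif) % d == 0 and motif == motif[:d] * (len(motif) // d):
            return d
    return len(motif)


def _simple_ssrs(seq: str, thresholds: dict[int, int]) -> list[SSRRecord]:
    import numpy as np

    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_n = arr == ord("N")
    found: list[SSRRecord] = []
    for u in sorted(thresholds):
        if n <= u:
            continue
        min_copies = thresholds[u]
        # match[x] true iff position x repeats u later (a period-u chain)
        match = (arr[:-u] == arr[u:]) & ~is_n[:-u] & ~is_n[u:]
        # maximal runs of True
        padded = np.concatenate(([False], match, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive, in match coords
        for x0, x1 in zip(starts, ends):
            span = (x1 - x0) + u  # matched chain plus the seeding unit
            copies = span // u
            if copies < min_copies:
                continue
            motif = seq[x0 : x0 + u]
            if _min_period(motif) != u:
                continue  # owned by a smaller unit length
            found.append(
                SSRRecord(motif, u, int(copies), int(x0),
                          int(x0 + u * copies), f"p{u}")
            )
    found.sort(key=lambda r: (r.start, r.end))
    return found


def _merge_compound(records: list[SSRRecord], max_gap: int) -> list[SSRRecord]:
    if not records:
        return []
    merged: list[list[SSRRecord]] = [[records[0]]]
    for rec in records[1:]:
        if rec.start - merged[-1][-1].end <= max_gap:
            merged[-1].append(rec)
        else:
            merged.append([rec])
    out = []
    for group in merged:
        if len(group) == 1:
            out.append(group[0])
        else:
            start, end = group[0].start, group[-1].end
            motif = "-".join(f"({g.motif}){g.copies}" for g in group)
            out.append(
                SSRRecord(motif, 0, len(group), start, end, "compound")
            )
    return out


def find_ssrs(genome: AnnotatedGenome,
              thresholds: dict[int, int] | None = None,
              compound_max_gap: int = 100,
              partition: QuadripartitePartition | None = None,
              merge_compound: bool = True) -> list[SSRRecord]:
    """Scan for perfect SSRs with MISA-style thresholds.

    Runs are assigned to the smallest unit length that generates them
    (poly-A is a mononucleotide SSR, never a stack of "AA" units); ``N``
    breaks runs.  Two or more SSRs separated by at most
    ``compound_max_gap`` bp merge into one compound record unless
    ``merge_compound`` is false.  With a partition, each record is
    labelled with the region containing its start.
    """
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    if partition is not None and partition.rotation != 0:
        genome = genome.rotate(partition.rotation)
    records = _simple_ssrs(genome.seq, thresholds)
    if merge_compound:
        records = _merge_compound(records, compound_max_gap)
    if partition is not None:
        records = [
            SSRRecord(r.motif, r.unit_len, r.copies, r.start, r.end,
                      r.ssr_type, partition.region_of(r.start))
            for r in records
        ]
    return records


def count_ssrs(records: list[SSRRecord],
               compound_as_one: bool = True) -> int:
    """Total SSR count; a compound either counts once or as its components."""
    if compound_as_one:
        return len(records)
    return sum(r.copies if r.ssr_type == "compound" else 1 for r in records)


# ---------------------------------------------------------------------------
# dispersed long repeats


def _maximal_matches(s: str, t: str, min_len: int,
                     max_mismatch: int = 0) -> list[tuple[int, int, int]]:
    """Maximal common substrings (i, j, L) with s[i:i+L] ~ t[j:j+L],
    L >= min_len, found by k-mer seeding (k = min_len) + extension.

    With ``max_mismatch > 0`` the extension greedily spends a Hamming
    budget shared by both directions and trims back to end on matches;
    the default 0 gives exact maximal matches.
    """
    k = min_len
    index: dict[str, list[int]] = {}
    for j in range(len(t) - k + 1):
        kmer = t[j : j + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(j)
    covered: dict[int, list[tuple[int, int]]] = {}  # diagonal i-j -> i spans
    out = []
    for i in range(len(s) - k + 1):
        hits = index.get(s[i : i + k])
        if not hits:
            continue
        for j in hits:
            diag = i - j
            spans = covered.get(diag)
            if spans and any(a <= i and i + k <= b for a, b in spans):
                continue
            a, b, L = i, j, k
            budget = max_mismatch
            while a > 0 and b > 0 and s[a - 1] != "N" and t[b - 1] != "N":
                if s[a - 1] != t[b - 1]:
                    if budget == 0:
                        break
                    budget -= 1
                a, b, L = a - 1, b - 1, L + 1
            while s[a] != t[b]:  # trim a leading mismatch back to a match
                a, b, L = a + 1, b + 1, L - 1
                budget += 1
            while (a + L < len(s) and b + L < len(t)
                   and s[a + L] != "N" and t[b + L] != "N"):
                if s[a + L] != t[b + L]:
                    if budget == 0:
                        break
                    budget -= 1
                L += 1
            while s[a + L - 1] != t[b + L - 1]:  # trim trailing mismatches
                L -= 1
            covered.setdefault(diag, []).append((a, a + L))
            out.append((a, b, L))
    return [m for m in out if m[2] >= min_len]


def _map_pair(cls: str, i: int, j: int, L: int, n: int):
    """Map a match on the transformed string back to genome coordinates."""
    if cls in ("forward", "complement"):
        return i, j
    # reverse / palindromic: t was reversed, so position j starts at n-j-L
    return i, n - j - L


def find_long_repeats(genome: AnnotatedGenome,
                      partition: QuadripartitePartition | None = None,
                      min_len: int = 30,
                      classes: tuple[str, ...] = REPEAT_CLASSES,
                      search_regions: tuple[str, ...] = ("LSC", "IRb", "SSC"),
                      max_mismatch: int = 0,
                      ) -> list[RepeatRecord]:
    """Maximal exact dispersed repeat pairs of length >= ``min_len``.

    The scan runs on the canonical LSC+IRb+SSC segment when a partition
    is given (IRa excluded, so the genome-scale IRa/IRb pair itself never
    appears); without a partition the whole sequence is scanned.
    Self-pairs, overlapping copies, symmetric duplicates and pairs whose
    two copies are contained in a longer pair of the same class are
    suppressed.  ``min_len`` uses >=-semantics ("longer than 30 bp" means
    length 30 and up).  ``max_mismatch`` allows a Hamming budget during
    extension (seeds stay exact); the default 0 keeps the scan exact and
    reproducible.
    """
    if partition is not None:
        if partition.rotation != 0:
            genome = genome.rotate(partition.rotation)
        # contiguous canonical prefix covering the requested regions
        stop = partition.n
        if set(search_regions) == {"LSC", "IRb", "SSC"}:
            stop = partition.ssc[1]
        seq = genome.seq[:stop]
    else:
        seq = genome.seq
    n = len(seq)
    transforms = {
        "forward": seq,
        "reverse": seq[::-1],
        "complement": complement(seq),
        "palindromic": revcomp(seq),
    }
    records: list[RepeatRecord] = []
    for cls in classes:
        seen: set[tuple[int, int, int]] = set()
        for i, j, L in _maximal_matches(seq, transforms[cls], min_len,
                                        max_mismatch):
            p1, p2 = _map_pair(cls, i, j, L, n)
            lo, hi = min(p1, p2), max(p1, p2)
            if lo == hi:  # self-pair
                continue
            if hi < lo + L:  # overlapping copies
                continue
            key = (lo, hi, L)
            if key in seen:
                continue
            seen.add(key)
            records.append(RepeatRecord(cls, L, lo, hi))
    records = _suppress_contained(records)
    if partition is not None:
        records = [
            RepeatRecord(r.repeat_class, r.length, r.pos1, r.pos2,
                         (partition.region_of(r.pos1),
                          partition.region_of(r.pos2)))
            for r in records
        ]
    records.sort(key=lambda r: (-r.length, r.pos1, r.pos2, r.repeat_class))
    return records


def _suppress_contained(records: list[RepeatRecord]) -> list[RepeatRecord]:
    """Drop pairs whose both copies sit inside a longer same-class pair."""
    by_class: dict[str, list[RepeatRecord]] = {}
    for r in records:
        by_class.setdefault(r.repeat_class, []).append(r)
    keep = []
    for cls, recs in by_class.items():
        recs.sort(key=lambda r: -r.length)
        kept: list[RepeatRecord] = []
        for r in recs:
            (a1, b1), (a2, b2) = r.intervals()
            contained = any(
                (o.pos1 <= a1 and b1 <= o.pos1 + o.length
                 and o.pos2 <= a2 and b2 <= o.pos2 + o.length)
                or (o.pos1 <= a2 and b2 <= o.pos1 + o.length
                    and o.pos2 <= a1 and b1 <= o.pos2 + o.length)
                for o in kept if o.length > r.length
            )
            if not contained:
                kept.append(r)
        keep.extend(kept)
    return keep
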