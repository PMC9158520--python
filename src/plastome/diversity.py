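"""Gap-aware sliding-window nucleotide diversity and hotspot calling.

Nucleotide diversity is estimated pixy-style as a ratio of sums: for each
alignment column the number of differing pairs among valid characters
(A/C/G/T only; gaps and N are missing data) and the number of comparable
pairs are accumulated, and pi over an interval is total differing pairs
divided by total comparable pairs.  This keeps the estimator unbiased in
the presence of gaps — columns with missing data contribute fewer pairs
instead of being dropped or imputed.

Sites are classified as invariant, singleton, parsimony-informative
(>= 2 distinct valid bases each seen >= 2 times) or invalid (< 2 valid
characters).  Windows of ``win_len`` columns advancing by ``step`` whose
pi and parsimony-informative-site count strictly exceed the thresholds
are merged into hypervariable regions, whose statistics are recomputed on
the merged column span (not aggregated from the windows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import AlignmentMatrix, AnnotatedGenome

__all__ = [
    "SiteClass",
    "WindowStat",
    "HypervariableRegion",
    "site_tables",
    "classify_site",
    "window_pi",
    "sliding_windows",
    "merge_hotspots",
    "name_region",
]


@dataclass(frozen=True)
class SiteClass:
    column: int
    n_valid: int
    n_diff_pairs: int
    n_pairs: int
    status: str  # invariant | singleton | parsimony_informative | invalid


@dataclass(frozen=True)
class WindowStat:
    start: int
    end: int
    pi: float | None
    n_pis: int
    n_singleton: int

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class HypervariableRegion:
    start: int
    end: int
    length: int
    n_svs: int
    n_pip: int
    pi: float
    name: str | None = None


def site_tables(aln: AlignmentMatrix):
    """Per-column arrays (diff_pairs, pairs, is_pis, is_singleton).

    The workhorse behind every estimator here: base counts per column give
    comparable pairs ``v(v-1)/2``, same-base pairs ``sum c(c-1)/2`` and
    their difference, plus the site classifications.
    """
    codes = aln.codes
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])
    n_valid = counts.sum(axis=0)
    n_pairs = n_valid * (n_valid - 1) // 2
    same = (counts * (counts - 1) // 2).sum(axis=0)
    diff = n_pairs - same
    n_distinct = (counts > 0).sum(axis=0)
    is_pis = ((counts >= 2).sum(axis=0) >= 2) & (n_distinct >= 2)
    variable = (n_distinct >= 2) & (n_valid >= 2)
    is_singleton = variable & ~is_pis
    return diff, n_pairs, is_pis, is_singleton, n_valid, n_distinct


def classify_site(column: str) -> SiteClass:
    """Classify one alignment column (a string of characters, one per row)."""
    aln = AlignmentMatrix([f"s{i}" for i in range(len(column))],
                          list(column))
    diff, pairs, pis, single, n_valid, n_distinct = site_tables(aln)
    if n_valid[0] < 2:
        status = "invalid"
    elif pis[0]:
        status = "parsimony_informative"
    elif single[0]:
        status = "singleton"
    else:
        status = "invariant"
    return SiteClass(0, int(n_valid[0]), int(diff[0]), int(pairs[0]), status)


def window_pi(aln: AlignmentMatrix, start: int, end: int):
    """(pi, n_pis, n_singleton) over columns [start, end).

    pi is the ratio of summed differing pairs to summed comparable pairs;
    ``None`` when no column in the interval has two comparable characters.
    """
    if not 0 <= start < end <= aln.n_columns:
        raise ValueError(f"bad column interval [{start},{end}) "
                         f"for alignment of {aln.n_columns} columns")
    diff, pairs, pis, single, *_ = site_tables(aln)
    d = int(diff[start:end].sum())
    c = int(pairs[start:end].sum())
    pi = d / c if c > 0 else None
    return pi, int(pis[start:end].sum()), int(single[start:end].sum())


def sliding_windows(aln: AlignmentMatrix, win_len: int = 600,
                    step: int = 200) -> list[WindowStat]:
    """Window statistics at starts 0, step, 2*step, ...; the last window is
    truncated to the alignment end."""
    if win_len < step:
        warnings.warn("win_len < step leaves columns uncovered")
    diff, pairs, pis, single, *_ = site_tables(aln)
    cd = np.concatenate(([0], np.cumsum(diff)))
    cc = np.concatenate(([0], np.cumsum(pairs)))
    cp = np.concatenate(([0], np.cumsum(pis)))
    cs = np.concatenate(([0], np.cumsum(single)))
    out = []
    for start in range(0, aln.n_columns, step):
        end = min(start + win_len, aln.n_columns)
        d = int(cd[end] - cd[start])
        c = int(cc[end] - cc[start])
        out.append(WindowStat(
            start, end,
            d / c if c > 0 else None,
            int(cp[end] - cp[start]),
            int(cs[end] - cs[start]),
        ))
    return out


def merge_hotspots(windows: list[WindowStat], aln: AlignmentMatrix,
                   pi_min: float = 0.01,
                   pis_min: int = 25) -> list[HypervariableRegion]:
    """Merge runs of qualifying windows into hypervariable regions.

    A window qualifies iff ``pi > pi_min`` and ``n_pis > pis_min`` (strict
    inequalities).  Maximal runs of consecutive qualifying windows span
    from the first window's start to the last window's end; overlapping
    spans from distinct runs (possible when windows overlap) are merged so
    the output is disjoint.  Region statistics are recomputed column-wise
    on the merged span.
    """
    qual = [w.pi is not None and w.pi > pi_min and w.n_pis > pis_min
            for w in windows]
    spans: list[list[int]] = []
    run_start = None
    for idx, q in enumerate(qual):
        if q and run_start is None:
            run_start = idx
        elif not q and run_start is not None:
            spans.append([windows[run_start].start, windows[idx - 1].end])
            run_start = None
    if run_start is not None:
        spans.append([windows[run_start].start, windows[-1].end])
    # enforce disjointness when overlapping windows bridge two runs
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    diff, pairs, pis, single, *_ = site_tables(aln)
    regions = []
    for s, e in merged:
        d = int(diff[s:e].sum())
        c = int(pairs[s:e].sum())
        regions.append(HypervariableRegion(
            start=s, end=e, length=e - s,
            n_svs=int(single[s:e].sum()),
            n_pip=int(pis[s:e].sum()),
            pi=d / c if c else 0.0,
        ))
    return regions


def name_region(region: HypervariableRegion, ref_genome: AnnotatedGenome,
                aln: AlignmentMatrix, ref_id: str) -> str:
    """Label a region by its flanking/overlapping genes on a reference row.

    Alignment columns are projected to reference coordinates by skipping
    the reference row's gap columns; the label is ``geneL-geneR`` for a
    region inside an intergenic spacer, the gene's own name when a single
    gene covers it, and ``unplaced`` when the whole region maps into a
    reference gap.
    """
    row = aln.row(ref_id)
    region_cols = row[region.start: region.end]
    if set(region_cols) <= {"-"}:
        return "unplaced"
    # ref coordinate of each non-gap column
    gapless_before = 0
    col_to_ref = {}
    for j, ch in enumerate(row):
        if ch != "-":
            col_to_ref[j] = gapless_before
            gapless_before += 1
    inside = [col_to_ref[j] for j in range(region.start, region.end)
              if j in col_to_ref]
    lo, hi = min(inside), max(inside) + 1
    genes = sorted(
        (f for f in ref_genome.features if f.kind != "CDS"),
        key=lambda f: f.start,
    )
    if not genes:
        return "unplaced"
    overlapping = [f for f in genes if f.start < hi and f.end > lo]
    left = [f for f in genes if f.end <= lo]
    right = [f for f in genes if f.start >= hi]
    if overlapping and overlapping[0].start <= lo and overlapping[-1].end >= hi:
        if len(overlapping) == 1:
            return overlapping[0].name
    name_l = (overlapping[0].name if overlapping and overlapping[0].start < lo
              else (left[-1].name if left else genes[-1].name))
    name_r = (overlapping[-1].name if overlapping and overlapping[-1].end > hi
              else (right[0].name if right else genes[0].name))
    if name_l == name_r:
        return name_l
    return f"{name_l}-{name_r}"
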