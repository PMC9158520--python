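"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

from plastome.io_formats import AlignmentMatrix, complement, revcomp


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.35) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


# ---------------------------------------------------------------------------
# diversity oracle: direct pairwise enumeration per column


def brute_site(column: str):
    """(n_valid, n_diff_pairs, n_pairs, status) by explicit enumeration."""
    valid = [c for c in column if c in "ACGT"]
    pairs = list(itertools.combinations(valid, 2))
    diff = sum(1 for a, b in pairs if a != b)
    counts = Counter(valid)
    if len(valid) < 2:
        status = "invalid"
    elif len(counts) == 1:
        status = "invariant"
    elif sum(1 for v in counts.values() if v >= 2) >= 2:
        status = "parsimony_informative"
    else:
        status = "singleton"
    return len(valid), diff, len(pairs), status


def brute_window(rows: list[str], start: int, end: int):
    """(pi, n_pis, n_singleton) as the ratio of summed pair counts."""
    d = c = pis = single = 0
    for col in range(start, end):
        _, dd, cc, status = brute_site("".join(r[col] for r in rows))
        d += dd
        c += cc
        pis += status == "parsimony_informative"
        single += status == "singleton"
    return (d / c if c else None), pis, single


def random_gapped_alignment(rng: np.random.Generator, n_rows: int,
                            n_cols: int) -> AlignmentMatrix:
    chars = np.array(list("ACGT-N"))
    mat = chars[rng.choice(6, size=(n_rows, n_cols),
                           p=[0.3, 0.2, 0.2, 0.2, 0.07, 0.03])]
    return AlignmentMatrix([f"r{i}" for i in range(n_rows)],
                           ["".join(row) for row in mat])


# ---------------------------------------------------------------------------
# repeat oracles: quadratic diagonal scans, independent of the seed-and-
# extend scanner


def _diagonal_runs(s: str, t: str, min_len: int):
    """All maximal runs (i, j, L >= min_len) with s[i:i+L] == t[j:j+L]."""
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    b = np.frombuffer(t.encode(), dtype=np.uint8)
    runs = []
    for d in range(-(len(b) - 1), len(a)):
        i0, j0 = max(0, d), max(0, -d)
        length = min(len(a) - i0, len(b) - j0)
        if length < min_len:
            continue
        m = (a[i0 : i0 + length] == b[j0 : j0 + length]) \
            & (a[i0 : i0 + length] != ord("N"))
        padded = np.concatenate(([False], m, [False]))
        edges = np.diff(padded.astype(np.int8))
        for x0, x1 in zip(np.flatnonzero(edges == 1),
                          np.flatnonzero(edges == -1)):
            if x1 - x0 >= min_len:
                runs.append((i0 + int(x0), j0 + int(x0), int(x1 - x0)))
    return runs


def brute_long_repeats(seq: str, min_len: int = 30):
    """Maximal exact pairs per orientation class, quadratic-scan oracle.

    Applies the same reporting rules as the scanner: lexicographic pair
    order, no self or overlapping copies, containment suppression.
    """
    n = len(seq)
    transforms = {
        "forward": seq,
        "reverse": seq[::-1],
        "complement": complement(seq),
        "palindromic": revcomp(seq),
    }
    out = {}
    for cls, t in transforms.items():
        pairs = set()
        for i, j, L in _diagonal_runs(seq, t, min_len):
            p2 = j if cls in ("forward", "complement") else n - j - L
            lo, hi = min(i, p2), max(i, p2)
            if lo == hi or hi < lo + L:
                continue
            pairs.add((lo, hi, L))
        # containment suppression (independent O(m^2) pass)
        kept = []
        for lo, hi, L in sorted(pairs, key=lambda x: -x[2]):
            if not any(
                oL > L and ((olo <= lo and lo + L <= olo + oL
                             and ohi <= hi and hi + L <= ohi + oL)
                            or (olo <= hi and hi + L <= olo + oL
                                and ohi <= lo and lo + L <= ohi + oL))
                for olo, ohi, oL in kept
            ):
                kept.append((lo, hi, L))
        out[cls] = set(kept)
    return out


def brute_ssrs(seq: str, thresholds: dict[int, int]):
    """Maximal perfect tandem repeats by direct per-position checking."""
    found = set()
    n = len(seq)
    for u, min_copies in thresholds.items():
        for i in range(n - u + 1):
            motif = seq[i : i + u]
            if "N" in motif:
                continue
            # minimal period must equal u
            if any(len(motif) % d == 0 and motif == motif[:d] * (u // d)
                   for d in range(1, u)):
                continue
            # left-maximal?
            if i >= u and seq[i - u : i] == motif:
                continue
            if i >= 1 and seq[i - 1] == motif[-1]:
                continue  # extendable leftwards by one period step
            copies = 1
            while i + (copies + 1) * u <= n and \
                    seq[i + copies * u : i + (copies + 1) * u] == motif:
                copies += 1
            if copies >= min_copies:
                found.add((i, i + copies * u, motif))
    return found


def ssr_free_flank(rng: np.random.Generator, n: int,
                   not_start: str = "", not_end: str = "") -> str:
    """Random DNA guaranteed (by the brute oracle) to contain no SSR and,
    optionally, not to begin/end with a given base (so a planted run next
    to it cannot extend)."""
    from plastome.repeats import DEFAULT_SSR_THRESHOLDS

    while True:
        s = random_dna(rng, n)
        if brute_ssrs(s, DEFAULT_SSR_THRESHOLDS):
            continue
        if not_start and s[0] in not_start:
            continue
        if not_end and s[-1] in not_end:
            continue
        return s


@pytest.fixture(scope="session")
def skewed_freqs():
    from plastome.selection import f3x4

    return f3x4(np.array([[0.3, 0.2, 0.2, 0.3],
                          [0.25, 0.25, 0.25, 0.25],
                          [0.35, 0.15, 0.15, 0.35]]))


@pytest.fixture(scope="session")
def eight_taxon_tree():
    return ("(((a:0.08,b:0.06):0.05,(c:0.07,d:0.09):0.04):0.06,"
            "((e:0.05,f:0.08):0.07,(g:0.06,h:0.04):0.05):0.03);")
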