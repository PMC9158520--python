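"""Synthetic data generators emulating comparative-plastome inputs.

Three generators make every pipeline stage testable offline, each fully
determined by its seed and returning a ground-truth record for oracle
assertions:

* :func:`simulate_plastome` — a circular quadripartite genome (random
  sequence at a target GC with IRa the exact reverse complement of IRb)
  carrying planted SSRs, dispersed repeats and gene annotations.
* :func:`simulate_alignment` — a star-phylogeny-like multiple alignment:
  an ancestral row mutated independently per sample and column, with
  localized hotspot intervals of elevated substitution probability and
  i.i.d. gaps.  Substitutions are not tree-structured; that is enough to
  exercise the (tree-free) diversity estimator but understates linkage
  between nearby columns relative to real data.
* :func:`simulate_codon_alignment` — codon sequences evolved along a tree
  under the GY94 model with branch-class-specific omega.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io_formats import AlignmentMatrix, AnnotatedGenome, Feature, revcomp
from .selection import (CodonAlignment, CodonFrequencies, IndexedTree,
                        _transition_matrix, _eigensystem, genetic_code,
                        gy94_rates)

__all__ = [
    "PlastomeSpec",
    "HotspotSpec",
    "PlastomeTruth",
    "simulate_plastome",
    "simulate_alignment",
    "simulate_codon_alignment",
]

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class PlastomeSpec:
    """Blueprint for one synthetic plastome.

    Region lengths mirror the quadripartite layout (``lsc_len`` must
    exceed ``ssc_len``).  Planted elements are placed at deterministic,
    non-overlapping offsets inside their region and recorded in the truth
    table.  ``planted_ssrs`` entries are (motif, copies, region);
    ``planted_repeats`` are (class, length, (region1, region2));
    ``planted_genes`` are (name, region, offset, length, strand).
    """

    lsc_len: int = 82_000
    ssc_len: int = 18_500
    ir_len: int = 23_700
    gc: float = 0.35
    planted_ssrs: list[tuple[str, int, str]] = field(default_factory=list)
    planted_repeats: list[tuple[str, int, tuple[str, str]]] = field(default_factory=list)
    planted_genes: list[tuple[str, str, int, int, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ValueError("region lengths must be positive")
        if self.lsc_len <= self.ssc_len:
            raise ValueError("lsc_len must exceed ssc_len")
        if not 0 < self.gc < 1:
            raise ValueError("gc must be a fraction in (0,1)")


@dataclass
class PlastomeTruth:
    """Ground truth emitted alongside a simulated plastome."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    ssrs: list[dict]
    repeats: list[dict]
    genes: list[dict]


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _NT[rng.choice(4, size=n, p=p)]


def _region_bounds(spec: PlastomeSpec) -> dict[str, tuple[int, int]]:
    lsc = (0, spec.lsc_len)
    irb = (lsc[1], lsc[1] + spec.ir_len)
    ssc = (irb[1], irb[1] + spec.ssc_len)
    ira = (ssc[1], ssc[1] + spec.ir_len)
    return {"LSC": lsc, "IRb": irb, "SSC": ssc, "IRa": ira}


def simulate_plastome(spec: PlastomeSpec) -> tuple[AnnotatedGenome, PlastomeTruth]:
    """Generate a quadripartite genome plus its ground-truth record.

    The LSC/IRb/SSC backbone is drawn at the target GC, planted elements
    are written in at spaced offsets (error if they cannot fit without
    overlap), and IRa is emitted as the exact reverse complement of IRb.
    Placement, like everything else, depends only on the seed.
    """
    rng = np.random.default_rng(spec.seed)
    bounds = _region_bounds(spec)
    n = bounds["IRa"][1]
    seq = np.empty(n, dtype=np.uint8)
    for region in ("LSC", "IRb", "SSC"):
        s, e = bounds[region]
        seq[s:e] = _random_seq(rng, e - s, spec.gc)

    # lay out planted elements without overlap, per region
    cursors = {r: b[0] + 200 for r, b in bounds.items()}
    spacing = 300

    def place(region: str, length: int) -> int:
        if region == "IRa":
            raise ValueError("plant elements in LSC/IRb/SSC; IRa mirrors IRb")
        start = cursors[region]
        end = start + length
        if end + 200 > bounds[region][1]:
            raise ValueError(f"planted elements overflow region {region}")
        cursors[region] = end + spacing
        return start

    truth_ssrs = []
    for motif, copies, region in spec.planted_ssrs:
        motif = motif.upper()
        start = place(region, len(motif) * copies)
        block = np.frombuffer((motif * copies).encode(), dtype=np.uint8)
        seq[start : start + block.size] = block
        # guard flanks so the run cannot extend: the periodic continuation
        # is motif[-1] on the left and motif[0] on the right
        seq[start - 1] = ord(next(c for c in "ACGT" if c != motif[-1]))
        seq[start + block.size] = ord(next(c for c in "ACGT" if c != motif[0]))
        truth_ssrs.append({"motif": motif, "copies": copies,
                           "start": int(start),
                           "end": int(start + block.size),
                           "region": region})

    truth_reps = []
    for cls, length, (r1, r2) in spec.planted_repeats:
        block = _random_seq(rng, length, spec.gc)
        p1 = place(r1, length)
        p2 = place(r2, length)
        seq[p1 : p1 + length] = block
        s = block.tobytes().decode()
        if cls == "forward":
            other = s
        elif cls == "reverse":
            other = s[::-1]
        elif cls == "complement":
            other = revcomp(s)[::-1]
        elif cls == "palindromic":
            other = revcomp(s)
        else:
            raise ValueError(f"unknown repeat class {cls!r}")
        seq[p2 : p2 + length] = np.frombuffer(other.encode(), dtype=np.uint8)
        # break any chance single-base extension of the planted pair so the
        # maximal match has exactly the planted length
        comp = dict(zip(b"ACGT", b"TGCA"))

        def _force_diff(pos: int, banned: int) -> None:
            if seq[pos] == banned:
                seq[pos] = next(b for b in b"ACGT" if b != banned)

        if cls == "forward":
            _force_diff(p2 + length, seq[p1 + length])
            _force_diff(p2 - 1, seq[p1 - 1])
        elif cls == "reverse":
            _force_diff(p2 - 1, seq[p1 + length])
            _force_diff(p2 + length, seq[p1 - 1])
        elif cls == "complement":
            _force_diff(p2 + length, comp[seq[p1 + length]])
            _force_diff(p2 - 1, comp[seq[p1 - 1]])
        else:  # palindromic
            _force_diff(p2 - 1, comp[seq[p1 + length]])
            _force_diff(p2 + length, comp[seq[p1 - 1]])
        lo, hi = sorted((p1, p2))
        truth_reps.append({"class": cls, "length": length,
                           "pos1": int(lo), "pos2": int(hi)})

    truth_genes = []
    features = []
    for name, region, offset, length, strand in spec.planted_genes:
        s0 = bounds[region][0] + offset
        features.append(Feature(name, "gene", strand, [(s0, s0 + length)]))
        truth_genes.append({"name": name, "start": int(s0),
                            "end": int(s0 + length), "strand": strand,
                            "region": region})

    irb_s, irb_e = bounds["IRb"]
    ira = revcomp(seq[irb_s:irb_e].tobytes().decode())
    seq[bounds["IRa"][0]: bounds["IRa"][1]] = np.frombuffer(ira.encode(),
                                                            dtype=np.uint8)
    # mismatch guards at the IR flanks so the planted pair is exactly
    # maximal: the copies must not extend into SSC (first SSC base vs the
    # last) or across the origin into LSC (first LSC base vs the last)
    comp = dict(zip(b"ACGT", b"TGCA"))
    ssc_s, ssc_e = bounds["SSC"]
    if seq[ssc_s] == comp[seq[ssc_e - 1]]:
        seq[ssc_s] = next(b for b in b"ACGT"
                          if b != comp[seq[ssc_e - 1]] and b != seq[ssc_s + 1])
    if seq[0] == comp[seq[bounds["LSC"][1] - 1]]:
        seq[0] = next(b for b in b"ACGT"
                      if b != comp[seq[bounds["LSC"][1] - 1]] and b != seq[1])
    genome = AnnotatedGenome(f"sim{spec.seed}", seq.tobytes().decode(),
                             circular=True, features=features)
    truth = PlastomeTruth(bounds["LSC"], bounds["IRb"], bounds["SSC"],
                          bounds["IRa"], truth_ssrs, truth_reps, truth_genes)
    return genome, truth


@dataclass
class HotspotSpec:
    """Blueprint for an alignment with localized diversity hotspots."""

    n_samples: int = 22
    n_columns: int = 150_000
    background_rate: float = 0.002
    hotspots: list[tuple[int, int]] = field(default_factory=list)
    hotspot_rate: float = 0.03
    gap_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.background_rate, self.hotspot_rate, self.gap_rate):
            if not 0 <= p <= 1:
                raise ValueError("rates must be probabilities")
        for s, e in self.hotspots:
            if not 0 <= s < e <= self.n_columns:
                raise ValueError(f"hotspot [{s},{e}) outside the alignment")


def simulate_alignment(spec: HotspotSpec) -> tuple[AlignmentMatrix,
                                                   list[tuple[int, int]]]:
    """Ancestral row plus per-sample i.i.d. substitutions and gaps.

    Each sample mutates each column with the background probability
    (hotspot probability inside hotspot intervals) to a uniformly chosen
    different base; gaps are inserted i.i.d.  Returns the matrix and the
    true hotspot intervals.
    """
    rng = np.random.default_rng(spec.seed)
    anc = _NT[rng.integers(0, 4, size=spec.n_columns)]
    rate = np.full(spec.n_columns, spec.background_rate)
    for s, e in spec.hotspots:
        rate[s:e] = spec.hotspot_rate
    rows = []
    for _ in range(spec.n_samples):
        row = anc.copy()
        mut = rng.random(spec.n_columns) < rate
        if mut.any():
            shift = rng.integers(1, 4, size=int(mut.sum()))
            idx = {int(b): k for k, b in enumerate(_NT)}
            cur = np.array([idx[int(b)] for b in row[mut]])
            row[mut] = _NT[(cur + shift) % 4]
        gaps = rng.random(spec.n_columns) < spec.gap_rate
        row = row.copy()
        row[gaps] = ord("-")
        rows.append(row.tobytes().decode())
    ids = [f"sample{k:02d}" for k in range(spec.n_samples)]
    return AlignmentMatrix(ids, rows), list(spec.hotspots)


def simulate_codon_alignment(tree, kappa: float,
                             omega_map: Mapping[int, float] | float,
                             freqs: CodonFrequencies, n_codons: int,
                             seed: int = 0,
                             foreground: Iterable[str] = ()) -> CodonAlignment:
    """Evolve codon sequences along a tree under GY94.

    Root codons are drawn from the equilibrium frequencies and each branch
    applies the transition matrix of its omega class for its length.
    """
    itree = tree if isinstance(tree, IndexedTree) else IndexedTree(tree, foreground)
    if isinstance(omega_map, (int, float)):
        omega_map = {0: float(omega_map), 1: float(omega_map)}
    rng = np.random.default_rng(seed)
    eigs = {c: _eigensystem(gy94_rates(kappa, w, freqs), freqs.pi)
            for c, w in omega_map.items()}
    nstate = freqs.pi.shape[0]
    states: dict[int, np.ndarray] = {
        itree.root: rng.choice(nstate, size=n_codons, p=freqs.pi)
    }
    # walk root -> leaves (reverse postorder)
    for i in reversed(range(itree.n_nodes)):
        if i == itree.root:
            continue
        parent_state = states[itree.parent[i]]
        p = _transition_matrix(eigs[itree.edge_class[i]], itree.lengths[i])
        p = p / p.sum(axis=1, keepdims=True)
        child = np.empty(n_codons, dtype=np.int64)
        for s in np.unique(parent_state):
            mask = parent_state == s
            child[mask] = rng.choice(nstate, size=int(mask.sum()), p=p[s])
        states[i] = child
    code = genetic_code(freqs.code.table_id)
    ids, mat = [], []
    for i in range(itree.n_nodes):
        if itree.labels[i] is not None:
            ids.append(itree.labels[i])
            mat.append(states[i])
    return CodonAlignment(ids, np.asarray(mat, dtype=np.int16), code)
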