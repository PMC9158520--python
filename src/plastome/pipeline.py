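"""End-to-end comparison over a directory of genomes.

Runs the structure, repeat, diversity and selection stages over the
configured inputs and writes the comparison report tables (TSV) plus a JSON
manifest recording the configuration, package version and seed.  Stage
failures are logged and isolated: the bundle notes skipped stages rather
than aborting the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .io_formats import read_alignment, read_fasta, read_genbank, read_newick, write_regions
from .structure import canonicalize, detect_inverted_repeats, junction_report, region_gc
from .repeats import count_ssrs, find_long_repeats, find_ssrs
from .diversity import merge_hotspots, name_region, sliding_windows
from .selection import fit_branch_model, lrt, CodonAlignment

log = logging.getLogger("plastome")

__all__ = ["RunConfig", "run_comparison"]


@dataclass
class RunConfig:
    """All knobs of one comparison run (defaults are the standard comparative-analysis settings)."""

    genomes: list[str] = field(default_factory=list)
    alignment: str | None = None
    ref_genome: str | None = None  # GenBank used to name hotspot regions
    ref_id: str | None = None
    codon_alignments: list[str] = field(default_factory=list)
    tree: str | None = None
    foreground: list[str] = field(default_factory=list)
    out_dir: str = "plastome_out"
    min_ir_len: int = 1000
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: {1: 11, 2: 6, 3: 5, 4: 4, 5: 3, 6: 3})
    repeat_min_len: int = 30
    win_len: int = 600
    step: int = 200
    pi_min: float = 0.01
    pis_min: int = 25
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")
        for name in ("min_ir_len", "repeat_min_len", "win_len", "step", "pis_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _load_genome(path: str):
    p = Path(path)
    if p.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
        return read_genbank(p)
    return read_fasta(p)[0]


def run_comparison(config: RunConfig) -> dict:
    """Execute every configured stage; returns the manifest dictionary."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": hashlib.md5(config_json.encode()).hexdigest(),
        "version": __version__,
        "python": platform.python_version(),
        "stages": {},
    }

    structure_rows, junction_rows, ssr_rows, repeat_rows = [], [], [], []
    for path in config.genomes:
        try:
            genome = _load_genome(path)
            part = detect_inverted_repeats(genome, config.min_ir_len)
            gc = region_gc(genome, part)
            canon = canonicalize(genome, part)
            lsc, ssc, ir = part.lengths()
            structure_rows.append(
                (genome.id, part.n, lsc, ssc, ir) + gc.rounded()
            )
            for j in junction_report(part, canon.features):
                junction_rows.append((genome.id, j.junction, j.position,
                                      j.gene or "NA",
                                      j.offset if j.offset is not None else "NA"))
            ssrs = find_ssrs(genome, config.ssr_thresholds, partition=part)
            for r in ssrs:
                ssr_rows.append((genome.id, r.ssr_type, r.motif, r.copies,
                                 r.start, r.end, r.region))
            for r in find_long_repeats(genome, part, config.repeat_min_len):
                repeat_rows.append((genome.id, r.repeat_class, r.length,
                                    r.pos1, r.pos2, *r.regions))
            log.info("%s: LSC=%d SSC=%d IR=%d, %d SSRs", genome.id, lsc, ssc,
                     ir, count_ssrs(ssrs))
        except Exception as exc:  # noqa: BLE001 - stage isolation by design
            log.error("genome %s failed: %s", path, exc)
            manifest["stages"].setdefault("failed_genomes", []).append(
                {"path": str(path), "error": str(exc)})

    _write_tsv(out / "structure.tsv",
               ("accession", "total", "LSC", "SSC", "IR",
                "GC_total", "GC_LSC", "GC_SSC", "GC_IR"), structure_rows)
    _write_tsv(out / "junctions.tsv",
               ("accession", "junction", "position", "gene", "offset"),
               junction_rows)
    _write_tsv(out / "ssrs.tsv",
               ("accession", "type", "motif", "copies", "start", "end", "region"),
               ssr_rows)
    _write_tsv(out / "repeats.tsv",
               ("accession", "class", "length", "pos1", "pos2",
                "region1", "region2"), repeat_rows)
    manifest["stages"]["structure"] = {"n_genomes": len(structure_rows)}

    if config.alignment:
        try:
            aln = read_alignment(config.alignment)
            windows = sliding_windows(aln, config.win_len, config.step)
            _write_tsv(out / "windows.tsv",
                       ("start", "end", "midpoint", "pi", "n_pis", "n_singleton"),
                       [(w.start, w.end, w.midpoint,
                         "NA" if w.pi is None else f"{w.pi:.8f}",
                         w.n_pis, w.n_singleton) for w in windows])
            regions = merge_hotspots(windows, aln, config.pi_min, config.pis_min)
            if config.ref_genome and config.ref_id:
                ref = read_genbank(config.ref_genome)
                regions = [
                    type(r)(r.start, r.end, r.length, r.n_svs, r.n_pip, r.pi,
                            name_region(r, ref, aln, config.ref_id))
                    for r in regions
                ]
            write_regions(regions, out / "hotspots.tsv", dialect="tsv")
            manifest["stages"]["diversity"] = {
                "n_windows": len(windows), "n_regions": len(regions)}
        except Exception as exc:  # noqa: BLE001
            log.error("diversity stage failed: %s", exc)
            manifest["stages"]["diversity"] = {"skipped": str(exc)}
    else:
        log.warning("no alignment configured; diversity stage skipped")
        manifest["stages"]["diversity"] = {"skipped": "no alignment"}

    if config.codon_alignments and config.tree:
        rows = []
        tree = read_newick(config.tree)
        for path in config.codon_alignments:
            gene = Path(path).stem
            try:
                from Bio import SeqIO

                recs = [(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]
                caln = CodonAlignment.from_dna_rows([r[0] for r in recs],
                                                    [r[1] for r in recs])
                null = fit_branch_model(caln, tree, config.foreground,
                                        model="one_ratio", seed=config.seed)
                alt = fit_branch_model(caln, tree, config.foreground,
                                       model="two_ratio", seed=config.seed,
                                       init=null)
                res = lrt(null, alt, config.alpha)
                verdict = ("positive_selection" if res.positive_selection
                           else "fast_evolving" if res.fast_evolving
                           else "significant" if res.significant else "ns")
                rows.append((gene, f"{null.lnL:.4f}", f"{alt.lnL:.4f}",
                             f"{null.omega0:.4f}",
                             f"{alt.omega_background:.4f}",
                             f"{alt.omega_foreground:.4f}",
                             f"{res.statistic:.4f}", f"{res.p_value:.4g}",
                             verdict))
            except Exception as exc:  # noqa: BLE001
                log.error("selection stage failed for %s: %s", gene, exc)
                rows.append((gene,) + ("NA",) * 7 + (f"error: {exc}",))
        _write_tsv(out / "lrt.tsv",
                   ("gene", "lnL0", "lnL1", "omega0", "omega_b", "omega_f",
                    "2dlnL", "p", "verdict"), rows)
        manifest["stages"]["selection"] = {"n_genes": len(rows)}
    else:
        manifest["stages"]["selection"] = {"skipped": "no codon alignments/tree"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


def _write_tsv(path: Path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
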