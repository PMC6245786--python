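"""End-to-end orchestration: simulate/load -> qc -> map -> annotate -> report.

Every stage writes its output under a stage-stamped filename in the run
directory, every removed record is attributable to exactly one named rule
in the JSON tally, and the whole run is deterministic given the seed.  A
run that finds no credible linkage peak is reported distinctly
(``status = "no_linkage"``) from a failing run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import bundle as bundle_mod
from .annotate import annotate_all, load_transcripts
from .candidates import CandidateReport, KnownSites, build_candidate_report
from .cross import GenomeSpec, PoolSpec
from .loess import LoessConfig
from .mapping import (
    ChromScore,
    CriticalRegion,
    WindowStats,
    extract_linked_variants,
    map_linkage,
)
from .qc import QcConfig, apply_hard_filters
from .variants import MUTANT, read_vcf, write_vcf

log = logging.getLogger("homozymap")


@dataclass
class MappingConfig:
    window_size: int = 1_000_000
    step: int = 500_000
    pseudocount: float = 1.0
    span: float = 0.3
    degree: int = 1
    iterations: int = 0
    threshold_frac: float = 0.95
    min_fit_floor: float = 1.5
    informative_only: bool = False

    @property
    def loess(self) -> LoessConfig:
        return LoessConfig(span=self.span, degree=self.degree,
                           iterations=self.iterations)


@dataclass
class PipelineConfig:
    """Full configuration of one run; round-trips through YAML."""

    seed: int = 0
    simulate: bool = True
    # simulated-study design
    n_chromosomes: int = 25
    chrom_length: int = 50_000_000
    marker_density: float = 2.0
    causal_site: list | None = field(
        default_factory=lambda: ["chr13", 29_288_858, "A", "T"]
    )
    cm_per_mb: float = 2.0
    n_mutants: int = 40
    n_siblings: int = 40
    mean_depth_mutant: float = 9.0
    mean_depth_sibling: float = 8.0
    base_error: float = 0.01
    known_fraction: float = 0.25
    # real-data inputs (used when simulate is false)
    vcf: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    known: str | None = None
    # stage parameters
    min_gq: int = 5
    biallelic_only: bool = True
    drop_missing: bool = True
    require_pass: bool = True
    mapping: MappingConfig = field(default_factory=MappingConfig)
    verbosity: str = "INFO"

    @property
    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec(
            chromosomes=tuple(
                (f"chr{i}", self.chrom_length)
                for i in range(1, self.n_chromosomes + 1)
            ),
            marker_density=self.marker_density,
            causal_site=tuple(self.causal_site) if self.causal_site else None,
            seed=self.seed,
            cm_per_mb=self.cm_per_mb,
        )

    @property
    def pool_spec(self) -> PoolSpec:
        return PoolSpec(
            n_mutants=self.n_mutants,
            n_siblings=self.n_siblings,
            mean_depth_mutant=self.mean_depth_mutant,
            mean_depth_sibling=self.mean_depth_sibling,
            base_error=self.base_error,
        )

    @property
    def qc_config(self) -> QcConfig:
        return QcConfig(
            min_gq=self.min_gq,
            biallelic_only=self.biallelic_only,
            drop_missing=self.drop_missing,
            require_pass=self.require_pass,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("mapping"), dict):
            d["mapping"] = MappingConfig(**d["mapping"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    status: str  # "ok" | "no_linkage"
    candidate_chrom: str | None = None
    region: CriticalRegion | None = None
    scores: list[ChromScore] = field(default_factory=list)
    windows: list[WindowStats] = field(default_factory=list)
    fitted: np.ndarray | None = None
    report: CandidateReport | None = None
    qc_counts: dict[str, int] = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)


def _write_scores_tsv(scores: list[ChromScore], path: Path) -> None:
    lines = ["chrom\trole\tn_hom_alt\tn_het\tn_hom_ref\tn_total\thomozygosity_score"]
    for s in scores:
        val = "" if s.homozygosity_score is None else f"{s.homozygosity_score:.6f}"
        lines.append(
            f"{s.chrom}\t{s.role}\t{s.n_hom_alt}\t{s.n_het}\t{s.n_hom_ref}\t"
            f"{s.n_total}\t{val}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_windows_tsv(windows: list[WindowStats], fitted, path: Path) -> None:
    lines = ["chrom\tstart\tend\tcenter\tn\tn_hom\tn_het\tfrac_hom\tfrac_het\tratio\tloess"]
    for w, f in zip(windows, fitted):
        # reported 1-based inclusive
        lines.append(
            f"{w.chrom}\t{w.start + 1}\t{w.end}\t{w.center:.1f}\t{w.n}\t{w.n_hom}\t"
            f"{w.n_het}\t{w.frac_hom:.6f}\t{w.frac_het:.6f}\t{w.ratio:.6f}\t{f:.6f}"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_region(region: CriticalRegion, bed_path: Path, txt_path: Path) -> None:
    # BED is 0-based half-open
    bed_path.write_text(
        f"{region.chrom}\t{region.start - 1}\t{region.end}\tcritical_region\t"
        f"{region.peak_value:.4f}\n"
    )
    txt_path.write_text(
        f"critical region: {region.chrom}:{region.start:,}-{region.end:,} "
        f"({region.width / 1e6:.2f} Mb)\n"
        f"peak: {region.chrom}:{region.peak_pos:,} "
        f"(smoothed hom/het ratio {region.peak_value:.3f})\n"
        f"threshold: {region.threshold_frac:.2f} of peak\n"
    )


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run every stage; returns the result object with all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity, logging.INFO))
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(fh)
    paths: dict[str, Path] = {}
    try:
        cfg.to_yaml(outdir / "config.yaml")
        paths["config"] = outdir / "config.yaml"
        log.info("configuration: %s", json.dumps(cfg.to_dict(), default=str))

        # ---- stage 1: inputs -------------------------------------------
        if cfg.simulate:
            study = bundle_mod.simulate_study(
                genome=cfg.genome_spec,
                pools=cfg.pool_spec,
                known_fraction=cfg.known_fraction,
            )
            stage_dir = outdir
            bpaths = bundle_mod.write_bundle(study, stage_dir)
            paths.update({f"01_{k}": v for k, v in bpaths.items()})
            records = study.records
            transcripts = study.transcripts
            genome_seq: Any = study.sequences
            known = study.known
        else:
            if not cfg.vcf:
                raise ValueError("simulate is false and no input VCF given")
            records = read_vcf(cfg.vcf)
            transcripts = []
            genome_seq = None
            if cfg.gff3 and cfg.fasta:
                import pyfaidx

                genome_seq = pyfaidx.Fasta(cfg.fasta)
                transcripts = load_transcripts(cfg.gff3, genome_seq)
            known = KnownSites.from_file(cfg.known) if cfg.known else KnownSites.empty()
        log.info("stage 1: %d variant records", len(records))

        # ---- stage 2: hard filters -------------------------------------
        qc_records, qc_counts = apply_hard_filters(records, cfg.qc_config)
        contigs = (
            list(cfg.genome_spec.chromosomes) if cfg.simulate else None
        )
        paths["02_qc_vcf"] = outdir / "02_qc.vcf"
        write_vcf(qc_records, paths["02_qc_vcf"], contigs=contigs)
        log.info(
            "stage 2: %d records retained; removed by rule: %s",
            len(qc_records), qc_counts,
        )

        # ---- stage 3: linkage mapping ----------------------------------
        m = cfg.mapping
        scores, chrom, windows, fitted, region = map_linkage(
            qc_records,
            window_size=m.window_size,
            step=m.step,
            pseudocount=m.pseudocount,
            loess_cfg=m.loess,
            threshold_frac=m.threshold_frac,
            min_fit_floor=m.min_fit_floor,
            informative_only=m.informative_only,
        )
        paths["03_scores"] = outdir / "03_chrom_scores.tsv"
        _write_scores_tsv(scores, paths["03_scores"])
        paths["03_windows"] = outdir / "03_windows.tsv"
        _write_windows_tsv(windows, fitted, paths["03_windows"])
        log.info("stage 3: candidate chromosome %s", chrom)
        if region is None:
            log.warning("no linkage detected (smoothed peak below floor)")
            _write_tally(outdir, paths, qc_counts, None, None)
            return PipelineResult(
                status="no_linkage", candidate_chrom=chrom, scores=scores,
                windows=windows, fitted=fitted, qc_counts=qc_counts, paths=paths,
            )
        paths["03_region_bed"] = outdir / "03_region.bed"
        paths["03_region_txt"] = outdir / "03_region.txt"
        _write_region(region, paths["03_region_bed"], paths["03_region_txt"])
        log.info(
            "stage 3: critical region %s:%d-%d (%.2f Mb)",
            region.chrom, region.start, region.end, region.width / 1e6,
        )

        # ---- stage 4: linked-variant extraction ------------------------
        linked = extract_linked_variants(qc_records, region)
        paths["04_linked_vcf"] = outdir / "04_linked.vcf"
        write_vcf(linked, paths["04_linked_vcf"], contigs=contigs)
        log.info("stage 4: %d linked variants in the region", len(linked))

        # ---- stage 5: annotation + candidate cascade -------------------
        snvs = [r for r in linked if r.is_snv]
        annotated = annotate_all(snvs, transcripts, genome_seq)
        report = build_candidate_report(annotated, known=known)
        paths["05_candidates"] = outdir / "05_candidates.tsv"
        report.to_tsv(paths["05_candidates"])
        _write_tally(outdir, paths, qc_counts, report, region)
        log.info("stage 5: %s", report.summary())

        return PipelineResult(
            status="ok", candidate_chrom=chrom, region=region, scores=scores,
            windows=windows, fitted=fitted, report=report, qc_counts=qc_counts,
            paths=paths,
        )
    finally:
        log.removeHandler(fh)
        fh.close()


def _write_tally(outdir: Path, paths: dict, qc_counts: dict,
                 report: CandidateReport | None,
                 region: CriticalRegion | None) -> None:
    tally: dict[str, Any] = {"qc_removed": qc_counts}
    if region is not None:
        tally["region"] = {
            "chrom": region.chrom, "start": region.start, "end": region.end,
            "peak_pos": region.peak_pos, "peak_value": region.peak_value,
            "threshold_frac": region.threshold_frac,
        }
    if report is not None:
        tally["cascade"] = report.tally
    paths["05_tally"] = outdir / "05_tally.json"
    paths["05_tally"].write_text(json.dumps(tally, indent=2) + "\n")


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------


def make_figures(
    scores: list[ChromScore],
    windows: list[WindowStats],
    fitted,
    region: CriticalRegion | None,
    outdir: str | Path,
) -> list[Path]:
    """Per-chromosome score plot and candidate-chromosome ratio + fit plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .variants import SIBLING, natural_key

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # figure 1: homozygosity score per chromosome, both samples
    chroms = sorted({s.chrom for s in scores}, key=natural_key)
    fig, ax = plt.subplots(figsize=(10, 4))
    x = np.arange(len(chroms))
    for role, color, dx in ((MUTANT, "crimson", -0.17), (SIBLING, "steelblue", 0.17)):
        vals = []
        for c in chroms:
            sc = next(
                (s.homozygosity_score for s in scores
                 if s.chrom == c and s.role == role), None)
            vals.append(np.nan if sc is None else sc)
        ax.bar(x + dx, vals, width=0.34, color=color, label=role)
    ax.set_xticks(x)
    ax.set_xticklabels(chroms, rotation=90, fontsize=7)
    ax.set_ylabel("homozygosity score")
    ax.legend()
    fig.tight_layout()
    p1 = outdir / "fig_chromosome_scores.png"
    fig.savefig(p1, dpi=120)
    plt.close(fig)

    # figure 2: windowed hom/het ratio with LOESS overlay and region markers
    fig, ax = plt.subplots(figsize=(8, 4))
    if windows:
        xs = np.array([w.center for w in windows]) / 1e6
        ys = np.array([w.ratio for w in windows])
        ax.plot(xs, ys, ".", color="grey", ms=4, label="window ratio")
        ax.plot(xs, np.asarray(fitted), "-", color="steelblue", lw=2, label="LOESS fit")
        if region is not None:
            ax.axvspan(region.start / 1e6, region.end / 1e6, color="gold",
                       alpha=0.25, label="critical region")
            ax.axvline(region.peak_pos / 1e6, color="red", ls=":", lw=1.5,
                       label="peak")
        ax.set_xlabel(f"{windows[0].chrom} position (Mb)")
        ax.set_ylabel("(hom + c) / (het + c)")
        ax.legend(fontsize=8)
    else:
        ax.text(0.5, 0.5, "no data", ha="center", va="center",
                transform=ax.transAxes)
    fig.tight_layout()
    p2 = outdir / "fig_ratio_fit.png"
    fig.savefig(p2, dpi=120)
    plt.close(fig)
    return [p1, p2]
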