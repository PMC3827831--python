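"""End-to-end orchestration: simulate -> call domains -> call CpGs -> score -> compare.

A :class:`RunConfig` bundles the generator configuration, the H/L/G caller
parameters, the scoring thresholds and the statistical settings.  One seeded
generator hierarchy (stage-indexed substreams) drives every stochastic stage,
so identical configuration plus seed reproduces byte-identical outputs; each
output file carries a header comment with the package version, a hash of the
configuration and the seed.

Stage layout of :func:`run_pipeline` (files written under ``outdir``):

========  =====================================================================
simulate  genome.fa, genes.gff3, truth_domains.bed, capseq_input.bed,
          capseq_cxxc.bed, bsseq_muscle_like.tsv, expression_classes.tsv
domains   input_covered.bed, cxxc_covered.bed, methylated_domains.bed
cpg       called_sites_muscle_like.tsv (binomial calls with the control-contig
          error model)
score     genes_sperm_domain_overlap.tsv, genes_muscle_cpg_fraction.tsv
compare   contingency.tsv, joint_degrees.tsv (+ r and permutation p in report)
enrich    enrichment.tsv
========  =====================================================================

plus ``report.json`` with per-stage record counts, parameters and sha256
digests of every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__
from .core import (
    pileup_coverage,
    write_bed,
    write_bed_records,
    write_expression_classes,
    write_fasta,
    write_gff3,
)
from .domains import DomainCallParams, call_covered_regions, call_methylated_domains
from .methylation import call_sites, estimate_error_rate, write_called_sites, write_cytosine_report
from .scores import (
    ScoreConfig,
    records_to_frame,
    score_genes_cpg_fraction,
    score_genes_domain_overlap,
    write_gene_records,
)
from .simulate import (
    SimulationConfig,
    build_synthetic_genome,
    simulate_bsseq,
    simulate_capseq,
    simulate_expression_classes,
)
from .stats import build_contingency, class_enrichment, joint_degree_distribution, permutation_test_r

logger = logging.getLogger("mosaicmeth")

__all__ = ["RunConfig", "PipelineError", "validate_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class RunConfig:
    outdir: str = "mosaicmeth_run"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    domain_params: DomainCallParams = field(default_factory=DomainCallParams)
    score: ScoreConfig = field(default_factory=ScoreConfig)
    alpha: float = 0.01
    n_perm: int = 10_000
    seed: int | None = None  # overrides sim.seed when set
    tissue_a: str = "sperm_like"  # CAP-seq / domain-overlap tissue
    tissue_b: str = "muscle_like"  # BS-seq / CpG-fraction tissue

    @property
    def effective_seed(self) -> int:
        return int(self.sim.seed if self.seed is None else self.seed)

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "sim": self.sim.to_dict(),
            "domain_params": self.domain_params.to_dict(),
            "score": dataclasses.asdict(self.score),
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "tissue_a": self.tissue_a,
            "tissue_b": self.tissue_b,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        sim = SimulationConfig.from_dict(d.pop("sim", {}))
        domain = DomainCallParams.from_dict(d.pop("domain_params", {}))
        score = ScoreConfig(**d.pop("score", {}))
        return cls(sim=sim, domain_params=domain, score=score, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # hash the analysis, not where it is written
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(config) -> list[str]:
    """Collect human-readable issues; never raises.

    Accepts a :class:`RunConfig` or a raw mapping (e.g. parsed YAML before
    construction, so threshold-ordering problems can be reported instead of
    thrown).
    """
    issues: list[str] = []
    if isinstance(config, RunConfig):
        issues.extend(config.sim.validate())
        if config.alpha <= 0 or config.alpha >= 1:
            issues.append(f"alpha={config.alpha} outside (0, 1)")
        if config.n_perm < 1:
            issues.append(f"n_perm={config.n_perm} must be >= 1")
        return issues

    d = dict(config or {})
    score = d.get("score", {})
    lo, hi = score.get("lo", 0.1), score.get("hi", 0.9)
    if not lo < hi:
        issues.append(f"lo must be < hi (got lo={lo}, hi={hi})")
    try:
        sim = SimulationConfig.from_dict(d.get("sim", {}))
    except TypeError as exc:
        issues.append(f"sim config: {exc}")
    else:
        issues.extend(sim.validate())
    try:
        DomainCallParams.from_dict(d.get("domain_params", {}))
    except (TypeError, ValueError) as exc:
        issues.append(f"domain_params: {exc}")
    alpha = d.get("alpha", 0.01)
    if not 0 < alpha < 1:
        issues.append(f"alpha={alpha} outside (0, 1)")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Stage:
    """Context manager: logs wall time, converts errors, renames partial outputs."""

    def __init__(self, name: str, outdir: Path, report: dict):
        self.name, self.outdir, self.report = name, outdir, report
        self.files: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / name
        self.files.append(p)
        return p

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        if exc is None:
            self.report.setdefault("stages", {})[self.name] = {
                "seconds": round(elapsed, 3),
                "outputs": [f.name for f in self.files],
            }
            logger.info("stage %s: done in %.2fs", self.name, elapsed)
            return False
        for f in self.files:  # keep partial outputs, clearly marked
            if f.exists():
                f.rename(f.with_suffix(f.suffix + ".partial"))
        if isinstance(exc, PipelineError):
            return False
        raise PipelineError(self.name, str(exc)) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run report."""
    issues = validate_config(config)
    if issues:
        raise PipelineError("validate", "; ".join(issues))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.effective_seed
    sim_cfg = dataclasses.replace(config.sim, seed=seed)
    chash = dataclasses.replace(config, sim=sim_cfg).config_hash()
    header = f"mosaicmeth {__version__} config={chash} seed={seed}"
    report: dict = {"version": __version__, "seed": seed, "config_hash": chash}

    with _Stage("simulate", outdir, report) as st:
        genome = build_synthetic_genome(sim_cfg)
        input_reads, cxxc_reads = simulate_capseq(genome, genome.truth, sim_cfg)
        bsseq_b = simulate_bsseq(genome, genome.truth, sim_cfg, config.tissue_b)
        classes = simulate_expression_classes(genome.genes, genome.truth, sim_cfg)
        sim_cfg.to_yaml(st.path("config.yaml"))
        write_fasta(genome.sequences, st.path("genome.fa"))
        write_gff3(genome.genes, st.path("genes.gff3"), header_extra=header)
        write_bed(genome.truth.domains, st.path("truth_domains.bed"), header=header)
        write_bed_records(input_reads, st.path("capseq_input.bed"), header=header)
        write_bed_records(cxxc_reads, st.path("capseq_cxxc.bed"), header=header)
        write_cytosine_report(bsseq_b, st.path(f"bsseq_{config.tissue_b}.tsv"), header=header)
        write_expression_classes(
            dict(zip(classes["gene_id"], classes["expression_class"])),
            st.path("expression_classes.tsv"),
            header=header,
        )
        report["simulate"] = {
            "n_genes": len(genome.genes),
            "n_methylated_true": len(genome.truth.methylated_genes),
            "n_true_domains": genome.truth.domains.n_intervals(),
            "n_input_reads": int(sum(len(v) for v in input_reads.values())),
            "n_cxxc_reads": int(sum(len(v) for v in cxxc_reads.values())),
            "n_cytosine_sites": int(len(bsseq_b)),
        }

    with _Stage("domains", outdir, report) as st:
        input_track = pileup_coverage(input_reads, genome.layout)
        cxxc_track = pileup_coverage(cxxc_reads, genome.layout)
        input_covered = call_covered_regions(input_track, config.domain_params)
        cxxc_covered = call_covered_regions(cxxc_track, config.domain_params)
        domains = call_methylated_domains(input_covered, cxxc_covered)
        write_bed(input_covered, st.path("input_covered.bed"), header=header)
        write_bed(cxxc_covered, st.path("cxxc_covered.bed"), header=header)
        write_bed(domains, st.path("methylated_domains.bed"), header=header)
        report["domains"] = {
            "params": config.domain_params.to_dict(),
            "input_covered_bp": input_covered.total_bp,
            "cxxc_covered_bp": cxxc_covered.total_bp,
            "methylated_domain_bp": domains.total_bp,
            "n_methylated_domains": domains.n_intervals(),
        }

    with _Stage("cpg", outdir, report) as st:
        control = genome.layout.control_contig
        control_sites = bsseq_b[bsseq_b["contig"] == control]
        error_model = estimate_error_rate(control_sites)
        called = call_sites(
            bsseq_b,
            error_model.error_rate,
            alpha=config.alpha,
            min_coverage=config.score.min_site_coverage,
        )
        write_called_sites(called, st.path(f"called_sites_{config.tissue_b}.tsv"), header=header)
        report["cpg"] = {
            "error_rate": error_model.error_rate,
            "n_control_sites": error_model.n_control_sites,
            "n_control_observations": error_model.n_control_observations,
            "alpha": config.alpha,
            "n_sites_called_methylated": int((called["call"] == "methylated").sum()),
        }

    with _Stage("score", outdir, report) as st:
        rec_a = score_genes_domain_overlap(
            genome.genes, domains, input_covered=input_covered, config=config.score
        )
        rec_b = score_genes_cpg_fraction(genome.genes, called, config=config.score)
        write_gene_records(rec_a, st.path(f"genes_{config.tissue_a}_domain_overlap.tsv"), header)
        write_gene_records(rec_b, st.path(f"genes_{config.tissue_b}_cpg_fraction.tsv"), header)
        frame_a, frame_b = records_to_frame(rec_a), records_to_frame(rec_b)
        report["score"] = {
            tissue: {
                "eligible": int(frame["eligible"].sum()),
                "methylated": int((frame["meth_class"] == "methylated").sum()),
                "unmethylated": int((frame["meth_class"] == "unmethylated").sum()),
                "intermediate": int((frame["meth_class"] == "intermediate").sum()),
            }
            for tissue, frame in ((config.tissue_a, frame_a), (config.tissue_b, frame_b))
        }

    with _Stage("compare", outdir, report) as st:
        el_a = frame_a[frame_a["eligible"]].set_index("gene_id")
        el_b = frame_b[frame_b["eligible"]].set_index("gene_id")
        if (
            report["score"][config.tissue_a]["methylated"] == 0
            and report["score"][config.tissue_b]["methylated"] == 0
        ):
            raise PipelineError("compare", "no methylated genes in either tissue")
        deg_a = el_a["degree"].to_dict()
        deg_b = el_b["degree"].to_dict()
        shared = sorted(set(deg_a) & set(deg_b))
        x = np.array([deg_a[g] for g in shared])
        y = np.array([deg_b[g] for g in shared])
        perm_seed = int(np.random.default_rng([5, seed]).integers(2**31))
        r, p = permutation_test_r(x, y, n_perm=config.n_perm, seed=perm_seed)
        table = build_contingency(
            el_a["meth_class"].to_dict(), el_b["meth_class"].to_dict()
        )
        joint = joint_degree_distribution(deg_a, deg_b, n_bins=10)
        with open(st.path("contingency.tsv"), "w") as fh:
            fh.write(f"# {header}\n")
            table.to_frame().to_csv(fh, sep="\t")
        np.savetxt(
            st.path("joint_degrees.tsv"), joint, fmt="%d", delimiter="\t", header=header
        )
        report["compare"] = {
            "n_matched": len(shared),
            "pearson_r": r,
            "permutation_p": p,
            "n_perm": config.n_perm,
            "contingency": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
            "discordant_fraction": table.discordant_fraction,
        }

    with _Stage("enrich", outdir, report) as st:
        meth_cls = frame_a.set_index("gene_id")["meth_class"].to_dict()
        expr_cls = dict(zip(classes["gene_id"], classes["expression_class"]))
        results = class_enrichment(meth_cls, expr_cls)
        with open(st.path("enrichment.tsv"), "w") as fh:
            fh.write(f"# {header}\n")
            fh.write("# class\tn_genes\tfold_enrichment\tp_raw\tp_bonferroni\n")
            for res in results:
                fh.write(
                    f"{res.expression_class}\t{res.n_genes}\t{res.fold_enrichment:.6g}\t"
                    f"{res.p_raw:.6g}\t{res.p_bonferroni:.6g}\n"
                )
        report["enrich"] = [dataclasses.asdict(r) for r in results]

    report["digests"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "report.json"
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
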