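"""End-to-end chip-to-panel workflow orchestration.

``run_pipeline`` sequences the stages — (optional) simulation, QC, DAPC with
cross-validation, panel selection, simulated capture re-genotyping of the
panel, concordance/coverage evaluation, and kinship on both the dense and the
reduced panel — writing every intermediate artifact, a parameter echo, and a
run manifest with content hashes so a rerun can be verified byte for byte.

Configuration is one YAML file (see :class:`RunConfig`); CLI flags override
config values (flag > file > default).  All logging goes to stderr and to a
``run.log`` in the output directory; every source of randomness derives from
the single top-level seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .dataio import (
    GenotypeDataset,
    load_genotypes,
    read_pop_labels,
    write_pop_labels,
    write_vcf,
)
from .evaluate import classify_offtarget, concordance, coverage_profile
from .kinship import DEFAULT_DEGREE_THRESHOLDS, compare_kinship, pcrelate
from .panel import select_panel, summarize_panel
from .qc import run_qc
from .structure import crossvalidate_dapc, default_k_grid, fit_dapc
from .synthetic_data import (
    PedigreeDesign,
    SimConfig,
    sim_seq_artifacts,
    sim_study,
    write_truth_table,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("panelforge")


@dataclass
class RunConfig:
    """All stage toggles and parameters of one pipeline run."""

    out_dir: str = "panelforge_run"
    seed: int = 0

    # inputs; when vcf is None the simulation stage provides the data
    vcf: str | None = None
    labels: str | None = None
    simulate: dict = field(default_factory=dict)  # SimConfig field overrides
    pedigree: dict | None = None  # PedigreeDesign field overrides

    # stage toggles
    do_qc: bool = True
    do_xval: bool = True
    do_select: bool = True
    do_capture: bool = True
    do_evaluate: bool = True
    do_kinship: bool = True

    # qc
    max_sample_miss: float = 0.10
    max_marker_miss: float = 0.10
    min_maf: float = 0.05
    ld_window_bp: int = 1000
    ld_step: int = 1
    ld_r2: float = 0.5
    min_gq: int = 30
    min_mean_dp: float = 10.0

    # dapc / xval
    k_grid: list[int] | None = None
    n_pcs: int | None = None  # used when do_xval is False
    n_rep: int = 100
    train_frac: float = 0.9

    # panel selection
    percentile: float = 95.0
    n_axes: int = 2
    exclude_chroms: list[str] = field(default_factory=lambda: ["MT"])
    probe_length: int = 120

    # evaluation
    near_bp: int = 150
    coverage_thresholds: list[int] | None = None

    # kinship
    kinship_pcs: int = 2
    degree_thresholds: tuple[float, float, float] = DEFAULT_DEGREE_THRESHOLDS

    def __post_init__(self) -> None:
        self.degree_thresholds = tuple(self.degree_thresholds)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["degree_thresholds"] = list(self.degree_thresholds)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def validate(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")
        if self.vcf is None and self.simulate is None:
            raise ValueError("either an input VCF or a simulation block is required")
        t1, t2, t3 = self.degree_thresholds
        if not t1 > t2 > t3 > 0:
            raise ValueError("degree_thresholds must be strictly decreasing, positive")

    def sim_config(self) -> SimConfig:
        return SimConfig(**{"seed": self.seed, **self.simulate})

    def pedigree_design(self) -> PedigreeDesign | None:
        return None if self.pedigree is None else PedigreeDesign(**self.pedigree)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(out: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(out / "run.log", mode="w")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in fixed order and return the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    outputs: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = str(path.relative_to(out))

    config.to_yaml(out / "params.yaml")
    emit("params", out / "params.yaml")

    # ---- input / simulation ------------------------------------------
    truth = None
    if config.vcf is not None:
        log.info("reading genotypes from %s", config.vcf)
        ds = load_genotypes(config.vcf)
        if config.labels:
            ds = read_pop_labels(config.labels, ds)
    else:
        sim = config.sim_config()
        log.info(
            "simulating study data: %d pops, F=%.3g, %d markers, seed=%d",
            sim.n_pops, sim.fst, sim.n_markers, sim.seed,
        )
        ds, _freqs, truth = sim_study(sim, config.pedigree_design())
        write_vcf(ds, out / "chip.vcf")
        write_pop_labels(ds, out / "chip_pops.tsv")
        emit("chip_vcf", out / "chip.vcf")
        emit("chip_labels", out / "chip_pops.tsv")
        if truth is not None:
            write_truth_table(truth, out / "pedigree_truth.tsv")
            emit("pedigree_truth", out / "pedigree_truth.tsv")

    # ---- QC -----------------------------------------------------------
    if config.do_qc:
        has_quality = ds.GQ is not None and ds.DP is not None
        ds_qc, reports = run_qc(
            ds,
            max_sample_miss=config.max_sample_miss,
            max_marker_miss=config.max_marker_miss,
            min_maf=config.min_maf,
            ld_window_bp=config.ld_window_bp,
            ld_step=config.ld_step,
            ld_r2=config.ld_r2,
            min_gq=config.min_gq if has_quality else None,
            min_mean_dp=config.min_mean_dp if has_quality else None,
        )
        with open(out / "qc_report.txt", "w") as fh:
            for rep in reports:
                fh.write(rep.to_text() + "\n")
        emit("qc_report", out / "qc_report.txt")
        write_vcf(ds_qc, out / "chip_filtered.vcf")
        emit("chip_filtered_vcf", out / "chip_filtered.vcf")
        for rep in reports:
            log.info(rep.to_text())
    else:
        ds_qc = ds

    # ---- DAPC + cross-validation -------------------------------------
    if config.do_xval:
        grid = config.k_grid or default_k_grid(ds_qc)
        log.info("cross-validating DAPC over K grid %s (%d reps)", grid, config.n_rep)
        xval = crossvalidate_dapc(
            ds_qc, grid, n_rep=config.n_rep, train_frac=config.train_frac, seed=config.seed
        )
        xval.write(out / "xval_report.tsv")
        emit("xval_report", out / "xval_report.tsv")
        chosen_k = xval.chosen_k
        log.info(
            "chosen K=%d, mean success %.4f", chosen_k, xval.mean_success_at_chosen
        )
    else:
        if config.n_pcs is None:
            raise ValueError("n_pcs must be given when cross-validation is disabled")
        xval = None
        chosen_k = config.n_pcs
        log.info("cross-validation disabled; using configured K=%d", chosen_k)

    dapc = fit_dapc(ds_qc, chosen_k)
    (out / "dapc_summary.txt").write_text(dapc.summary() + "\n")
    emit("dapc_summary", out / "dapc_summary.txt")
    assign = dapc.predict(ds_qc)
    post = dapc.posterior(ds_qc)
    table = post.copy()
    table.insert(0, "assigned", assign)
    table.to_csv(out / "assignments.tsv", sep="\t", index_label="sample")
    emit("assignments", out / "assignments.tsv")

    manifest: dict = {
        "package": "panelforge",
        "version": __version__,
        "seed": config.seed,
        "chosen_k": chosen_k,
    }
    if xval is not None:
        manifest["xval_mean_success"] = xval.mean_success_at_chosen

    # ---- panel selection ---------------------------------------------
    panel = None
    if config.do_select:
        panel = select_panel(
            dapc,
            percentile=config.percentile,
            n_axes=min(config.n_axes, dapc.n_axes),
            exclude_chroms=set(config.exclude_chroms),
            probe_length=config.probe_length,
        )
        log.info(
            "selected %d panel markers (%d dropped on excluded chromosomes)",
            panel.n_markers, panel.n_excluded_by_chrom,
        )
        panel.write_table(out / "panel.tsv")
        panel.write_bed(out / "panel.bed")
        emit("panel_table", out / "panel.tsv")
        emit("panel_bed", out / "panel.bed")
        summ = summarize_panel(panel)
        (out / "panel_summary.txt").write_text(summ.to_text() + "\n")
        emit("panel_summary", out / "panel_summary.txt")
        manifest["panel_markers"] = panel.n_markers

    # ---- simulated capture of the panel ------------------------------
    capture = None
    if config.do_capture and panel is not None and config.vcf is None:
        sim = config.sim_config()
        rng = np.random.default_rng(sim.seed + 1)
        capture_raw = ds.restrict_to_keys(panel.marker_keys())
        capture_raw, depth = sim_seq_artifacts(capture_raw, sim, rng)
        depth.to_csv(out / "capture_depth.tsv", sep="\t")
        emit("capture_depth", out / "capture_depth.tsv")
        capture, cap_reports = run_qc(
            capture_raw,
            max_sample_miss=config.max_sample_miss,
            max_marker_miss=config.max_marker_miss,
            min_maf=config.min_maf,
            min_gq=config.min_gq,
            min_mean_dp=config.min_mean_dp,
            skip_ld=True,
        )
        with open(out / "capture_qc_report.txt", "w") as fh:
            for rep in cap_reports:
                fh.write(rep.to_text() + "\n")
        emit("capture_qc_report", out / "capture_qc_report.txt")
        write_vcf(capture, out / "capture.vcf")
        emit("capture_vcf", out / "capture.vcf")
        manifest["capture_markers"] = capture.n_markers

        if config.do_evaluate:
            rep = concordance(ds_qc, capture)
            (out / "concordance.txt").write_text(rep.summary() + "\n")
            emit("concordance", out / "concordance.txt")
            manifest["concordance_percent_identical"] = rep.percent_identical
            cov = coverage_profile(depth, config.coverage_thresholds)
            (out / "coverage.txt").write_text(cov.summary() + "\n")
            cov.curves.to_csv(out / "coverage_curves.tsv", sep="\t")
            emit("coverage", out / "coverage.txt")
            emit("coverage_curves", out / "coverage_curves.tsv")
            off = classify_offtarget(capture, panel, near_bp=config.near_bp)
            (out / "offtarget.txt").write_text(off.summary() + "\n")
            emit("offtarget", out / "offtarget.txt")

    # ---- kinship ------------------------------------------------------
    if config.do_kinship:
        kin_full = pcrelate(ds_qc, n_pcs=config.kinship_pcs)
        kin_full.write_dyads(out / "kinship_full.tsv", config.degree_thresholds)
        emit("kinship_full", out / "kinship_full.tsv")
        manifest["n_dyads_full"] = len(kin_full.dyads())
        if capture is not None:
            kin_panel = pcrelate(capture, n_pcs=config.kinship_pcs)
            kin_panel.write_dyads(out / "kinship_panel.tsv", config.degree_thresholds)
            emit("kinship_panel", out / "kinship_panel.tsv")
            r, t, df, n_dyads = compare_kinship(kin_full, kin_panel)
            (out / "kinship_compare.tsv").write_text(
                "r\tt\tdf\tn_dyads\n" f"{r:.6f}\t{t:.4f}\t{df}\t{n_dyads}\n"
            )
            emit("kinship_compare", out / "kinship_compare.tsv")
            manifest["kinship_r"] = r
            manifest["kinship_t"] = t
            manifest["kinship_df"] = df
            log.info("cross-panel kinship: r=%.3f, t(%d)=%.2f over %d dyads", r, df, t, n_dyads)

    # ---- manifest -----------------------------------------------------
    manifest["outputs"] = {
        name: {"path": rel, "sha256": _sha256(out / rel)} for name, rel in outputs.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("run complete; %d artifacts in %s", len(outputs), out)
    return manifest
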