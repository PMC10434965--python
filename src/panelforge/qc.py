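"""Sample/marker quality control and windowed LD pruning.

The filter battery mirrors a standard array-genotyping QC recipe: samples
with >=10% missing genotypes are excluded first, then markers are filtered
for missingness (>=10%), minor allele frequency (monomorphic markers always
removed; retain iff MAF >= threshold), optional per-genotype quality/depth
masking (GQ >= 30, mean depth >= 10x, marker missingness <= 10%), and finally
linkage-disequilibrium pruning with a sliding base-pair window (1 kb, step 1
marker, r^2 > 0.5 removes one pair member).

Every removal is attributed to exactly one rule, and the per-stage
:class:`QCReport` counts reconcile exactly with the change in marker count.
The boundary conventions (">= threshold removes" for missingness; "retain iff
MAF >= threshold") are deliberate and documented; both thresholds are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeDataset

__all__ = [
    "QCReport",
    "filter_missingness",
    "filter_maf",
    "mask_low_quality",
    "ld_prune",
    "pairwise_r2",
    "audit_ld",
    "run_qc",
]


@dataclass
class QCReport:
    """Accounting of one QC stage: what was removed, under which rule, and why."""

    stage: str
    thresholds: dict
    samples_removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "missing_frac"])
    )
    markers_removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "pos", "rule", "value"])
    )
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_markers_in: int = 0
    n_markers_out: int = 0

    def counts_by_rule(self) -> pd.Series:
        if len(self.markers_removed) == 0:
            return pd.Series(dtype=int)
        return self.markers_removed["rule"].value_counts()

    def reconciles(self) -> bool:
        return (
            len(self.markers_removed) == self.n_markers_in - self.n_markers_out
            and len(self.samples_removed) == self.n_samples_in - self.n_samples_out
        )

    def to_text(self) -> str:
        lines = [f"[{self.stage}] thresholds: {self.thresholds}"]
        lines.append(
            f"  samples: {self.n_samples_in} -> {self.n_samples_out} "
            f"({len(self.samples_removed)} removed)"
        )
        lines.append(
            f"  markers: {self.n_markers_in} -> {self.n_markers_out} "
            f"({len(self.markers_removed)} removed)"
        )
        for rule, n in self.counts_by_rule().items():
            lines.append(f"    rule {rule}: {n}")
        return "\n".join(lines)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# stage: {self.stage}\n# thresholds: {self.thresholds}\n")
            fh.write("# samples removed\n")
            self.samples_removed.to_csv(fh, sep="\t", index=False)
            fh.write("# markers removed\n")
            self.markers_removed.to_csv(fh, sep="\t", index=False)


def _marker_removal_frame(ds, mask, rule, values) -> pd.DataFrame:
    sub = ds.markers.loc[mask, ["chrom", "pos"]].copy()
    sub["rule"] = rule
    sub["value"] = np.asarray(values)[np.asarray(mask)]
    return sub


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------


def filter_missingness(
    ds: GenotypeDataset,
    max_sample_miss: float = 0.10,
    max_marker_miss: float = 0.10,
) -> tuple[GenotypeDataset, QCReport]:
    """Remove samples, then markers, whose missing fraction is >= the threshold.

    The sample pass runs first; marker missingness is then computed over the
    remaining samples only.  The ``>=`` boundary means a sample at exactly 10%
    missing is removed at the default threshold.
    """
    for name, t in (("max_sample_miss", max_sample_miss), ("max_marker_miss", max_marker_miss)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    report = QCReport(
        stage="missingness",
        thresholds={"max_sample_miss": max_sample_miss, "max_marker_miss": max_marker_miss},
        n_samples_in=ds.n_samples,
        n_markers_in=ds.n_markers,
    )
    smiss = ds.sample_missing_fraction()
    drop_s = smiss >= max_sample_miss
    report.samples_removed = pd.DataFrame(
        {"sample": np.array(ds.samples)[drop_s], "missing_frac": smiss[drop_s]}
    )
    ds1 = ds.subset_samples(~drop_s) if drop_s.any() else ds

    mmiss = ds1.marker_missing_fraction()
    drop_m = mmiss >= max_marker_miss
    report.markers_removed = _marker_removal_frame(ds1, drop_m, "missingness", mmiss)
    ds2 = ds1.subset_markers(~drop_m) if drop_m.any() else ds1

    report.n_samples_out = ds2.n_samples
    report.n_markers_out = ds2.n_markers
    if ds2.n_samples == 0 or ds2.n_markers == 0:
        raise ValueError(
            "missingness filter removed everything "
            f"({ds2.n_samples} samples x {ds2.n_markers} markers left)"
        )
    return ds2, report


# ---------------------------------------------------------------------------
# Minor allele frequency
# ---------------------------------------------------------------------------


def filter_maf(ds: GenotypeDataset, min_maf: float = 0.05) -> tuple[GenotypeDataset, QCReport]:
    """Remove monomorphic markers and markers with MAF below ``min_maf``.

    MAF is computed from non-missing dosages.  Retention is inclusive
    (MAF >= min_maf kept); monomorphic markers are always removed, so
    ``min_maf = 0`` removes only those.  A marker with every genotype missing
    has undefined MAF and is removed under this rule with value NaN.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    maf = ds.maf()
    all_missing = np.isnan(maf)
    monomorphic = ~all_missing & (maf == 0.0)
    low = ~all_missing & ~monomorphic & (maf < min_maf)
    drop = all_missing | monomorphic | low
    rule = np.where(all_missing, "maf_undefined", np.where(monomorphic, "monomorphic", "maf"))
    report = QCReport(
        stage="maf",
        thresholds={"min_maf": min_maf},
        n_samples_in=ds.n_samples,
        n_samples_out=ds.n_samples,
        n_markers_in=ds.n_markers,
    )
    sub = ds.markers.loc[drop, ["chrom", "pos"]].copy()
    sub["rule"] = rule[drop]
    sub["value"] = maf[drop]
    report.markers_removed = sub
    out = ds.subset_markers(~drop) if drop.any() else ds
    report.n_markers_out = out.n_markers
    return out, report


# ---------------------------------------------------------------------------
# Sequencing quality masking
# ---------------------------------------------------------------------------


def mask_low_quality(
    ds: GenotypeDataset,
    min_gq: int = 30,
    min_mean_dp: float = 10.0,
    max_marker_miss: float = 0.10,
) -> tuple[GenotypeDataset, QCReport]:
    """Mask low-GQ genotypes, then drop low-depth and high-missingness markers.

    Order: genotypes with GQ < ``min_gq`` are set missing; markers whose mean
    DP over all samples is < ``min_mean_dp`` are removed; markers whose
    missing fraction (after masking) exceeds ``max_marker_miss`` are removed.
    Requires DP and GQ matrices.
    """
    if ds.GQ is None or ds.DP is None:
        raise ValueError(
            "dataset has no GQ/DP matrices; skip the quality-masking stage for "
            "platforms without per-genotype quality annotations"
        )
    report = QCReport(
        stage="quality",
        thresholds={
            "min_gq": min_gq,
            "min_mean_dp": min_mean_dp,
            "max_marker_miss": max_marker_miss,
        },
        n_samples_in=ds.n_samples,
        n_samples_out=ds.n_samples,
        n_markers_in=ds.n_markers,
    )
    out = ds.copy()
    out.G[(out.GQ < min_gq) & (out.G != MISSING)] = MISSING

    mean_dp = out.DP.astype(float).clip(min=0).mean(axis=0)
    drop_dp = mean_dp < min_mean_dp
    part1 = _marker_removal_frame(out, drop_dp, "mean_depth", mean_dp)

    mmiss = out.marker_missing_fraction()
    drop_miss = ~drop_dp & (mmiss > max_marker_miss)
    part2 = _marker_removal_frame(out, drop_miss, "missingness_after_masking", mmiss)

    report.markers_removed = pd.concat([part1, part2], ignore_index=True)
    drop = drop_dp | drop_miss
    out = out.subset_markers(~drop) if drop.any() else out
    report.n_markers_out = out.n_markers
    return out, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete.

    With fewer than two complete pairs, or zero variance in either vector,
    r^2 is defined as 0 (no evidence of linkage).
    """
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    xv -= xv.mean()
    yv -= yv.mean()
    sx = (xv * xv).sum()
    sy = (yv * yv).sum()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    r = (xv * yv).sum() / np.sqrt(sx * sy)
    return float(r * r)


def ld_prune(
    ds: GenotypeDataset,
    window_bp: int = 1000,
    step: int = 1,
    r2_max: float = 0.5,
    window_markers: int | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Sliding-window LD pruning: no surviving same-chromosome pair within the
    window may have dosage r^2 > ``r2_max``.

    The window is a base-pair span anchored at the left marker and advanced
    ``step`` markers at a time; it never crosses a chromosome boundary.  When
    a pair violates the threshold, the member with higher missingness is
    removed; ties go to the lower-MAF member, then to the larger position —
    the more informative marker is kept, deterministically.  Passing
    ``window_markers`` switches to a marker-count window instead of bp.
    """
    if not 0.0 <= r2_max <= 1.0:
        raise ValueError(f"r2_max must be in [0, 1], got {r2_max}")
    if step < 1:
        raise ValueError("step must be >= 1")

    G = ds.G
    pos = ds.markers["pos"].to_numpy()
    chroms = ds.markers["chrom"].to_numpy()
    mmiss = ds.marker_missing_fraction()
    maf = np.nan_to_num(ds.maf(), nan=-1.0)
    alive = np.ones(ds.n_markers, dtype=bool)

    def worse(a: int, b: int) -> int:
        """Index of the pair member to remove under the documented tie rule."""
        if mmiss[a] != mmiss[b]:
            return a if mmiss[a] > mmiss[b] else b
        if maf[a] != maf[b]:
            return a if maf[a] < maf[b] else b
        return a if pos[a] > pos[b] else b

    r2_removed: list[int] = []
    start = 0
    m = ds.n_markers
    while start < m:
        chrom = chroms[start]
        end = start
        while end < m and chroms[end] == chrom:
            end += 1
        for i in range(start, end, step):
            if not alive[i]:
                continue
            j = i + 1
            while j < end:
                if window_markers is not None:
                    if j - i >= window_markers:
                        break
                elif pos[j] - pos[i] > window_bp:
                    break
                if alive[j] and alive[i]:
                    if pairwise_r2(G[:, i], G[:, j]) > r2_max:
                        victim = worse(i, j)
                        alive[victim] = False
                        r2_removed.append(victim)
                        if victim == i:
                            break
                j += 1
        start = end

    report = QCReport(
        stage="ld_prune",
        thresholds={
            "window_bp": window_bp,
            "step": step,
            "r2_max": r2_max,
            "window_markers": window_markers,
        },
        n_samples_in=ds.n_samples,
        n_samples_out=ds.n_samples,
        n_markers_in=ds.n_markers,
    )
    drop = ~alive
    report.markers_removed = _marker_removal_frame(ds, drop, "ld", np.full(m, r2_max))
    out = ds.subset_markers(alive) if drop.any() else ds
    report.n_markers_out = out.n_markers
    return out, report


def audit_ld(ds: GenotypeDataset, window_bp: int = 1000, r2_max: float = 0.5) -> list[tuple]:
    """Exhaustive scan for same-chromosome pairs within ``window_bp`` whose
    r^2 exceeds ``r2_max``; returns the offending (key_i, key_j, r2) triples.
    """
    pos = ds.markers["pos"].to_numpy()
    chroms = ds.markers["chrom"].to_numpy()
    bad = []
    for i in range(ds.n_markers):
        for j in range(i + 1, ds.n_markers):
            if chroms[j] != chroms[i] or pos[j] - pos[i] > window_bp:
                break
            r2 = pairwise_r2(ds.G[:, i], ds.G[:, j])
            if r2 > r2_max:
                bad.append(((chroms[i], pos[i]), (chroms[j], pos[j]), r2))
    return bad


# ---------------------------------------------------------------------------
# Composite recipe
# ---------------------------------------------------------------------------


def run_qc(
    ds: GenotypeDataset,
    max_sample_miss: float = 0.10,
    max_marker_miss: float = 0.10,
    min_maf: float = 0.05,
    ld_window_bp: int = 1000,
    ld_step: int = 1,
    ld_r2: float = 0.5,
    min_gq: int | None = None,
    min_mean_dp: float | None = None,
    skip_ld: bool = False,
) -> tuple[GenotypeDataset, list[QCReport]]:
    """The full QC battery in its fixed order:
    missingness -> MAF -> (quality masking if GQ/DP thresholds given) -> LD.
    """
    reports = []
    ds, rep = filter_missingness(ds, max_sample_miss, max_marker_miss)
    reports.append(rep)
    ds, rep = filter_maf(ds, min_maf)
    reports.append(rep)
    if min_gq is not None or min_mean_dp is not None:
        ds, rep = mask_low_quality(
            ds,
            min_gq=30 if min_gq is None else min_gq,
            min_mean_dp=10.0 if min_mean_dp is None else min_mean_dp,
            max_marker_miss=max_marker_miss,
        )
        reports.append(rep)
    if not skip_ld:
        ds, rep = ld_prune(ds, window_bp=ld_window_bp, step=ld_step, r2_max=ld_r2)
        reports.append(rep)
    return ds, reports
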