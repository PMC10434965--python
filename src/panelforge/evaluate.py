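"""Cross-platform genotype evaluation: concordance, coverage profiles,
off-target SNP classification, and targeted-locus screening.

Concordance compares two datasets over their shared samples and shared
(chrom, pos) sites after allele harmonization: identical REF/ALT pairs are
compared directly, swapped REF/ALT pairs by complementing the dosage
(``2 - dosage``), and any other allele combination drops the site into the
harmonization log.  Every shared sample x site cell is classified into
exactly one of five categories, and all percentages use the full cell grid
(including missing cells) as denominator.  No strand flipping is attempted:
the two platforms of this workflow share a reference orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeDataset

__all__ = [
    "ConcordanceReport",
    "concordance",
    "CoverageProfile",
    "coverage_profile",
    "OfftargetReport",
    "classify_offtarget",
    "screen_loci",
]


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    """Five-way cell classification between two datasets on harmonized sites."""

    n_samples: int
    n_sites: int
    identical: int
    discordant: int
    missing_in_a_called_in_b: int
    called_in_a_missing_in_b: int
    missing_in_both: int
    per_site_discordance: pd.DataFrame  # chrom, pos, n_discordant
    harmonization_log: pd.DataFrame  # chrom, pos, action, detail

    @property
    def total_cells(self) -> int:
        return self.n_samples * self.n_sites

    @property
    def percent_identical(self) -> float:
        return 100.0 * self.identical / self.total_cells

    @property
    def percent_discordant(self) -> float:
        return 100.0 * self.discordant / self.total_cells

    @property
    def missingness_ratio(self) -> float | None:
        """missing-in-A-called-in-B over the reciprocal; None when undefined."""
        if self.called_in_a_missing_in_b == 0:
            return None
        return self.missing_in_a_called_in_b / self.called_in_a_missing_in_b

    def cells_reconcile(self) -> bool:
        return (
            self.identical
            + self.discordant
            + self.missing_in_a_called_in_b
            + self.called_in_a_missing_in_b
            + self.missing_in_both
            == self.total_cells
        )

    def summary(self) -> str:
        ratio = self.missingness_ratio
        return "\n".join(
            [
                "Genotype concordance",
                "====================",
                f"shared samples: {self.n_samples}, shared sites: {self.n_sites} "
                f"({self.total_cells} cells)",
                f"identical:  {self.identical} ({self.percent_identical:.1f}%)",
                f"discordant: {self.discordant} ({self.percent_discordant:.2f}%)",
                f"missing in A, called in B: {self.missing_in_a_called_in_b}",
                f"called in A, missing in B: {self.called_in_a_missing_in_b}",
                f"missing in both: {self.missing_in_both}",
                "reciprocal missingness ratio: "
                + ("undefined (0 denominator)" if ratio is None else f"{ratio:.2f}"),
                f"sites dropped/swapped in harmonization: "
                f"{len(self.harmonization_log)}",
            ]
        )


def concordance(dsA: GenotypeDataset, dsB: GenotypeDataset) -> ConcordanceReport:
    """Classify every shared sample x harmonized shared site cell."""
    shared_samples = [s for s in dsA.samples if s in set(dsB.samples)]
    if not shared_samples:
        raise ValueError("no shared samples between the two datasets")
    keysA = {k: j for j, k in enumerate(dsA.marker_keys())}
    keysB = {k: j for j, k in enumerate(dsB.marker_keys())}
    shared_keys = [k for k in keysA if k in keysB]
    if not shared_keys:
        raise ValueError("no shared (chrom, pos) sites between the two datasets")

    log_rows = []
    use_keys, flip = [], []
    mA = dsA.markers
    mB = dsB.markers
    for k in shared_keys:
        ja, jb = keysA[k], keysB[k]
        ra, aa = mA["ref"].iat[ja], mA["alt"].iat[ja]
        rb, ab = mB["ref"].iat[jb], mB["alt"].iat[jb]
        if (ra, aa) == (rb, ab):
            use_keys.append(k)
            flip.append(False)
        elif (ra, aa) == (ab, rb):
            use_keys.append(k)
            flip.append(True)
            log_rows.append((k[0], k[1], "swapped", f"{ra}/{aa} vs {rb}/{ab}"))
        else:
            log_rows.append((k[0], k[1], "dropped", f"{ra}/{aa} vs {rb}/{ab}"))
    if not use_keys:
        raise ValueError("no harmonizable shared sites (all dropped for allele mismatch)")

    ia = [dsA.samples.index(s) for s in shared_samples]
    ib = [dsB.samples.index(s) for s in shared_samples]
    ja = [keysA[k] for k in use_keys]
    jb = [keysB[k] for k in use_keys]
    A = dsA.G[np.ix_(ia, ja)].astype(np.int16)
    B = dsB.G[np.ix_(ib, jb)].astype(np.int16)
    flip = np.asarray(flip)
    B[:, flip] = np.where(B[:, flip] == MISSING, MISSING, 2 - B[:, flip])

    am = A == MISSING
    bm = B == MISSING
    both_called = ~am & ~bm
    identical = int((both_called & (A == B)).sum())
    disc_cells = both_called & (A != B)
    discordant = int(disc_cells.sum())
    miss_a = int((am & ~bm).sum())
    miss_b = int((~am & bm).sum())
    miss_both = int((am & bm).sum())

    per_site = pd.DataFrame(
        {
            "chrom": [k[0] for k in use_keys],
            "pos": [k[1] for k in use_keys],
            "n_discordant": disc_cells.sum(axis=0),
        }
    )
    return ConcordanceReport(
        n_samples=len(shared_samples),
        n_sites=len(use_keys),
        identical=identical,
        discordant=discordant,
        missing_in_a_called_in_b=miss_a,
        called_in_a_missing_in_b=miss_b,
        missing_in_both=miss_both,
        per_site_discordance=per_site,
        harmonization_log=pd.DataFrame(
            log_rows, columns=["chrom", "pos", "action", "detail"]
        ),
    )


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


@dataclass
class CoverageProfile:
    """Per-sample proportion-of-targets-at-depth curves and depth moments."""

    curves: pd.DataFrame  # index samples, columns thresholds; non-increasing rows
    per_sample_mean: pd.Series
    per_sample_sd: pd.Series
    grand_mean: float
    grand_sd: float

    def proportion_at(self, threshold: int) -> pd.Series:
        return self.curves[threshold]

    def n_samples_above(self, threshold: int = 10, min_proportion: float = 0.9) -> int:
        """Samples covering at least ``min_proportion`` of targets at depth
        >= ``threshold``."""
        return int((self.curves[threshold] > min_proportion).sum())

    def summary(self) -> str:
        return "\n".join(
            [
                "Target coverage profile",
                "=======================",
                f"samples: {len(self.curves)}, targets: n/a (per-sample curves)",
                f"grand mean depth: {self.grand_mean:.1f} (S.D. = {self.grand_sd:.2f})",
                f"samples with >90% of targets at >=10x: "
                f"{self.n_samples_above(10, 0.9)} / {len(self.curves)}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for _, row in self.curves.iterrows():
            ax.plot(self.curves.columns, row.values, color="grey", alpha=0.4, lw=0.8)
        ax.set_xlabel("depth threshold (x)")
        ax.set_ylabel("proportion of targets at or above threshold")
        return ax


def coverage_profile(
    depth_table: pd.DataFrame, thresholds: list[int] | None = None
) -> CoverageProfile:
    """Per-sample curves of the proportion of targets with depth >= t.

    ``depth_table`` is samples x targets (non-negative).  The default
    threshold grid is 1..100.
    """
    if depth_table.size == 0:
        raise ValueError("empty depth table")
    D = depth_table.to_numpy(dtype=float)
    if (D < 0).any():
        raise ValueError("depths must be >= 0")
    if thresholds is None:
        thresholds = list(range(1, 101))
    thresholds = list(thresholds)
    if not thresholds or any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("threshold grid must be non-empty and strictly increasing")
    curves = pd.DataFrame(
        {t: (D >= t).mean(axis=1) for t in thresholds}, index=depth_table.index
    )
    per_mean = pd.Series(D.mean(axis=1), index=depth_table.index)
    per_sd = pd.Series(D.std(axis=1, ddof=1), index=depth_table.index)
    return CoverageProfile(
        curves=curves,
        per_sample_mean=per_mean,
        per_sample_sd=per_sd,
        grand_mean=float(D.mean()),
        grand_sd=float(D.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Off-target classification
# ---------------------------------------------------------------------------


@dataclass
class OfftargetReport:
    """Distances of non-target called SNPs to the nearest panel target."""

    table: pd.DataFrame  # chrom, pos, distance, classification
    near_bp: int
    n_target: int
    n_near: int
    n_far: int
    fraction_near: float
    low_maf_fraction: float
    clusters: pd.DataFrame  # chrom, start, end, n_snps

    @property
    def n_offtarget(self) -> int:
        return self.n_near + self.n_far

    def summary(self) -> str:
        return "\n".join(
            [
                "Off-target SNP classification",
                "=============================",
                f"called SNPs at panel targets: {self.n_target}",
                f"non-target SNPs: {self.n_offtarget} "
                f"({self.n_near} within {self.near_bp} bp = "
                f"{100 * self.fraction_near:.1f}%, {self.n_far} far)",
                f"far-SNP clusters: {len(self.clusters)}",
                f"fraction of non-target SNPs with low MAF: "
                f"{100 * self.low_maf_fraction:.1f}%",
            ]
        )


def classify_offtarget(
    ds_called: GenotypeDataset,
    panel,
    near_bp: int = 150,
    maf_cut: float = 0.05,
    cluster_gap: int = 10_000,
) -> OfftargetReport:
    """Classify called SNPs that are not panel targets as near/far.

    ``panel`` is a :class:`~panelforge.panel.PanelSelection` or any object
    with ``marker_keys()`` / an iterable of (chrom, pos).  Distance is
    ``|pos - nearest same-chromosome target pos|`` ("within ``near_bp``" is
    inclusive); with no target on the chromosome the distance is infinite and
    the SNP is far.  Consecutive far SNPs <= ``cluster_gap`` apart form one
    cluster.
    """
    keys = panel.marker_keys() if hasattr(panel, "marker_keys") else list(panel)
    if not keys:
        raise ValueError("panel is empty")
    targets_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in keys:
        targets_by_chrom.setdefault(chrom, []).append(pos)
    targets_by_chrom = {c: np.sort(np.asarray(p)) for c, p in targets_by_chrom.items()}
    keyset = set(map(tuple, keys))

    maf = ds_called.maf()
    rows = []
    n_target = 0
    for j, (chrom, pos) in enumerate(ds_called.marker_keys()):
        if (chrom, pos) in keyset:
            n_target += 1
            continue
        tp = targets_by_chrom.get(chrom)
        if tp is None or len(tp) == 0:
            dist = np.inf
        else:
            i = np.searchsorted(tp, pos)
            cands = []
            if i < len(tp):
                cands.append(abs(int(tp[i]) - pos))
            if i > 0:
                cands.append(abs(pos - int(tp[i - 1])))
            dist = min(cands)
        cls = "near" if dist <= near_bp else "far"
        rows.append((chrom, pos, dist, cls, maf[j]))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "distance", "classification", "maf"])

    far = table[table["classification"] == "far"].sort_values(["chrom", "pos"])
    clusters = []
    for chrom, grp in far.groupby("chrom", sort=False):
        positions = grp["pos"].to_numpy()
        start = positions[0] if len(positions) else None
        prev = start
        count = 1
        for p in positions[1:]:
            if p - prev <= cluster_gap:
                count += 1
            else:
                clusters.append((chrom, start, prev, count))
                start, count = p, 1
            prev = p
        if start is not None:
            clusters.append((chrom, start, prev, count))
    clusters = pd.DataFrame(clusters, columns=["chrom", "start", "end", "n_snps"])

    n_off = len(table)
    n_near = int((table["classification"] == "near").sum())
    low_maf = float((table["maf"] < maf_cut).mean()) if n_off else 0.0
    return OfftargetReport(
        table=table,
        near_bp=near_bp,
        n_target=n_target,
        n_near=n_near,
        n_far=n_off - n_near,
        fraction_near=n_near / n_off if n_off else 0.0,
        low_maf_fraction=low_maf,
        clusters=clusters,
    )


# ---------------------------------------------------------------------------
# Targeted-locus screening
# ---------------------------------------------------------------------------


def screen_loci(
    ds: GenotypeDataset, loci: list[tuple[str, int, str]]
) -> pd.DataFrame:
    """Genotype count table (hom-ref / het / hom-alt / missing) per queried locus.

    Loci absent from the dataset get ``assayed = False`` and zero counts; for
    assayed loci the four counts partition the samples.  Typical use is the
    rodenticide-resistance screen of known coding SNPs.
    """
    lookup = {k: j for j, k in enumerate(ds.marker_keys())}
    rows = []
    for chrom, pos, label in loci:
        j = lookup.get((chrom, int(pos)))
        if j is None:
            rows.append((label, chrom, pos, False, 0, 0, 0, 0))
        else:
            g = ds.G[:, j]
            rows.append(
                (
                    label,
                    chrom,
                    pos,
                    True,
                    int((g == 0).sum()),
                    int((g == 1).sum()),
                    int((g == 2).sum()),
                    int((g == MISSING).sum()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["label", "chrom", "pos", "assayed", "hom_ref", "het", "hom_alt", "missing"],
    )
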