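"""Reduced-panel selection from discriminant-loading contributions, probe
interval construction, and panel summaries.

A marker enters the panel when its contribution to any of the leading
discriminant axes reaches that axis's percentile threshold (union across
axes; ties at the threshold are included).  Capture probes are fixed-length
intervals centred on the SNP — for the default even length of 120 nt the SNP
sits at probe base 61, i.e. the interval is ``[pos - 60, pos + 59]`` in
1-based inclusive coordinates.  Markers on excluded chromosomes (the
mitochondrion by default, whose probes would swamp an enriched library) are
dropped after selection, with a count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import DAPCResults

__all__ = ["PanelSelection", "select_panel", "summarize_panel", "PanelSummary"]


@dataclass
class PanelSelection:
    """A selected marker panel with probe intervals.

    ``table`` columns: chrom, pos, id, ref, alt, per-axis contributions,
    probe_start, probe_end (1-based inclusive, length = ``probe_length``
    unless clipped at the chromosome start, in which case ``clipped`` is
    True).
    """

    table: pd.DataFrame
    axes_used: int
    percentile: float
    thresholds: list[float]  # per-axis contribution cut
    probe_length: int
    excluded_chroms: set[str] = field(default_factory=set)
    n_excluded_by_chrom: int = 0
    pooled: bool = False

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def marker_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.table["chrom"], self.table["pos"]))

    def per_chromosome_counts(self) -> pd.Series:
        return self.table["chrom"].value_counts()

    def to_bed(self) -> pd.DataFrame:
        """Probe intervals as BED (0-based half-open): start = probe_start - 1."""
        return pd.DataFrame(
            {
                "chrom": self.table["chrom"],
                "start": self.table["probe_start"] - 1,
                "end": self.table["probe_end"],
                "name": self.table["id"],
            }
        )

    def write_bed(self, path) -> None:
        self.to_bed().to_csv(path, sep="\t", header=False, index=False)

    def write_table(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# axes={self.axes_used} percentile={self.percentile} "
                f"probe_length={self.probe_length} coords=1-based-inclusive\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)


def select_panel(
    model: DAPCResults,
    percentile: float = 95.0,
    n_axes: int = 2,
    exclude_chroms: set[str] | None = None,
    probe_length: int = 120,
    use_signed_loadings: bool = False,
    pooled: bool = False,
) -> PanelSelection:
    """Select the markers in the top ``100 - percentile`` percent of
    contributions on any of the leading ``n_axes`` discriminant axes.

    Per axis, the threshold is the ``percentile``-th empirical percentile of
    the contribution distribution and selection is inclusive (``>=``), so
    threshold ties are all kept; the selected set is the union over axes.
    With ``pooled=True`` a single threshold is computed on the pooled
    contributions of all used axes instead.  ``use_signed_loadings`` ranks by
    absolute signed loading rather than the normalized squared contribution.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile must be inside (0, 100), got {percentile}")
    if model.n_axes < n_axes:
        raise ValueError(
            f"model has {model.n_axes} discriminant axes, {n_axes} requested"
        )
    exclude_chroms = {"MT"} if exclude_chroms is None else set(exclude_chroms)

    values = (
        np.abs(model.marker_loadings[:, :n_axes])
        if use_signed_loadings
        else model.contributions[:, :n_axes]
    )
    q = percentile / 100.0
    if pooled:
        t = float(np.quantile(values.ravel(), q))
        thresholds = [t] * n_axes
    else:
        thresholds = [float(np.quantile(values[:, d], q)) for d in range(n_axes)]
    selected = np.zeros(len(values), dtype=bool)
    for d in range(n_axes):
        selected |= values[:, d] >= thresholds[d]

    table = model.markers.loc[selected, ["chrom", "pos", "id", "ref", "alt"]].copy()
    for d in range(n_axes):
        table[f"contrib_LD{d + 1}"] = model.contributions[selected, d]

    on_excluded = table["chrom"].isin(exclude_chroms)
    n_excluded = int(on_excluded.sum())
    table = table.loc[~on_excluded].reset_index(drop=True)

    half = probe_length // 2
    start = table["pos"] - half
    end = table["pos"] + (probe_length - half) - 1
    clipped = start < 1
    shift = np.where(clipped, 1 - start, 0)
    table["probe_start"] = start + shift
    table["probe_end"] = end + shift
    table["clipped"] = clipped.to_numpy()

    return PanelSelection(
        table=table,
        axes_used=n_axes,
        percentile=percentile,
        thresholds=thresholds,
        probe_length=probe_length,
        excluded_chroms=exclude_chroms,
        n_excluded_by_chrom=n_excluded,
        pooled=pooled,
    )


@dataclass
class PanelSummary:
    """Per-chromosome panel composition plus optional probe sequences."""

    per_chromosome: pd.Series
    autosome_mean: float
    autosome_sd: float
    n_markers: int
    probes: pd.DataFrame  # chrom, start, end, name [, sequence, flag]

    def to_text(self) -> str:
        lines = [
            f"panel markers: {self.n_markers}",
            f"markers per autosome: mean {self.autosome_mean:.1f} "
            f"(S.D. = {self.autosome_sd:.1f})",
            "per-chromosome counts:",
        ]
        for chrom, n in self.per_chromosome.items():
            lines.append(f"  {chrom}: {n}")
        return "\n".join(lines)


def autosome_stats(counts: pd.Series, autosomes: list[str]) -> tuple[float, float]:
    """Mean and sample SD of markers per autosome over the declared autosome
    set (chromosomes without panel markers count as zero)."""
    vec = np.array([counts.get(c, 0) for c in autosomes], dtype=float)
    if len(vec) == 0:
        return float("nan"), float("nan")
    sd = float(vec.std(ddof=1)) if len(vec) > 1 else float("nan")
    return float(vec.mean()), sd


def summarize_panel(
    panel: PanelSelection,
    fasta=None,
    autosomes: list[str] | None = None,
    homopolymer_min: int = 15,
) -> PanelSummary:
    """Per-chromosome counts, markers-per-autosome mean/SD, probe intervals,
    and (when a FASTA is given) uppercase probe sequences with degeneracy
    flags (Ns, homopolymer runs >= ``homopolymer_min``).

    ``fasta`` may be a path (read with pyfaidx) or a mapping chrom -> sequence.
    """
    counts = panel.per_chromosome_counts()
    if autosomes is None:
        autosomes = sorted(
            (c for c in counts.index if str(c).lstrip("chr").isdigit()),
            key=lambda c: int(str(c).lstrip("chr")),
        )
    mean, sd = autosome_stats(counts, autosomes)

    probes = panel.to_bed().copy()
    probes["start"] = probes["start"] + 1  # report 1-based inclusive here
    if fasta is not None:
        getter = _sequence_getter(fasta)
        seqs, flags = [], []
        for row in probes.itertuples(index=False):
            seq = getter(row.chrom, row.start, row.end).upper()
            seqs.append(seq)
            flags.append(_flag_sequence(seq, panel.probe_length, homopolymer_min))
        probes["sequence"] = seqs
        probes["flag"] = flags
    return PanelSummary(
        per_chromosome=counts,
        autosome_mean=mean,
        autosome_sd=sd,
        n_markers=panel.n_markers,
        probes=probes,
    )


def _sequence_getter(fasta):
    if hasattr(fasta, "keys") and not isinstance(fasta, (str, bytes)):
        mapping = fasta

        def get(chrom, start, end):
            if chrom not in mapping:
                raise KeyError(f"chromosome {chrom} absent from reference")
            return str(mapping[chrom][start - 1 : end])

        return get
    from pyfaidx import Fasta

    fa = Fasta(str(fasta))

    def get(chrom, start, end):
        if chrom not in fa:
            raise KeyError(f"chromosome {chrom} absent from reference {fasta}")
        return str(fa[chrom][start - 1 : end])

    return get


def _flag_sequence(seq: str, probe_length: int, homopolymer_min: int) -> str:
    flags = []
    if len(seq) != probe_length:
        flags.append("short")
    if "N" in seq:
        flags.append("contains_N")
    run, prev, best = 0, "", 0
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    if best >= homopolymer_min:
        flags.append(f"homopolymer_{best}")
    return ";".join(flags) if flags else "ok"
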