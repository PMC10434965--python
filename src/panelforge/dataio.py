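"""Genotype data model and file I/O.

The central container is :class:`GenotypeDataset`: a samples x markers matrix of
diploid alternate-allele dosages (0/1/2, with ``-1`` encoding a missing call)
together with marker coordinates, REF/ALT alleles, optional per-genotype depth
(DP) and genotype quality (GQ) matrices, and optional per-sample population
labels.  All coordinates are 1-based inclusive (VCF convention); dosage counts
the ALT allele and alleles are taken verbatim from the source file — no strand
normalisation happens at load time (cross-platform harmonisation is the job of
:mod:`panelforge.evaluate`).

VCF 4.2 is read through :mod:`cyvcf2` and written as plain text.  The reader
never silently drops a record: sites with more than two observed alleles are
returned as :class:`MultiallelicRecord` entries and indels / non-SNP records
are listed in an explicit skip log.  Phase is ignored ("0|1" == "0/1"): the
whole workflow is dosage-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "MultiallelicRecord",
    "VcfReadResult",
    "read_vcf",
    "load_genotypes",
    "write_vcf",
    "read_pop_labels",
    "write_pop_labels",
    "concat_samples",
    "chrom_sort_key",
]

#: Sentinel for a missing genotype / DP / GQ cell.
MISSING = -1

MARKER_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

_SPECIAL_CHROMS = {"X": 1000, "Y": 1001, "MT": 1002, "M": 1002}


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key giving the conventional order 1..n, X, Y, MT, then others."""
    s = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if s.isdigit():
        return (0, int(s), "")
    if s.upper() in _SPECIAL_CHROMS:
        return (0, _SPECIAL_CHROMS[s.upper()], "")
    return (1, 0, s)


@dataclass
class MultiallelicRecord:
    """A site excluded from the dosage matrix because >2 alleles were observed."""

    chrom: str
    pos: int
    alleles: tuple[str, ...]
    carrier_counts: tuple[int, ...]  # samples carrying each non-REF allele

    def __post_init__(self) -> None:
        if len(self.alleles) < 3:
            raise ValueError(
                f"multiallelic record at {self.chrom}:{self.pos} has "
                f"{len(self.alleles)} alleles; expected at least 3"
            )


@dataclass
class GenotypeDataset:
    """Samples x biallelic markers dosage matrix with metadata.

    Parameters
    ----------
    samples
        Ordered unique sample identifiers.
    markers
        DataFrame with columns ``chrom, pos, id, ref, alt``, sorted by
        chromosome (natural order) then position; (chrom, pos) unique.
    G
        ``(n_samples, n_markers)`` int8 array of ALT dosages in {0, 1, 2},
        with :data:`MISSING` (-1) for missing calls.
    DP, GQ
        Optional per-genotype depth / quality matrices of the same shape
        (int32; :data:`MISSING` where absent).
    populations
        Optional Series mapping sample id -> population label.
    """

    samples: list[str]
    markers: pd.DataFrame
    G: np.ndarray
    DP: np.ndarray | None = None
    GQ: np.ndarray | None = None
    populations: pd.Series | None = None

    # -- construction ---------------------------------------------------

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.markers = self.markers.reset_index(drop=True)
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.DP is not None:
            self.DP = np.asarray(self.DP, dtype=np.int32)
        if self.GQ is not None:
            self.GQ = np.asarray(self.GQ, dtype=np.int32)
        self.validate()

    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        missing_cols = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing_cols:
            raise ValueError(f"marker table lacks columns {missing_cols}")
        m = self.markers
        if len(m) and (m["pos"] < 1).any():
            raise ValueError("marker positions must be >= 1")
        keys = list(zip(m["chrom"], m["pos"]))
        if len(set(keys)) != len(keys):
            raise ValueError("(chrom, pos) marker keys are not unique")
        order = sorted(range(len(keys)), key=lambda i: (chrom_sort_key(keys[i][0]), keys[i][1]))
        if order != list(range(len(keys))):
            raise ValueError("markers are not sorted by chromosome then position")
        if self.G.shape != (len(self.samples), len(m)):
            raise ValueError(
                f"G shape {self.G.shape} does not match "
                f"({len(self.samples)} samples, {len(m)} markers)"
            )
        if len(m) and self.G.size:
            bad = ~np.isin(self.G, [-1, 0, 1, 2])
            if bad.any():
                raise ValueError("dosages must be in {-1, 0, 1, 2}")
        for name, mat in (("DP", self.DP), ("GQ", self.GQ)):
            if mat is not None:
                if mat.shape != self.G.shape:
                    raise ValueError(f"{name} shape {mat.shape} != G shape {self.G.shape}")
                if mat.size and (mat < -1).any():
                    raise ValueError(f"{name} values must be >= 0 (or -1 for absent)")
        if self.populations is not None:
            self.populations = self.populations.reindex(self.samples)
            if self.populations.isna().any():
                missing = list(self.populations.index[self.populations.isna()])
                raise ValueError(f"samples without population label: {missing}")

    # -- basic properties -----------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.markers["chrom"], self.markers["pos"]))

    @property
    def population_labels(self) -> np.ndarray:
        if self.populations is None:
            raise ValueError("dataset has no population labels attached")
        return self.populations.to_numpy()

    # -- derived statistics ---------------------------------------------

    def missing_mask(self) -> np.ndarray:
        return self.G == MISSING

    def sample_missing_fraction(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.zeros(self.n_samples)
        return self.missing_mask().mean(axis=1)

    def marker_missing_fraction(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_markers)
        return self.missing_mask().mean(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """Per-marker ALT allele frequency over non-missing calls (NaN if none)."""
        called = self.G != MISSING
        n = called.sum(axis=0)
        tot = np.where(called, self.G, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    # -- subsetting ------------------------------------------------------

    def subset_samples(self, keep) -> "GenotypeDataset":
        """Subset to samples given by boolean mask, indices, or names."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            lookup = {s: i for i, s in enumerate(self.samples)}
            absent = [s for s in keep if s not in lookup]
            if absent:
                raise KeyError(f"samples not in dataset: {absent}")
            idx = np.array([lookup[s] for s in keep], dtype=int)
        samples = [self.samples[i] for i in idx]
        pops = self.populations.loc[samples] if self.populations is not None else None
        return GenotypeDataset(
            samples=samples,
            markers=self.markers.copy(),
            G=self.G[idx].copy(),
            DP=None if self.DP is None else self.DP[idx].copy(),
            GQ=None if self.GQ is None else self.GQ[idx].copy(),
            populations=pops,
        )

    def subset_markers(self, keep) -> "GenotypeDataset":
        """Subset markers by boolean mask or integer indices (order preserved)."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeDataset(
            samples=list(self.samples),
            markers=self.markers.iloc[idx].reset_index(drop=True),
            G=self.G[:, idx].copy(),
            DP=None if self.DP is None else self.DP[:, idx].copy(),
            GQ=None if self.GQ is None else self.GQ[:, idx].copy(),
            populations=None if self.populations is None else self.populations.copy(),
        )

    def restrict_to_keys(self, keys) -> "GenotypeDataset":
        """Subset to the markers whose (chrom, pos) keys appear in ``keys``."""
        keyset = set(keys)
        mask = np.array([k in keyset for k in self.marker_keys()])
        return self.subset_markers(mask)

    def copy(self) -> "GenotypeDataset":
        return dataclasses.replace(
            self,
            samples=list(self.samples),
            markers=self.markers.copy(),
            G=self.G.copy(),
            DP=None if self.DP is None else self.DP.copy(),
            GQ=None if self.GQ is None else self.GQ.copy(),
            populations=None if self.populations is None else self.populations.copy(),
        )

    def with_populations(self, populations: pd.Series) -> "GenotypeDataset":
        out = self.copy()
        out.populations = populations
        out.validate()
        return out

    def equals(self, other: "GenotypeDataset") -> bool:
        def mat_eq(a, b):
            if a is None and b is None:
                return True
            return a is not None and b is not None and np.array_equal(a, b)

        return (
            self.samples == other.samples
            and self.markers[MARKER_COLUMNS].equals(other.markers[MARKER_COLUMNS])
            and np.array_equal(self.G, other.G)
            and mat_eq(self.DP, other.DP)
            and mat_eq(self.GQ, other.GQ)
        )


def concat_samples(datasets: list[GenotypeDataset]) -> GenotypeDataset:
    """Stack datasets that share an identical marker table along the sample axis."""
    if not datasets:
        raise ValueError("no datasets to concatenate")
    first = datasets[0]
    for ds in datasets[1:]:
        if not first.markers[MARKER_COLUMNS].equals(ds.markers[MARKER_COLUMNS]):
            raise ValueError("datasets do not share an identical marker table")
    samples = [s for ds in datasets for s in ds.samples]
    has_dp = all(ds.DP is not None for ds in datasets)
    has_gq = all(ds.GQ is not None for ds in datasets)
    has_pop = all(ds.populations is not None for ds in datasets)
    return GenotypeDataset(
        samples=samples,
        markers=first.markers.copy(),
        G=np.vstack([ds.G for ds in datasets]),
        DP=np.vstack([ds.DP for ds in datasets]) if has_dp else None,
        GQ=np.vstack([ds.GQ for ds in datasets]) if has_gq else None,
        populations=pd.concat([ds.populations for ds in datasets]) if has_pop else None,
    )


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(ds: GenotypeDataset, path) -> None:
    """Write ``ds`` as an uncompressed VCF 4.2 file (GT, plus DP/GQ when present).

    Missing genotypes are encoded ``./.``.  The header carries no timestamp so
    identical datasets produce byte-identical files.
    """
    path = Path(path)
    fmt_fields = ["GT"]
    if ds.DP is not None:
        fmt_fields.append("DP")
    if ds.GQ is not None:
        fmt_fields.append("GQ")
    fmt = ":".join(fmt_fields)

    lines: list[str] = ["##fileformat=VCFv4.2", "##source=panelforge"]
    seen: list[str] = []
    for c in ds.markers["chrom"]:
        if c not in seen:
            seen.append(c)
    for c in seen:
        lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if ds.DP is not None:
        lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    if ds.GQ is not None:
        lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ds.samples)
        if ds.samples
        else "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    )

    G, DP, GQ = ds.G, ds.DP, ds.GQ
    for j, rec in enumerate(ds.markers.itertuples(index=False)):
        cells = []
        for i in range(ds.n_samples):
            cell = _GT_STRINGS[int(G[i, j])]
            if DP is not None:
                v = int(DP[i, j])
                cell += ":" + ("." if v < 0 else str(v))
            if GQ is not None:
                v = int(GQ[i, j])
                cell += ":" + ("." if v < 0 else str(v))
            cells.append(cell)
        mid = rec.id if rec.id else "."
        row = f"{rec.chrom}\t{rec.pos}\t{mid}\t{rec.ref}\t{rec.alt}\t.\t.\t.\t{fmt}"
        if cells:
            row += "\t" + "\t".join(cells)
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


@dataclass
class VcfReadResult:
    """Outcome of :func:`read_vcf`: the dataset plus full accounting of exclusions."""

    dataset: GenotypeDataset
    multiallelic: list[MultiallelicRecord] = field(default_factory=list)
    skipped: list[tuple[str, int, str]] = field(default_factory=list)  # chrom, pos, reason

    def __iter__(self):
        return iter((self.dataset, self.multiallelic))


def read_vcf(path) -> VcfReadResult:
    """Read a VCF with a GT field into a :class:`GenotypeDataset`.

    Biallelic SNPs become dosage columns; half-missing or missing genotypes
    become missing; sites with more than two alleles are excluded from the
    matrix and reported as :class:`MultiallelicRecord`; indels and other
    non-SNP records go to the skip log.  DP and GQ matrices are loaded when
    the FORMAT declares them.  Non-monotone positions within a chromosome
    raise an error naming the offending record.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc

    samples = list(vcf.samples)
    n = len(samples)
    has_dp = "DP" in [f["ID"] for f in _format_headers(vcf)]
    has_gq = "GQ" in [f["ID"] for f in _format_headers(vcf)]

    rows: list[tuple] = []
    g_cols: list[np.ndarray] = []
    dp_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    multi: list[MultiallelicRecord] = []
    skipped: list[tuple[str, int, str]] = []
    last: dict[str, int] = {}
    chrom_order: list[str] = []

    for var in vcf:
        chrom, pos = var.CHROM, var.POS
        if chrom not in last:
            chrom_order.append(chrom)
        else:
            if chrom != chrom_order[-1]:
                raise ValueError(
                    f"chromosome {chrom} reappears at {chrom}:{pos}; "
                    "records must be grouped by chromosome"
                )
            if pos <= last[chrom]:
                raise ValueError(
                    f"non-monotone position at record {chrom}:{pos} "
                    f"(previous position {last[chrom]})"
                )
        last[chrom] = pos

        alts = [a for a in var.ALT if a not in (".", "")]
        if len(alts) > 1:
            counts = _carrier_counts(var, len(alts))
            multi.append(
                MultiallelicRecord(chrom, pos, tuple([var.REF] + alts), tuple(counts))
            )
            continue
        alt = alts[0] if alts else "."
        if len(var.REF) != 1 or (alt != "." and len(alt) != 1):
            skipped.append((chrom, pos, "non-SNP"))
            continue
        if alt == ".":
            skipped.append((chrom, pos, "no ALT allele"))
            continue

        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0/1/2, 3 = unknown
        gt[gt == 3] = MISSING
        # gt_types calls half-missing genotypes by the observed allele; the
        # workflow treats any genotype with a missing allele as missing
        try:
            alleles = var.genotype.array()[:, :2]
        except Exception:
            alleles = np.array([g[:2] for g in var.genotypes])
        gt[(alleles < 0).any(axis=1)] = MISSING
        rows.append((chrom, pos, var.ID or "", var.REF, alt))
        g_cols.append(gt)
        if has_dp:
            dp_cols.append(_format_column(var, "DP", n))
        if has_gq:
            gq_cols.append(_format_column(var, "GQ", n))

    markers = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    G = np.column_stack(g_cols) if g_cols else np.zeros((n, 0), dtype=np.int8)
    DP = np.column_stack(dp_cols) if (has_dp and g_cols) else None
    GQ = np.column_stack(gq_cols) if (has_gq and g_cols) else None

    # re-sort into the canonical chromosome order if the file ordered
    # chromosomes differently (positions are already monotone within chrom)
    order = sorted(
        range(len(markers)),
        key=lambda i: (chrom_sort_key(markers["chrom"].iat[i]), markers["pos"].iat[i]),
    )
    if order != list(range(len(markers))):
        markers = markers.iloc[order].reset_index(drop=True)
        G = G[:, order]
        DP = DP[:, order] if DP is not None else None
        GQ = GQ[:, order] if GQ is not None else None

    ds = GenotypeDataset(samples=samples, markers=markers, G=G, DP=DP, GQ=GQ)
    return VcfReadResult(dataset=ds, multiallelic=multi, skipped=skipped)


def _format_headers(vcf):
    out = []
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<"):
            body = line[len("##FORMAT=<") : -1]
            entries = dict(kv.split("=", 1) for kv in body.split(",") if "=" in kv)
            out.append(entries)
    return out


def _format_column(var, key: str, n: int) -> np.ndarray:
    arr = var.format(key)
    if arr is None:
        return np.full(n, MISSING, dtype=np.int32)
    arr = np.asarray(arr).reshape(n, -1)[:, 0]
    arr = np.where(np.isfinite(arr.astype(float)), arr, MISSING).astype(np.int32)
    arr[arr < 0] = MISSING
    return arr


def _carrier_counts(var, n_alts: int) -> list[int]:
    counts = [0] * n_alts
    for geno in var.genotypes:
        alleles = [a for a in geno[:-1] if a is not None and a > 0]
        for k in range(1, n_alts + 1):
            if k in alleles:
                counts[k - 1] += 1
    return counts


def load_genotypes(path) -> GenotypeDataset:
    """Convenience: read a VCF and return only the dataset."""
    return read_vcf(path).dataset


# ---------------------------------------------------------------------------
# Population label files
# ---------------------------------------------------------------------------


def read_pop_labels(path, ds: GenotypeDataset) -> GenotypeDataset:
    """Attach population labels from a 2-column tab-separated file.

    Every dataset sample must be assigned exactly one label; extra samples in
    the file, samples missing from it, and duplicate rows are all errors.
    """
    tab = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    dup = tab["sample"][tab["sample"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate sample rows in label file: {sorted(set(dup))}")
    in_ds = set(ds.samples)
    extra = [s for s in tab["sample"] if s not in in_ds]
    if extra:
        raise ValueError(f"label file lists samples absent from dataset: {extra}")
    labelled = set(tab["sample"])
    missing = [s for s in ds.samples if s not in labelled]
    if missing:
        raise ValueError(f"dataset samples without a label: {missing}")
    series = tab.set_index("sample")["population"]
    return ds.with_populations(series)


def write_pop_labels(ds: GenotypeDataset, path) -> None:
    if ds.populations is None:
        raise ValueError("dataset has no population labels to write")
    with open(path, "w") as fh:
        for s in ds.samples:
            fh.write(f"{s}\t{ds.populations[s]}\n")
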