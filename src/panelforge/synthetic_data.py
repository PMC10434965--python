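"""Synthetic structured, pedigreed genotype datasets with sequencing artefacts.

This module emulates the study system the workflow was built for: several
wild rodent populations sampled at nearby farm sites, differentiated by drift
(Balding–Nichols model), carrying local LD, containing 1st–3rd degree relative
pairs, with array-scale missingness and capture-sequencing depth/quality
annotations.  Every downstream stage of the package can therefore be exercised
end to end with no external data, against known truth.

Model summary
-------------
* Population allele frequencies drift from an ancestral frequency ``p`` under
  the Balding–Nichols model: ``p_k ~ Beta(p(1-F)/F, (1-p)(1-F)/F)``, so
  ``E[p_k] = p`` and ``Var[p_k] = F p (1-p)``.  ``F = 0`` returns ``p``
  exactly; ``F = 1`` is rejected (degenerate Beta).
* Genotypes are Hardy–Weinberg draws within population.  Local LD is created
  by latent-haplotype copying: markers inside a block share a latent uniform
  per haplotype that is re-drawn with probability ``ld_leak`` at each marker,
  which preserves the per-marker allele frequency while correlating dosages.
* Pedigrees are built by Mendelian gene-dropping (one allele from each parent
  per marker, independent across markers), with expected kinships derived from
  the standard pedigree recursion.
* Sequencing depth is negative-binomial per genotype; GQ is a deterministic,
  capped, increasing function of DP; DP = 0 forces a missing call.

All randomness flows through one seeded :class:`numpy.random.Generator`; an
identical config produces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataio import MISSING, MARKER_COLUMNS, GenotypeDataset, concat_samples

__all__ = [
    "SimConfig",
    "PedigreeDesign",
    "PedigreeTruth",
    "sim_structured_freqs",
    "sim_genotypes",
    "sim_pedigree",
    "corrupt_genotypes",
    "sim_seq_artifacts",
    "sim_study",
    "write_truth_table",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study system.

    Defaults describe the regime the workflow targets: two farm-scale
    populations with modest drift (F = 0.1), ancestral frequencies away from
    the monomorphic boundary, unlinked markers unless LD blocks are requested,
    and capture-sequencing depth around 27.6x with dispersion matched to a
    depth SD near 10x.
    """

    n_pops: int = 2
    n_per_pop: int = 150
    n_markers: int = 3500
    fst: float = 0.1
    anc_freq_range: tuple[float, float] = (0.05, 0.95)
    ld_block_size: int = 1
    ld_leak: float = 0.0
    miss_rate: float = 0.05
    error_rate: float = 0.0
    mean_depth: float = 27.6
    depth_dispersion: float = 11.0
    gq_per_depth: float = 3.0
    gq_cap: int = 99
    structure: str = "star"  # or "chain": sequential drift along a site chain
    n_autosomes: int = 19
    include_x: bool = True
    intra_block_gap: int = 150
    inter_block_gap: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        for name in ("miss_rate", "error_rate", "ld_leak"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError(f"fst must be in [0, 1) (F = 1 is degenerate), got {self.fst}")
        lo, hi = self.anc_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"anc_freq_range must be inside (0, 1), got {self.anc_freq_range}")
        if self.n_markers < 0:
            raise ValueError("n_markers must be >= 0")
        if self.n_pops < 1 or self.n_per_pop < 1:
            raise ValueError("n_pops and n_per_pop must be >= 1")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be > 0")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.structure not in ("star", "chain"):
            raise ValueError("structure must be 'star' or 'chain'")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PedigreeDesign:
    """Counts of family units to embed in a simulated population.

    Each unit is built from fresh founders, so relatedness never crosses
    units: a parent–offspring unit contributes two 1st-degree dyads, a
    full-sib unit a sib pair plus four parent–child dyads, a half-sib unit a
    2nd-degree dyad, and a cousin unit a 3rd-degree dyad (plus the internal
    sib/avuncular/parent–child dyads implied by the pedigree).
    ``n_unrelated`` adds lone founders.
    """

    n_parent_offspring: int = 0
    n_full_sib: int = 0
    n_half_sib: int = 0
    n_cousin: int = 0
    n_unrelated: int = 0


@dataclass
class PedigreeTruth:
    """Expected kinship for every dyad involving at least one non-founder,
    plus the parent links of every non-founder (for Mendelian checks)."""

    dyads: pd.DataFrame  # sample_a, sample_b, kinship, degree
    parents: pd.DataFrame | None = None  # child, father, mother

    DEGREE_BY_KINSHIP = {0.25: "1st", 0.125: "2nd", 0.0625: "3rd", 0.0: "unrelated"}

    def of_degree(self, degree: str) -> pd.DataFrame:
        return self.dyads[self.dyads["degree"] == degree]


# ---------------------------------------------------------------------------
# Allele frequencies and genotypes
# ---------------------------------------------------------------------------


def sim_structured_freqs(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-population allele frequencies under the Balding–Nichols model.

    Returns a (populations x markers) DataFrame whose ``attrs['ancestral']``
    holds the ancestral frequencies.  With ``structure='chain'`` each
    population drifts from its predecessor instead of the common ancestor,
    emulating isolation by distance.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    lo, hi = config.anc_freq_range
    if config.ld_block_size > 1:
        # markers of one LD block share an ancestral frequency, so the latent
        # copying below yields high r^2 between them (tag-SNP-like blocks)
        n_blocks = int(np.ceil(config.n_markers / config.ld_block_size))
        per_block = rng.uniform(lo, hi, size=n_blocks)
        anc = np.repeat(per_block, config.ld_block_size)[: config.n_markers]
    else:
        anc = rng.uniform(lo, hi, size=config.n_markers)
    F = config.fst
    freqs = np.empty((config.n_pops, config.n_markers))
    parent = anc
    bs = config.ld_block_size
    for k in range(config.n_pops):
        base = anc if config.structure == "star" else parent
        if bs > 1:
            # one drift draw per block, shared by its markers
            block_base = base[::bs]
            drawn = _bn_draw(block_base, F, rng)
            freqs[k] = np.repeat(drawn, bs)[: config.n_markers]
        else:
            freqs[k] = _bn_draw(base, F, rng)
        parent = freqs[k]
    out = pd.DataFrame(freqs, index=[f"pop{k + 1}" for k in range(config.n_pops)])
    out.attrs["ancestral"] = anc
    return out


def _bn_draw(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    if F == 0.0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place markers on a synthetic genome (autosomes + X), positions increasing.

    Markers of one LD block sit ``intra_block_gap`` apart; blocks are separated
    by ``inter_block_gap`` so that unlinked markers fall outside any kb-scale
    pruning window.  Blocks never span chromosomes.
    """
    chroms = [str(c) for c in range(1, config.n_autosomes + 1)]
    if config.include_x:
        chroms.append("X")
    m = config.n_markers
    bs = config.ld_block_size
    n_blocks = int(np.ceil(m / bs)) if m else 0
    blocks_per_chrom = int(np.ceil(n_blocks / len(chroms))) if n_blocks else 0

    rows = []
    alleles = np.array(["A", "C", "G", "T"])
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    j = 0
    for b in range(n_blocks):
        chrom = chroms[min(b // blocks_per_chrom, len(chroms) - 1)]
        prev_chrom = rows[-1][0] if rows else None
        if chrom != prev_chrom:
            pos = int(rng.integers(10_000, 60_000))
        else:
            pos = rows[-1][1] + config.inter_block_gap + int(rng.integers(0, 10_000))
        for _ in range(min(bs, m - j)):
            rows.append((chrom, pos, f"snp{j + 1}", alleles[ref_i[j]], alleles[alt_i[j]]))
            pos += config.intra_block_gap
            j += 1
    return pd.DataFrame(rows, columns=MARKER_COLUMNS)


def sim_genotypes(
    freqs: pd.DataFrame | np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> GenotypeDataset:
    """Draw within-population Hardy–Weinberg genotypes on a synthetic genome.

    Markers inside an LD block copy a shared pair of latent haplotypes,
    re-drawing the latent state with probability ``ld_leak`` per marker.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    P = np.asarray(freqs, dtype=float)
    if P.ndim != 2:
        raise ValueError("freqs must be a (populations x markers) table")
    if np.any((P < 0) | (P > 1)):
        raise ValueError("allele frequencies must be in [0, 1]")
    n_pops, m = P.shape
    if m != config.n_markers:
        config = replace(config, n_markers=m)
    markers = _marker_map(config, rng)

    sample_names, labels, g_rows = [], [], []
    for k in range(n_pops):
        pop = f"pop{k + 1}"
        H = _sim_haplotypes(P[k], config.n_per_pop, config, rng)
        g_rows.append(H.sum(axis=2, dtype=np.int8))
        for i in range(config.n_per_pop):
            sample_names.append(f"{pop}_ind{i + 1:03d}")
            labels.append(pop)
    G = (
        np.vstack(g_rows)
        if g_rows
        else np.zeros((n_pops * config.n_per_pop, 0), dtype=np.int8)
    )
    pops = pd.Series(labels, index=sample_names)
    return GenotypeDataset(samples=sample_names, markers=markers, G=G, populations=pops)


def _sim_haplotypes(
    p: np.ndarray, n: int, config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """(n, m, 2) haplotype alleles with latent-copying LD inside blocks."""
    m = len(p)
    bs = config.ld_block_size
    if bs == 1 or config.ld_leak >= 1.0:
        return (rng.random((n, m, 2)) < p[None, :, None]).astype(np.uint8)
    H = np.empty((n, m, 2), dtype=np.uint8)
    for start in range(0, m, bs):
        stop = min(start + bs, m)
        u = np.empty((n, 2))
        for j in range(start, stop):
            fresh = rng.random((n, 2))
            if j == start:
                u = fresh
            else:
                redraw = rng.random((n, 2)) < config.ld_leak
                u = np.where(redraw, fresh, u)
            H[:, j, :] = (u < p[j]).astype(np.uint8)
    return H


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


@dataclass
class _Pedigree:
    # member id -> (father id | None, mother id | None); insertion order is
    # generational order (parents always precede children)
    members: dict = field(default_factory=dict)

    def add_founder(self, name: str) -> str:
        self.members[name] = (None, None)
        return name

    def add_child(self, name: str, father: str, mother: str) -> str:
        for parent in (father, mother):
            if parent not in self.members:
                raise ValueError(
                    f"parent {parent!r} of {name!r} not defined before the child "
                    "(cyclic or out-of-order pedigree)"
                )
        if name in self.members:
            raise ValueError(f"duplicate pedigree member {name!r}")
        self.members[name] = (father, mother)
        return name

    def kinship_matrix(self) -> pd.DataFrame:
        """Expected kinships by the standard pedigree recursion."""
        names = list(self.members)
        idx = {s: i for i, s in enumerate(names)}
        n = len(names)
        K = np.zeros((n, n))
        for i, s in enumerate(names):
            f, mo = self.members[s]
            if f is None:
                K[i, i] = 0.5
            else:
                K[i, i] = 0.5 * (1.0 + K[idx[f], idx[mo]])
            for j in range(i):
                if f is None:
                    K[i, j] = K[j, i] = 0.0
                else:
                    K[i, j] = K[j, i] = 0.5 * (K[idx[f], j] + K[idx[mo], j])
        return pd.DataFrame(K, index=names, columns=names)


def _build_design_pedigree(design: PedigreeDesign) -> tuple[_Pedigree, list[str]]:
    ped = _Pedigree()
    founders: list[str] = []

    def founder(tag):
        name = f"{tag}"
        founders.append(name)
        return ped.add_founder(name)

    u = 0
    for _ in range(design.n_parent_offspring):
        u += 1
        f, m = founder(f"po{u}_f"), founder(f"po{u}_m")
        ped.add_child(f"po{u}_c", f, m)
    for _ in range(design.n_full_sib):
        u += 1
        f, m = founder(f"fs{u}_f"), founder(f"fs{u}_m")
        ped.add_child(f"fs{u}_c1", f, m)
        ped.add_child(f"fs{u}_c2", f, m)
    for _ in range(design.n_half_sib):
        u += 1
        f = founder(f"hs{u}_f")
        m1, m2 = founder(f"hs{u}_m1"), founder(f"hs{u}_m2")
        ped.add_child(f"hs{u}_c1", f, m1)
        ped.add_child(f"hs{u}_c2", f, m2)
    for _ in range(design.n_cousin):
        u += 1
        gf, gm = founder(f"cz{u}_gf"), founder(f"cz{u}_gm")
        sp1, sp2 = founder(f"cz{u}_s1"), founder(f"cz{u}_s2")
        ped.add_child(f"cz{u}_a", gf, gm)
        ped.add_child(f"cz{u}_b", gf, gm)
        ped.add_child(f"cz{u}_c1", f"cz{u}_a", sp1)
        ped.add_child(f"cz{u}_c2", f"cz{u}_b", sp2)
    for i in range(design.n_unrelated):
        founder(f"un{i + 1}")
    return ped, founders


def sim_pedigree(
    founder_freqs: np.ndarray,
    design: PedigreeDesign,
    seed: int | np.random.Generator = 0,
    config: SimConfig | None = None,
    sample_prefix: str = "ped",
) -> tuple[GenotypeDataset, PedigreeTruth]:
    """Gene-drop a designed pedigree from population allele frequencies.

    Founder haplotypes are Bernoulli draws from ``founder_freqs``; each child
    receives one uniformly chosen allele from each parent per marker,
    independently across markers.  The truth table lists every dyad involving
    at least one non-founder, with the pedigree-expected kinship and a degree
    label (1st / 2nd / 3rd / unrelated).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(founder_freqs, dtype=float)
    if config is None:
        config = SimConfig(n_markers=len(p))
    config.validate()
    ped, founders = _build_design_pedigree(design)
    names = list(ped.members)
    m = len(p)

    H: dict[str, np.ndarray] = {}
    for s in names:
        f, mo = ped.members[s]
        if f is None:
            H[s] = (rng.random((m, 2)) < p[:, None]).astype(np.uint8)
        else:
            pick_f = rng.integers(0, 2, size=m)
            pick_m = rng.integers(0, 2, size=m)
            H[s] = np.stack(
                [H[f][np.arange(m), pick_f], H[mo][np.arange(m), pick_m]], axis=1
            )

    markers = _marker_map(replace(config, n_markers=m, ld_block_size=1), rng)
    full_names = [f"{sample_prefix}_{s}" for s in names]
    G = np.stack([H[s].sum(axis=1, dtype=np.int8) for s in names])
    ds = GenotypeDataset(samples=full_names, markers=markers, G=G)

    K = ped.kinship_matrix()
    founder_set = set(founders)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if a in founder_set and b in founder_set:
                continue
            phi = float(K.loc[a, b])
            degree = PedigreeTruth.DEGREE_BY_KINSHIP.get(phi)
            if degree is None:  # degrees beyond 3rd do not arise from these units
                degree = "other"
            rows.append((f"{sample_prefix}_{a}", f"{sample_prefix}_{b}", phi, degree))
    parent_rows = [
        (f"{sample_prefix}_{s}", f"{sample_prefix}_{f}", f"{sample_prefix}_{mo}")
        for s, (f, mo) in ped.members.items()
        if f is not None
    ]
    truth = PedigreeTruth(
        dyads=pd.DataFrame(rows, columns=["sample_a", "sample_b", "kinship", "degree"]),
        parents=pd.DataFrame(parent_rows, columns=["child", "father", "mother"]),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# Corruption and sequencing artefacts
# ---------------------------------------------------------------------------


def corrupt_genotypes(
    ds: GenotypeDataset,
    miss_rate: float,
    error_rate: float,
    seed: int | np.random.Generator = 0,
) -> GenotypeDataset:
    """Knock out calls at ``miss_rate`` and perturb survivors at ``error_rate``.

    An erroneous call is replaced by one of the two other valid dosages,
    chosen uniformly.  Marker and sample metadata are untouched.
    """
    for name, r in (("miss_rate", miss_rate), ("error_rate", error_rate)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = ds.copy()
    G = out.G
    called = G != MISSING
    drop = called & (rng.random(G.shape) < miss_rate)
    G[drop] = MISSING
    surviving = (G != MISSING)
    err = surviving & (rng.random(G.shape) < error_rate)
    # shift by 1 or 2 mod 3 lands on a different valid dosage uniformly
    shift = rng.integers(1, 3, size=G.shape).astype(np.int8)
    G[err] = (G[err] + shift[err]) % 3
    return out


def sim_seq_artifacts(
    ds: GenotypeDataset,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Attach negative-binomial DP and deterministic GQ; DP = 0 kills the call.

    DP is negative-binomial with mean ``mean_depth`` and size parameter
    ``depth_dispersion`` (variance mu + mu^2/size), independently per cell.
    GQ = min(gq_cap, round(gq_per_depth * DP)).  Also returns the samples x
    markers depth table used by coverage profiling.
    """
    config.validate()
    rng = config.rng() if rng is None else rng
    out = ds.copy()
    mu, r = config.mean_depth, config.depth_dispersion
    if mu == 0:
        DP = np.zeros(out.G.shape, dtype=np.int32)
    else:
        DP = rng.negative_binomial(r, r / (r + mu), size=out.G.shape).astype(np.int32)
    GQ = np.minimum(config.gq_cap, np.rint(config.gq_per_depth * DP)).astype(np.int32)
    out.G[DP == 0] = MISSING
    out.DP, out.GQ = DP, GQ
    out.validate()
    depth = pd.DataFrame(DP, index=out.samples, columns=out.markers["id"].tolist())
    return out, depth


# ---------------------------------------------------------------------------
# Study-level convenience
# ---------------------------------------------------------------------------


def sim_study(
    config: SimConfig,
    design: PedigreeDesign | None = None,
) -> tuple[GenotypeDataset, pd.DataFrame, PedigreeTruth | None]:
    """Simulate the full study layout: drifted populations, optional pedigrees.

    With a :class:`PedigreeDesign`, each population is populated by
    gene-dropping that design from its drifted allele frequencies (relatives
    never cross populations), and ``n_per_pop`` is ignored in favour of the
    design's member count.  Without one, plain Hardy–Weinberg sampling is
    used.  Missingness/error corruption from the config is applied last.

    Returns ``(dataset, per-population frequency table, truth-or-None)``.
    """
    config.validate()
    rng = config.rng()
    freqs = sim_structured_freqs(config, rng)
    if design is None:
        ds = sim_genotypes(freqs, config, rng)
        truth = None
    else:
        parts, truths, parent_tabs = [], [], []
        markers = None
        for k, pop in enumerate(freqs.index):
            part, t = sim_pedigree(
                freqs.iloc[k].to_numpy(), design, rng, config, sample_prefix=pop
            )
            if markers is None:
                markers = part.markers
            else:
                part = GenotypeDataset(
                    samples=part.samples, markers=markers, G=part.G, DP=part.DP, GQ=part.GQ
                )
            part.populations = pd.Series([pop] * part.n_samples, index=part.samples)
            parts.append(part)
            truths.append(t.dyads)
            parent_tabs.append(t.parents)
        ds = concat_samples(parts)
        truth = PedigreeTruth(
            dyads=pd.concat(truths, ignore_index=True),
            parents=pd.concat(parent_tabs, ignore_index=True),
        )
    if config.miss_rate > 0 or config.error_rate > 0:
        ds = corrupt_genotypes(ds, config.miss_rate, config.error_rate, rng)
    return ds, freqs, truth


def write_truth_table(truth: PedigreeTruth, path) -> None:
    truth.dyads.to_csv(path, sep="\t", index=False)
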