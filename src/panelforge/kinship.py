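"""Structure-adjusted pairwise kinship (the PC-Relate estimator), degree
classification, and cross-panel kinship comparison.

The estimator replaces population allele frequencies with individual-specific
frequencies predicted from principal components, removing the bias that
population structure induces in classical kinship estimates.  For each marker
``s`` the dosage is regressed on an intercept plus the leading PCs by
ordinary least squares; half the fitted value is the individual-specific
frequency ``mu_is``, clipped into ``[eps, 1 - eps]``.  The kinship of samples
``i, j`` is then

    phi_ij = sum_s (g_is - 2 mu_is)(g_js - 2 mu_js)
             / [ 4 sum_s sqrt(mu_is (1 - mu_is)) sqrt(mu_js (1 - mu_js)) ]

with both sums over the markers where both genotypes are called (no
imputation inside the estimator).  The diagonal of the same moment ratio
estimates ``(1 + f_i) / 2``, giving a per-sample inbreeding estimate.

Close relatives distort the frequency model if they are allowed to train it:
a principal component that captures a large family deflates that family's
kinship estimates.  The default therefore fits the PCA and the per-marker
regressions on a mutually unrelated training subset — chosen deterministically
with the structure-robust within-family (KING-robust) estimator and a greedy
maximal-degree removal — and only predicts ``mu`` for the remaining samples
(``training="all"`` disables this and uses every sample).  This is a single
partition pass, not an iterative refinement.  With zero PCs the fitted value
collapses to the sample allele frequency and the estimator reduces exactly to
the classical frequency-standardized kinship estimator (all samples train, so
the reduction is exact).

Presented statsmodels-style: ``PCRelate(ds, n_pcs).fit()`` returns a
:class:`PCRelateResults` carrying the kinship matrix, dyad table, inbreeding
estimates and ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .dataio import MISSING, GenotypeDataset
from .structure import fit_pca

__all__ = [
    "PCRelate",
    "PCRelateResults",
    "KinshipResult",
    "pcrelate",
    "king_robust_kinship",
    "unrelated_subset",
    "classify_degree",
    "compare_kinship",
    "DEFAULT_DEGREE_THRESHOLDS",
]

#: Powers-of-two midpoint cut-offs: 2^-5/2, 2^-7/2, 2^-9/2 separate
#: 1st / 2nd / 3rd degree / unrelated.
DEFAULT_DEGREE_THRESHOLDS = (2 ** -2.5, 2 ** -3.5, 2 ** -4.5)


def king_robust_kinship(ds: GenotypeDataset) -> np.ndarray:
    """Within-family (KING-robust) kinship for all pairs.

    ``phi = (N_het,het - 2 N_opposing_hom) / (N_het_i + N_het_j)`` over
    pairwise-complete markers.  Robust to population structure for related
    pairs; pairs from diverged populations come out negative, which is
    exactly what makes it a safe relatedness screen.  NaN where the
    denominator is zero.
    """
    called = ds.G != MISSING
    H = ((ds.G == 1) & called).astype(np.float64)
    A0 = ((ds.G == 0) & called).astype(np.float64)
    A2 = ((ds.G == 2) & called).astype(np.float64)
    C = called.astype(np.float64)
    n_het_het = H @ H.T
    n_opposing = A0 @ A2.T + A2 @ A0.T
    het_i = H @ C.T  # het count of i over markers shared with j
    denom = het_i + het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (n_het_het - 2.0 * n_opposing) / denom, np.nan)


def unrelated_subset(
    ds: GenotypeDataset, threshold: float = DEFAULT_DEGREE_THRESHOLDS[2]
) -> np.ndarray:
    """Boolean mask of a mutually unrelated sample subset.

    Pairs with KING-robust kinship above ``threshold`` (3rd-degree cut by
    default) are linked; samples are greedily removed in order of remaining
    relative count (ties to the earlier sample index) until no link survives.
    Deterministic.
    """
    phi = king_robust_kinship(ds)
    rel = np.nan_to_num(phi, nan=0.0) > threshold
    np.fill_diagonal(rel, False)
    keep = np.ones(ds.n_samples, dtype=bool)
    while True:
        active = rel & keep[None, :] & keep[:, None]
        degree = active.sum(axis=1)
        if degree.max(initial=0) == 0:
            return keep
        keep[int(np.argmax(degree))] = False


class PCRelate:
    """PC-Relate kinship model for a genotype dataset.

    Parameters
    ----------
    ds
        Dataset with polymorphic markers (monomorphic markers contribute
        nothing and should be QC-filtered first).
    n_pcs
        Number of principal components used to predict individual-specific
        allele frequencies; 0 gives the classical unadjusted estimator.
    eps
        Clipping bound for the individual-specific frequencies; clipped
        values still contribute (keeps dyad marker counts stable).
    training
        ``"unrelated"`` (default for ``n_pcs > 0``): fit PCA and regressions
        on a KING-partitioned mutually unrelated subset; ``"all"``: fit on
        every sample; or an explicit list of training sample ids.  With
        ``n_pcs == 0`` the default is ``"all"`` (the classical estimator).
    """

    def __init__(
        self,
        ds: GenotypeDataset,
        n_pcs: int = 2,
        eps: float = 0.01,
        training: str | list[str] | None = None,
    ):
        if n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if n_pcs >= ds.n_samples:
            raise ValueError(
                f"n_pcs={n_pcs} must be smaller than the sample count {ds.n_samples}"
            )
        if not 0.0 < eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")
        if training is None:
            training = "all" if n_pcs == 0 else "unrelated"
        self.ds = ds
        self.n_pcs = n_pcs
        self.eps = eps
        self.training = training

    def _training_mask(self) -> np.ndarray:
        ds = self.ds
        if isinstance(self.training, str):
            if self.training == "all":
                return np.ones(ds.n_samples, dtype=bool)
            if self.training == "unrelated":
                return unrelated_subset(ds)
            raise ValueError(f"unknown training spec {self.training!r}")
        wanted = set(self.training)
        absent = wanted - set(ds.samples)
        if absent:
            raise ValueError(f"training samples absent from dataset: {sorted(absent)}")
        return np.array([s in wanted for s in ds.samples])

    def fit(self) -> "PCRelateResults":
        ds, n_pcs, eps = self.ds, self.n_pcs, self.eps
        G = ds.G.astype(np.float64)
        called = ds.G != MISSING
        n, m = G.shape
        keep = self._training_mask()
        if keep.sum() <= n_pcs + 1:
            raise ValueError(
                f"training subset of {int(keep.sum())} samples is too small for "
                f"{n_pcs} PCs"
            )

        train = ds if keep.all() else ds.subset_samples(keep)
        if n_pcs == 0:
            mu = np.broadcast_to(train.alt_allele_freq(), (n, m)).copy()
        else:
            pca = fit_pca(train, n_pcs)
            X_all = np.column_stack([np.ones(n), pca.transform(ds)])
            mu = _regress_mu(X_all, G, called, keep)
        mu = np.clip(mu, eps, 1.0 - eps)

        R = np.where(called, G - 2.0 * mu, 0.0)
        S = np.where(called, np.sqrt(mu * (1.0 - mu)), 0.0)
        num = R @ R.T
        den = 4.0 * (S @ S.T)
        n_shared = called.astype(np.int32) @ called.astype(np.int32).T
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(den > 0, num / den, np.nan)

        self_kin = np.diag(phi)
        inbreeding = 2.0 * self_kin - 1.0
        return PCRelateResults(
            samples=list(ds.samples),
            kinship=phi,
            self_kinship=self_kin,
            inbreeding=inbreeding,
            mu=mu,
            n_pcs=n_pcs,
            eps=eps,
            n_shared_markers=n_shared,
            training_mask=keep,
            populations=None if ds.populations is None else ds.populations.copy(),
        )


def _regress_mu(
    X_all: np.ndarray, G: np.ndarray, called: np.ndarray, keep: np.ndarray
) -> np.ndarray:
    """Per-marker OLS of dosage on the design over called training samples,
    batched across markers via masked normal equations; predicts mu for all
    samples.  Falls back to lstsq for (near-)singular markers."""
    n, m = G.shape
    p = X_all.shape[1]
    X_tr = X_all[keep]
    M = called[keep].astype(np.float64)  # (n_tr, m)
    G_tr = np.where(called[keep], G[keep], 0.0)

    A = np.empty((m, p, p))
    for a in range(p):
        for b in range(a, p):
            v = M.T @ (X_tr[:, a] * X_tr[:, b])
            A[:, a, b] = v
            A[:, b, a] = v
    B = G_tr.T @ X_tr  # (m, p)

    beta = np.empty((m, p))
    dets = np.linalg.det(A)
    good = np.abs(dets) > 1e-10
    if good.any():
        beta[good] = np.linalg.solve(A[good], B[good][..., None])[..., 0]
    for s in np.flatnonzero(~good):
        ok = M[:, s] > 0
        beta[s], *_ = np.linalg.lstsq(X_tr[ok], G_tr[ok, s], rcond=None)
    return (X_all @ beta.T) / 2.0


@dataclass
class PCRelateResults:
    """Fitted PC-Relate kinship estimates.

    ``kinship`` is a symmetric n x n matrix of dyad coefficients (NaN where a
    dyad shares no usable marker); ``mu`` holds the individual-specific
    frequencies; ``n_shared_markers`` the per-dyad usable marker counts;
    ``training_mask`` flags the samples that trained the frequency model.
    """

    samples: list[str]
    kinship: np.ndarray
    self_kinship: np.ndarray
    inbreeding: np.ndarray
    mu: np.ndarray
    n_pcs: int
    eps: float
    n_shared_markers: np.ndarray
    training_mask: np.ndarray
    populations: pd.Series | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def dyads(self) -> pd.DataFrame:
        """All n(n-1)/2 dyads: id_a, id_b, kinship, n_markers."""
        rows = []
        for i in range(self.n_samples):
            for j in range(i + 1, self.n_samples):
                rows.append(
                    (
                        self.samples[i],
                        self.samples[j],
                        self.kinship[i, j],
                        int(self.n_shared_markers[i, j]),
                    )
                )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "kinship", "n_markers"])

    def degree_table(self, thresholds=DEFAULT_DEGREE_THRESHOLDS) -> pd.DataFrame:
        return classify_degree(self, thresholds)

    def kinship_of(self, a: str, b: str) -> float:
        ia, ib = self.samples.index(a), self.samples.index(b)
        return float(self.kinship[ia, ib])

    def summary(self) -> str:
        d = self.dyads()
        counts = self.degree_table()["degree"].value_counts()
        lines = [
            "PC-Relate kinship",
            "=================",
            f"samples: {self.n_samples}, dyads: {len(d)}, PCs used: {self.n_pcs}",
            f"frequency-model training samples: {int(self.training_mask.sum())}",
            f"mean pairwise kinship: {np.nanmean(d['kinship']):.3f} "
            f"(S.D. {np.nanstd(d['kinship'], ddof=1):.3f})",
            "dyads by degree: "
            + ", ".join(
                f"{k}: {counts.get(k, 0)}" for k in ("1st", "2nd", "3rd", "unrelated")
            ),
            f"mean inbreeding estimate: {np.mean(self.inbreeding):.3f}",
        ]
        return "\n".join(lines)

    def write_dyads(self, path, thresholds=DEFAULT_DEGREE_THRESHOLDS) -> None:
        self.degree_table(thresholds).to_csv(path, sep="\t", index=False)

    def write_matrix(self, path) -> None:
        pd.DataFrame(self.kinship, index=self.samples, columns=self.samples).to_csv(
            path, sep="\t"
        )


#: Back-compat alias matching the pipeline vocabulary.
KinshipResult = PCRelateResults


def pcrelate(
    ds: GenotypeDataset,
    n_pcs: int = 2,
    eps: float = 0.01,
    training: str | list[str] | None = None,
) -> PCRelateResults:
    """Functional wrapper: ``PCRelate(ds, n_pcs, eps, training).fit()``."""
    return PCRelate(ds, n_pcs, eps, training).fit()


def classify_degree(
    kin: PCRelateResults | pd.DataFrame, thresholds=DEFAULT_DEGREE_THRESHOLDS
) -> pd.DataFrame:
    """Attach a relationship-degree class to every dyad.

    phi > t1 -> 1st; (t2, t1] -> 2nd; (t3, t2] -> 3rd; <= t3 -> unrelated.
    Thresholds must be strictly decreasing and positive.
    """
    t1, t2, t3 = thresholds
    if not (t1 > t2 > t3 > 0):
        raise ValueError(f"thresholds must be strictly decreasing and positive: {thresholds}")
    table = kin.dyads() if isinstance(kin, PCRelateResults) else kin.copy()
    phi = table["kinship"].to_numpy(dtype=float)
    degree = np.select(
        [phi > t1, phi > t2, phi > t3], ["1st", "2nd", "3rd"], default="unrelated"
    )
    degree = np.where(np.isnan(phi), "undefined", degree)
    out = table.copy()
    out["degree"] = degree
    out.attrs["thresholds"] = tuple(thresholds)
    return out


def compare_kinship(
    kinA: PCRelateResults, kinB: PCRelateResults
) -> tuple[float, float, int, int]:
    """Pearson correlation of dyad kinships across two panels.

    Dyads are matched by unordered sample-id pair over the shared samples;
    returns ``(r, t, df, n_dyads)`` with ``t = r sqrt(df) / sqrt(1 - r^2)``
    and ``df = n_dyads - 2``.
    """
    shared = [s for s in kinA.samples if s in set(kinB.samples)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, found {len(shared)}")
    ia = {s: kinA.samples.index(s) for s in shared}
    ib = {s: kinB.samples.index(s) for s in shared}
    va, vb = [], []
    for x in range(len(shared)):
        for y in range(x + 1, len(shared)):
            a, b = shared[x], shared[y]
            va.append(kinA.kinship[ia[a], ia[b]])
            vb.append(kinB.kinship[ib[a], ib[b]])
    va = np.asarray(va)
    vb = np.asarray(vb)
    ok = ~np.isnan(va) & ~np.isnan(vb)
    va, vb = va[ok], vb[ok]
    n = len(va)
    if n < 3:
        raise ValueError("fewer than 3 usable dyads")
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in a kinship vector; correlation undefined")
    r = float(scipy.stats.pearsonr(va, vb).statistic)
    df = n - 2
    if abs(r) >= 1.0:
        t = float("inf") if r > 0 else float("-inf")
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    return r, float(t), df, n
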