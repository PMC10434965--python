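"""Population structure: PCA, discriminant analysis of principal components
(DAPC), and repeated stratified cross-validation of assignment success.

DAPC with a-priori group labels first reduces the standardized genotype
matrix to ``n_pcs`` principal components, then finds linear discriminant axes
maximizing the between-group to within-group variance ratio of the PC scores
(the generalized eigenproblem ``B a = lambda W a`` with axes scaled so
``a' W a = 1``).  Per-marker loadings on each discriminant axis follow by
composing the PCA loadings with the discriminant coefficients, and the
normalized squared loadings ("contributions", summing to 1 per axis) rank
markers by how much they separate the groups — the quantity the panel-design
stage thresholds.

The estimator is presented statsmodels-style: build a :class:`DAPC` model
from a labelled dataset, call :meth:`DAPC.fit`, and work with the returned
:class:`DAPCResults` (predict, posteriors, contributions, ``summary()``).
Functional wrappers (:func:`fit_pca`, :func:`fit_dapc`, :func:`predict_dapc`,
:func:`crossvalidate_dapc`) mirror the pipeline-stage vocabulary.

Standardization centres each marker by its mean dosage and scales by the
binomial SD ``sqrt(2 p (1-p))`` of the allele frequency (plain SD or no
scaling are available); missing dosages are mean-imputed, and all
standardization parameters are stored in the model so that new samples are
projected with the training parameters, never refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .dataio import MISSING, GenotypeDataset

__all__ = [
    "PCAModel",
    "fit_pca",
    "DAPC",
    "DAPCResults",
    "fit_dapc",
    "predict_dapc",
    "XValReport",
    "crossvalidate_dapc",
    "default_k_grid",
]


# ---------------------------------------------------------------------------
# Standardization + PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Genotype PCA: standardization parameters, loadings, eigenvalues.

    ``loadings`` columns are orthonormal; ``eigenvalues`` are the variances of
    the corresponding score axes (non-increasing); ``explained`` are fractions
    of the total standardized variance.
    """

    markers: pd.DataFrame
    center: np.ndarray  # per-marker mean dosage (also the imputation value)
    scale: np.ndarray  # per-marker divisor (1 where zero variance)
    loadings: np.ndarray  # (m, K), orthonormal columns
    eigenvalues: np.ndarray  # (K,), non-increasing
    total_variance: float
    scaling: str = "binomial"

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def explained(self) -> np.ndarray:
        if self.total_variance == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.total_variance

    def standardize(self, ds: GenotypeDataset) -> np.ndarray:
        """Impute, centre and scale ``ds`` with the stored training parameters."""
        _check_marker_match(self.markers, ds.markers)
        X = ds.G.astype(float)
        miss = ds.G == MISSING
        X[miss] = np.broadcast_to(self.center, X.shape)[miss]
        return (X - self.center) / self.scale

    def transform(self, ds: GenotypeDataset, k: int | None = None) -> np.ndarray:
        """Project samples onto the leading ``k`` principal axes."""
        k = self.n_components if k is None else k
        return self.standardize(ds) @ self.loadings[:, :k]


def _check_marker_match(ref: pd.DataFrame, new: pd.DataFrame) -> None:
    ref_keys = list(zip(ref["chrom"], ref["pos"], ref["ref"], ref["alt"]))
    new_keys = list(zip(new["chrom"], new["pos"], new["ref"], new["alt"]))
    if ref_keys != new_keys:
        missing = sorted(set(map(tuple, ref_keys)) - set(map(tuple, new_keys)))[:10]
        raise ValueError(
            "marker set of the new data does not match the model "
            f"(same keys and allele orientation required); first mismatches: {missing}"
        )


def _standardization(ds: GenotypeDataset, scaling: str):
    p = ds.alt_allele_freq()
    if np.isnan(p).any():
        bad = ds.markers.loc[np.isnan(p), ["chrom", "pos"]]
        raise ValueError(f"markers with all genotypes missing: {bad.values.tolist()[:5]}")
    center = 2.0 * p
    if scaling == "binomial":
        scale = np.sqrt(2.0 * p * (1.0 - p))
    elif scaling == "sd":
        X = ds.G.astype(float)
        X[ds.G == MISSING] = np.nan
        scale = np.sqrt(np.nanvar(X, axis=0))
    elif scaling == "none":
        scale = np.ones_like(p)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    scale = np.where(scale == 0.0, 1.0, scale)
    return center, scale


def fit_pca(ds: GenotypeDataset, k: int, scaling: str = "binomial") -> PCAModel:
    """Fit a genotype PCA with ``k`` components.

    ``k`` must be at most ``min(n_samples - 1, n_markers)``.  Missing dosages
    are mean-imputed per marker before centring/scaling; eigenvalues are those
    of the sample covariance of the standardized matrix.
    """
    bound = min(ds.n_samples - 1, ds.n_markers)
    if not 1 <= k <= bound:
        raise ValueError(
            f"k={k} out of range; must satisfy 1 <= k <= min(n_samples - 1, "
            f"n_markers) = {bound}"
        )
    center, scale = _standardization(ds, scaling)
    X = ds.G.astype(float)
    miss = ds.G == MISSING
    X[miss] = np.broadcast_to(center, X.shape)[miss]
    X = (X - center) / scale
    X -= X.mean(axis=0)  # imputation can shift the realized column means

    n = ds.n_samples
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = (s**2) / (n - 1)
    total = float((X**2).sum()) / (n - 1)
    return PCAModel(
        markers=ds.markers.copy(),
        center=center,
        scale=scale,
        loadings=Vt[:k].T.copy(),
        eigenvalues=eigvals[:k].copy(),
        total_variance=total,
        scaling=scaling,
    )


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------


class DAPC:
    """Discriminant analysis of principal components with a-priori groups.

    Parameters
    ----------
    ds
        Labelled :class:`GenotypeDataset` (populations attached).
    n_pcs
        Number of principal components retained before the discriminant step.
    n_axes
        Number of discriminant axes; defaults to ``min(n_groups - 1, n_pcs)``.
    scaling
        Genotype standardization passed to the PCA step.
    """

    def __init__(
        self,
        ds: GenotypeDataset,
        n_pcs: int,
        n_axes: int | None = None,
        scaling: str = "binomial",
    ):
        if ds.populations is None:
            raise ValueError("DAPC requires a dataset with population labels")
        labels = ds.population_labels
        groups, counts = np.unique(labels, return_counts=True)
        if len(groups) < 2:
            raise ValueError("DAPC requires at least two populations")
        if (counts < 2).any():
            small = groups[counts < 2].tolist()
            raise ValueError(f"every population needs >= 2 samples; too small: {small}")
        self.ds = ds
        self.n_pcs = n_pcs
        self.groups = list(groups)
        self.n_axes = min(len(groups) - 1, n_pcs) if n_axes is None else n_axes
        if not 1 <= self.n_axes <= min(len(groups) - 1, n_pcs):
            raise ValueError(
                f"n_axes={n_axes} out of range; bound is min(n_groups - 1, n_pcs) "
                f"= {min(len(groups) - 1, n_pcs)}"
            )
        self.scaling = scaling

    def fit(self) -> "DAPCResults":
        pca = fit_pca(self.ds, self.n_pcs, self.scaling)
        scores = pca.transform(self.ds)
        return _fit_discriminant(self.ds, pca, scores, self.groups, self.n_axes)


def _fit_discriminant(ds, pca, scores, groups, n_axes) -> "DAPCResults":
    labels = ds.population_labels
    n, k = scores.shape
    g = len(groups)
    grand = scores.mean(axis=0)
    W = np.zeros((k, k))
    B = np.zeros((k, k))
    group_means = {}
    for grp in groups:
        sel = scores[labels == grp]
        mu = sel.mean(axis=0)
        group_means[grp] = mu
        dev = sel - mu
        W += dev.T @ dev
        dm = (mu - grand)[:, None]
        B += len(sel) * (dm @ dm.T)
    W /= n - g
    B /= n - 1

    try:
        eigvals, eigvecs = scipy.linalg.eigh(B, W)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "within-group scatter is singular; retain fewer principal components"
        ) from exc
    order = np.argsort(eigvals)[::-1][:n_axes]
    disc_eigvals = eigvals[order]
    A = eigvecs[:, order]  # scipy.linalg.eigh normalizes a' W a = 1

    centroids = {grp: mu @ A for grp, mu in group_means.items()}
    marker_loadings = pca.loadings[:, :k] @ A
    sq = marker_loadings**2
    colsum = sq.sum(axis=0)
    contributions = sq / np.where(colsum == 0.0, 1.0, colsum)

    all_pos = eigvals[eigvals > 0]
    axis_share = disc_eigvals / all_pos.sum() if all_pos.sum() > 0 else disc_eigvals * 0.0

    return DAPCResults(
        pca=pca,
        groups=list(groups),
        coef=A,
        disc_eigenvalues=disc_eigvals,
        axis_variance_share=axis_share,
        centroids=centroids,
        marker_loadings=marker_loadings,
        contributions=contributions,
        training_scores=scores @ A,
        training_labels=np.asarray(labels),
        training_samples=list(ds.samples),
    )


@dataclass
class DAPCResults:
    """Fitted DAPC: discriminant axes, centroids, per-marker contributions."""

    pca: PCAModel
    groups: list[str]
    coef: np.ndarray  # (n_pcs, n_axes), a' W a = 1 per axis
    disc_eigenvalues: np.ndarray
    axis_variance_share: np.ndarray  # per-axis share of between-group variance
    centroids: dict[str, np.ndarray]
    marker_loadings: np.ndarray  # (m, n_axes), standardized-genotype scale
    contributions: np.ndarray  # (m, n_axes), columns sum to 1
    training_scores: np.ndarray
    training_labels: np.ndarray
    training_samples: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return self.coef.shape[1]

    @property
    def markers(self) -> pd.DataFrame:
        return self.pca.markers

    def discriminant_scores(self, ds: GenotypeDataset) -> np.ndarray:
        """Project ``ds`` into discriminant space with the training parameters."""
        return self.pca.transform(ds) @ self.coef

    def posterior(self, ds: GenotypeDataset) -> pd.DataFrame:
        """Posterior membership per sample: isotropic Gaussian around each
        centroid in discriminant space, equal priors, rows summing to 1."""
        scores = self.discriminant_scores(ds)
        d2 = np.stack(
            [((scores - self.centroids[g]) ** 2).sum(axis=1) for g in self.groups], axis=1
        )
        logp = -0.5 * d2
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        p /= p.sum(axis=1, keepdims=True)
        return pd.DataFrame(p, index=ds.samples, columns=self.groups)

    def predict(self, ds: GenotypeDataset) -> pd.Series:
        """Assigned population per sample (argmax posterior; ties break by
        population order, deterministically)."""
        post = self.posterior(ds)
        idx = np.argmax(post.to_numpy(), axis=1)
        return pd.Series([self.groups[i] for i in idx], index=ds.samples, name="assigned")

    def contributions_frame(self) -> pd.DataFrame:
        out = self.markers[["chrom", "pos", "id"]].copy()
        for d in range(self.n_axes):
            out[f"LD{d + 1}"] = self.contributions[:, d]
        return out

    def summary(self) -> str:
        lines = [
            "DAPC results",
            "============",
            f"samples:            {len(self.training_samples)}",
            f"markers:            {len(self.markers)}",
            f"populations:        {', '.join(self.groups)}",
            f"PCs retained:       {self.pca.n_components}"
            f"  (PC variance kept: {self.pca.explained.sum():.1%})",
            f"discriminant axes:  {self.n_axes}",
        ]
        for d in range(self.n_axes):
            lines.append(
                f"  LD{d + 1}: eigenvalue {self.disc_eigenvalues[d]:.4f}, "
                f"{self.axis_variance_share[d]:.1%} of between-group variance"
            )
        acc = float((self.predict_training() == self.training_labels).mean())
        lines.append(f"training re-assignment: {acc:.1%}")
        return "\n".join(lines)

    def predict_training(self) -> np.ndarray:
        d2 = np.stack(
            [
                ((self.training_scores - self.centroids[g]) ** 2).sum(axis=1)
                for g in self.groups
            ],
            axis=1,
        )
        return np.array([self.groups[i] for i in np.argmin(d2, axis=1)])

    def plot_scores(self, ax=None):
        """Scatter of the first two discriminant axes (or a 1-D strip)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g in self.groups:
            sel = self.training_scores[self.training_labels == g]
            if self.n_axes >= 2:
                ax.scatter(sel[:, 0], sel[:, 1], label=g, s=12)
            else:
                ax.scatter(sel[:, 0], np.zeros(len(sel)), label=g, s=12)
        ax.set_xlabel("LD1")
        ax.set_ylabel("LD2" if self.n_axes >= 2 else "")
        ax.legend()
        return ax


def fit_dapc(
    ds: GenotypeDataset, n_pcs: int, n_axes: int | None = None, scaling: str = "binomial"
) -> DAPCResults:
    """Functional wrapper: ``DAPC(ds, n_pcs, n_axes).fit()``."""
    return DAPC(ds, n_pcs, n_axes, scaling).fit()


def predict_dapc(results: DAPCResults, ds: GenotypeDataset) -> tuple[pd.Series, pd.DataFrame]:
    """Assigned population and posterior membership for new samples."""
    return results.predict(ds), results.posterior(ds)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class XValReport:
    """Repeated stratified cross-validation of DAPC assignment success.

    ``table`` has one row per PC-grid point with the mean held-out assignment
    success and the root mean squared error ``sqrt(mean((1 - success)^2))``
    over replicates; ``chosen_k`` minimizes the RMSE (ties to the smaller K).
    """

    table: pd.DataFrame  # columns: n_pcs, mean_success, rmse
    chosen_k: int
    n_replicates: int
    train_frac: float
    seed: int
    successes: pd.DataFrame | None = None  # replicates x grid, per-replicate success

    @property
    def mean_success_at_chosen(self) -> float:
        row = self.table[self.table["n_pcs"] == self.chosen_k]
        return float(row["mean_success"].iloc[0])

    def mc_sd_at_chosen(self) -> float:
        """Monte-Carlo standard error of the mean success at the chosen K."""
        if self.successes is None:
            raise ValueError("per-replicate successes were not retained")
        s = self.successes[self.chosen_k]
        return float(s.std(ddof=1) / np.sqrt(len(s)))

    def summary(self) -> str:
        lines = [
            "DAPC cross-validation",
            "=====================",
            f"replicates: {self.n_replicates}, train fraction: {self.train_frac}, "
            f"seed: {self.seed}",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            f"chosen number of PCs: {self.chosen_k} "
            f"(mean success {self.mean_success_at_chosen:.4f})",
        ]
        return "\n".join(lines)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# replicates={self.n_replicates} train_frac={self.train_frac} "
                f"seed={self.seed} chosen_k={self.chosen_k}\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)


def default_k_grid(ds: GenotypeDataset, n_points: int = 10) -> list[int]:
    """Ten (by default) evenly spaced PC counts up to
    ``min(n_samples - n_groups, n_markers, 100)``."""
    g = len(np.unique(ds.population_labels))
    top = min(ds.n_samples - g, ds.n_markers, 100)
    if top < 1:
        raise ValueError("dataset too small for cross-validation")
    grid = np.unique(np.linspace(1, top, num=min(n_points, top), dtype=int))
    return [int(v) for v in grid]


def crossvalidate_dapc(
    ds: GenotypeDataset,
    k_grid: list[int] | None = None,
    n_rep: int = 1000,
    train_frac: float = 0.9,
    seed: int = 0,
    scaling: str = "binomial",
) -> XValReport:
    """Stratified repeated train/test DAPC assignment.

    Per replicate: ``train_frac`` of each population (at least one held out)
    trains the model, the held-out rest is predicted, and success is the
    fraction assigned to their true population.  The whole PC grid is
    evaluated on the same splits — the PCA at the largest grid value is
    computed once per replicate and nested column subsets give the smaller
    grid points exactly.
    """
    if ds.populations is None:
        raise ValueError("cross-validation requires population labels")
    labels = ds.population_labels
    groups, counts = np.unique(labels, return_counts=True)
    heldout = counts - np.floor(counts * train_frac).astype(int)
    if (counts < 2).any() or (heldout < 1).any():
        raise ValueError(
            "every population must be large enough to hold out at least one "
            f"sample at train_frac={train_frac}; population sizes: {dict(zip(groups, counts))}"
        )
    if k_grid is None:
        k_grid = default_k_grid(ds)
    k_grid = sorted(set(int(k) for k in k_grid))
    n_train_min = int(sum(np.floor(counts * train_frac)))
    k_cap = n_train_min - len(groups)
    bad = [k for k in k_grid if k < 1 or k > k_cap]
    if bad:
        raise ValueError(
            f"grid values {bad} exceed the usable bound n_train - n_groups = {k_cap}"
        )

    rng = np.random.default_rng(seed)
    kmax = max(k_grid)
    success = np.zeros((n_rep, len(k_grid)))
    idx_by_group = {g: np.flatnonzero(labels == g) for g in groups}

    for rep in range(n_rep):
        train_idx, test_idx = [], []
        for g in groups:
            idx = rng.permutation(idx_by_group[g])
            n_tr = int(np.floor(len(idx) * train_frac))
            train_idx.extend(idx[:n_tr])
            test_idx.extend(idx[n_tr:])
        train = ds.subset_samples(np.array(sorted(train_idx)))
        test = ds.subset_samples(np.array(sorted(test_idx)))
        pca = fit_pca(train, kmax, scaling)
        scores_all = pca.transform(train)
        test_std_scores = pca.transform(test)
        truth = test.population_labels
        for kj, k in enumerate(k_grid):
            res = _fit_discriminant(
                train, pca, scores_all[:, :k], list(groups), min(len(groups) - 1, k)
            )
            disc = test_std_scores[:, :k] @ res.coef
            d2 = np.stack(
                [((disc - res.centroids[g]) ** 2).sum(axis=1) for g in res.groups], axis=1
            )
            pred = np.array([res.groups[i] for i in np.argmin(d2, axis=1)])
            success[rep, kj] = float((pred == truth).mean())

    mean_success = success.mean(axis=0)
    rmse = np.sqrt(((1.0 - success) ** 2).mean(axis=0))
    table = pd.DataFrame({"n_pcs": k_grid, "mean_success": mean_success, "rmse": rmse})
    chosen = int(table["n_pcs"].iloc[int(np.argmin(rmse))])
    return XValReport(
        table=table,
        chosen_k=chosen,
        n_replicates=n_rep,
        train_frac=train_frac,
        seed=seed,
        successes=pd.DataFrame(success, columns=k_grid),
    )
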