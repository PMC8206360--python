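"""Population-substructure inference on SNP genotypes.

Workflow: mean-impute and centre the dosage matrix, project onto principal
components, then (i) scan the number of clusters K with best-of-starts
K-means and a BIC criterion, and (ii) describe and validate the grouping
with discriminant analysis of principal components (DAPC): a linear
discriminant classifier fitted in the retained-PC subspace, with the PC
count chosen by stratified cross-validation and pairwise hold-out
validation of subgroup separability.

The K-means BIC uses the spherical-Gaussian profile likelihood,
``BIC(K) = n ln(WSS_K / n) + K ln n``; consecutive differences
``delta_bic = BIC(K) - BIC(K+1)`` quantify the evidence for adding one
cluster, with a difference above 2 read as strong evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.model_selection import StratifiedShuffleSplit

from .plink import MISSING, GenotypeDataset


# ---------------------------------------------------------------------------
# centring and PCA
# ---------------------------------------------------------------------------

def center_matrix(data) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages and mean-centre columns (no scaling).

    ``data`` is a :class:`GenotypeDataset` or a raw dosage matrix with
    :data:`MISSING` sentinels.  Returns (centered matrix, per-variant means).
    """
    calls = data.calls if isinstance(data, GenotypeDataset) else np.asarray(data)
    X = calls.astype(float)
    mask = calls == MISSING
    if mask.all(axis=0).any():
        raise ValueError("all-missing variant column (should be removed by QC)")
    X[mask] = np.nan
    means = np.nanmean(X, axis=0)
    X = np.where(mask, means, X) - means
    return X, means


@dataclass
class PCABasis:
    """Principal-component basis of a centred genotype matrix."""

    variant_means: np.ndarray
    loadings: np.ndarray      # variants x components, orthonormal columns
    eigenvalues: np.ndarray   # component variances, non-increasing
    total_variance: float     # sum of all eigenvalues of the data

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def explained_variance_fraction(self, k: int | None = None) -> float:
        k = self.n_components if k is None else k
        return float(self.eigenvalues[:k].sum() / self.total_variance)

    def project_raw(self, calls: np.ndarray, n_pcs: int | None = None) -> np.ndarray:
        """PC scores of raw dosages, centred with the basis's own means."""
        X = np.asarray(calls, dtype=float)
        mask = np.asarray(calls) == MISSING
        X = np.where(mask, self.variant_means, X) - self.variant_means
        L = self.loadings if n_pcs is None else self.loadings[:, :n_pcs]
        return X @ L


def pca(X: np.ndarray, n_components: int | None = None) -> tuple[PCABasis, np.ndarray]:
    """PCA of a centred matrix via SVD; returns (basis, scores).

    Eigenvalues are sample variances of the scores (divisor n - 1).  Signs
    are fixed so each loading column's largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    max_rank = min(n, p)
    if n_components is None:
        n_components = max_rank
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds min(dims)={max_rank}")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    signs = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    Vt = Vt * signs[:, None]
    U = U * signs[None, :]
    eig = S ** 2 / max(n - 1, 1)
    basis = PCABasis(
        variant_means=np.zeros(p),
        loadings=Vt[:n_components].T.copy(),
        eigenvalues=eig[:n_components].copy(),
        total_variance=float(eig.sum()),
    )
    scores = U[:, :n_components] * S[:n_components]
    return basis, scores


def pca_genotypes(data, n_components: int | None = None):
    """Centre a genotype matrix/dataset and run :func:`pca` on it."""
    X, means = center_matrix(data)
    basis, scores = pca(X, n_components)
    basis.variant_means = means
    return basis, scores


# ---------------------------------------------------------------------------
# K-means / BIC scan
# ---------------------------------------------------------------------------

@dataclass
class BICScan:
    k_values: np.ndarray
    wss: np.ndarray
    bic: np.ndarray
    delta_bic: np.ndarray  # bic[K] - bic[K+1] for consecutive K
    k_best: int


def _wss(X: np.ndarray, centers: np.ndarray, labels: np.ndarray) -> float:
    return float(((X - centers[labels]) ** 2).sum())


def kmeans_bic_scan(scores: np.ndarray, k_max: int = 20, n_starts: int = 10,
                    seed: int = 0) -> BICScan:
    """Scan K = 1..k_max with best-of-starts K-means and pick argmin BIC.

    Each K runs ``n_starts`` seeded Lloyd fits initialised at random data
    points, plus one warm start from the previous K's centers augmented with
    the point farthest from its center — which makes WSS(K) non-increasing
    by construction.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    if n <= k_max:
        raise ValueError("need more samples than k_max")
    rng = np.random.default_rng(seed)
    k_values = np.arange(1, k_max + 1)
    wss = np.empty(k_max)
    center_of_mass = X.mean(axis=0, keepdims=True)
    wss[0] = _wss(X, center_of_mass, np.zeros(n, dtype=int))
    prev_centers = center_of_mass
    for K in range(2, k_max + 1):
        best = None
        # warm start: previous centers + farthest point
        d = cdist(X, prev_centers).min(axis=1)
        warm = np.vstack([prev_centers, X[int(np.argmax(d))]])
        inits = [warm] + ["random"] * n_starts
        for init in inits:
            km = KMeans(n_clusters=K, init=init,
                        n_init=1, algorithm="lloyd", max_iter=300,
                        random_state=int(rng.integers(2 ** 31)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                km.fit(X)
            if best is None or km.inertia_ < best.inertia_:
                best = km
        wss[K - 1] = best.inertia_
        prev_centers = best.cluster_centers_
    bic = n * np.log(wss / n) + k_values * np.log(n)
    return BICScan(
        k_values=k_values, wss=wss, bic=bic,
        delta_bic=bic[:-1] - bic[1:],
        k_best=int(k_values[np.argmin(bic)]),
    )


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------

@dataclass
class DAPCModel:
    """Linear discriminant classifier in a retained-PC subspace."""

    basis: PCABasis | None
    n_pcs: int
    group_labels: list[str]
    priors: np.ndarray                  # per-group, sums to 1
    discriminant_axes: np.ndarray       # n_pcs x n_da, within-sphered
    group_means_da: np.ndarray          # groups x n_da
    eigenvalues: np.ndarray             # between/within variance ratios
    pooled_within_cov: np.ndarray = field(repr=False, default=None)

    @property
    def n_da(self) -> int:
        return self.discriminant_axes.shape[1]


@dataclass
class AssignmentResult:
    posterior: np.ndarray     # samples x groups, rows sum to 1
    assigned: np.ndarray      # label per sample
    accuracy_overall: float | None = None
    accuracy_by_group: dict[str, float] | None = None


def dapc_fit(scores: np.ndarray, labels, n_pcs: int | None = None,
             n_da: int | None = None, basis: PCABasis | None = None) -> DAPCModel:
    """Fit discriminant axes on PC scores.

    Axes solve the generalized eigenproblem B a = lambda W a (between vs
    pooled-within covariance in the retained-PC space) and are scaled so the
    pooled within-group covariance in discriminant space is the identity.
    Priors are proportional to training group sizes.
    """
    labels = np.asarray([str(l) for l in labels])
    scores = np.asarray(scores, dtype=float)
    if n_pcs is None:
        n_pcs = scores.shape[1]
    n_pcs = min(n_pcs, scores.shape[1])
    X = scores[:, :n_pcs]
    groups, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    g = len(groups)
    n = len(labels)
    if n_da is None:
        n_da = min(n_pcs, g - 1)
    n_da = min(n_da, n_pcs, g - 1)

    grand = X.mean(axis=0)
    W = np.zeros((n_pcs, n_pcs))
    B = np.zeros((n_pcs, n_pcs))
    means = np.empty((g, n_pcs))
    for k, grp in enumerate(groups):
        Xg = X[labels == grp]
        means[k] = Xg.mean(axis=0)
        D = Xg - means[k]
        W += D.T @ D
        dm = means[k] - grand
        B += len(Xg) * np.outer(dm, dm)
    W /= (n - g)
    B /= max(g - 1, 1)
    try:
        np.linalg.cholesky(W)
    except np.linalg.LinAlgError:
        eps = 1e-8 * np.trace(W) / n_pcs
        warnings.warn("singular pooled within covariance; ridge-regularizing")
        W = W + eps * np.eye(n_pcs)
    evals, evecs = scipy.linalg.eigh(B, W)  # ascending; vecs W-orthonormal
    order = np.argsort(evals)[::-1][:n_da]
    axes = evecs[:, order]
    # report eigenvalues as between/within *scatter* ratios (a'Ba / a'Wa with
    # both as scatter matrices), the scale-free discriminant convention
    evals = np.maximum(evals[order], 0.0) * (g - 1) / (n - g)
    model = DAPCModel(
        basis=basis, n_pcs=n_pcs, group_labels=[str(grp) for grp in groups],
        priors=counts / n, discriminant_axes=axes,
        group_means_da=means @ axes, eigenvalues=evals,
        pooled_within_cov=W,
    )
    return model


def dapc_fit_genotypes(data, labels, n_pcs: int, n_da: int | None = None) -> DAPCModel:
    """Centre + PCA + discriminant fit, keeping the basis for prediction."""
    n = data.n_samples if isinstance(data, GenotypeDataset) else np.asarray(data).shape[0]
    p = data.n_variants if isinstance(data, GenotypeDataset) else np.asarray(data).shape[1]
    n_pcs = min(n_pcs, n - 1, p)
    basis, scores = pca_genotypes(data, n_components=n_pcs)
    return dapc_fit(scores, labels, n_pcs=n_pcs, n_da=n_da, basis=basis)


def dapc_predict(model: DAPCModel, new_data, kind: str = "auto") -> AssignmentResult:
    """Posterior group membership for new samples.

    ``new_data`` may be PC scores (``kind="scores"``, aligned with the
    model's retained PCs) or raw genotypes / a dataset
    (``kind="genotypes"``), which are centred with the MODEL's variant means
    and projected through its basis.  ``kind="auto"`` treats a
    :class:`GenotypeDataset`, or a matrix whose width equals the model's
    variant count, as genotypes.  Posteriors are Gaussian with identity
    within-group covariance in discriminant space.
    """
    if kind == "auto":
        arr = getattr(new_data, "calls", new_data)
        is_geno = isinstance(new_data, GenotypeDataset) or (
            model.basis is not None
            and np.asarray(arr).shape[1] == model.basis.loadings.shape[0])
        kind = "genotypes" if is_geno else "scores"
    if kind == "genotypes":
        calls = new_data.calls if isinstance(new_data, GenotypeDataset) else np.asarray(new_data)
        if model.basis is None:
            raise ValueError("model carries no PCA basis; pass PC scores instead")
        if model.basis.loadings.shape[0] != calls.shape[1]:
            raise ValueError(
                f"variant mismatch: model expects {model.basis.loadings.shape[0]} "
                f"variants, got {calls.shape[1]}")
        scores = model.basis.project_raw(calls, n_pcs=model.n_pcs)
    elif kind == "scores":
        scores = np.asarray(new_data, dtype=float)[:, :model.n_pcs]
    else:
        raise ValueError("kind must be 'auto', 'scores' or 'genotypes'")
    Z = scores @ model.discriminant_axes
    d2 = cdist(Z, model.group_means_da, metric="sqeuclidean")
    loglik = -0.5 * d2 + np.log(model.priors)[None, :]
    loglik -= loglik.max(axis=1, keepdims=True)
    post = np.exp(loglik)
    post /= post.sum(axis=1, keepdims=True)
    assigned = np.asarray(model.group_labels)[post.argmax(axis=1)]
    return AssignmentResult(posterior=post, assigned=assigned)


def reassignment_accuracy(result: AssignmentResult, labels) -> AssignmentResult:
    """Fill overall and per-group agreement between assignments and labels."""
    labels = np.asarray([str(l) for l in labels])
    correct = result.assigned == labels
    result.accuracy_overall = float(correct.mean())
    result.accuracy_by_group = {
        grp: float(correct[labels == grp].mean()) for grp in np.unique(labels)
    }
    return result


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class XvalResult:
    npc_grid: np.ndarray
    success_by_rep: np.ndarray  # len(npc_grid) x reps
    rmse: np.ndarray
    chosen_npcs: int


def _stratified_splits(labels: np.ndarray, train_fraction: float, reps: int,
                       seed: int):
    splitter = StratifiedShuffleSplit(n_splits=reps, train_size=train_fraction,
                                      random_state=seed % (2 ** 31))
    yield from splitter.split(np.zeros(len(labels)), labels)


def xval_select_npcs(data, labels, npc_grid, training_fraction: float = 0.9,
                     reps: int = 30, seed: int = 0) -> XvalResult:
    """Choose the PC count by stratified hold-out cross-validation.

    Per replicate and candidate PC count: fit DAPC on the training split,
    score hold-out assignment success; RMSE(n_pcs) is the root mean square
    of (1 - success) over replicates; ties go to the smaller PC count.
    """
    labels = np.asarray([str(l) for l in labels])
    npc_grid = np.asarray(sorted(npc_grid))
    calls = data.calls if isinstance(data, GenotypeDataset) else np.asarray(data)
    success = np.zeros((len(npc_grid), reps))
    for r, (tr, te) in enumerate(_stratified_splits(labels, training_fraction,
                                                    reps, seed)):
        for i, npc in enumerate(npc_grid):
            model = dapc_fit_genotypes(calls[tr], labels[tr], n_pcs=int(npc))
            pred = dapc_predict(model, calls[te], kind="genotypes")
            success[i, r] = float((pred.assigned == labels[te]).mean())
    rmse = np.sqrt(((1.0 - success) ** 2).mean(axis=1))
    chosen = int(npc_grid[np.argmin(rmse)])  # argmin takes first = smallest
    return XvalResult(npc_grid=npc_grid, success_by_rep=success, rmse=rmse,
                      chosen_npcs=chosen)


@dataclass
class PairwiseValidationResult:
    pair: tuple[str, str]
    per_rep_accuracy: np.ndarray
    mean: float
    sd: float


def pairwise_external_validation(data, labels, pair, n_pcs: int,
                                 training_fraction: float = 0.8,
                                 reps: int = 10, seed: int = 0
                                 ) -> PairwiseValidationResult:
    """Hold-out separability of one subgroup pair.

    Per repetition: stratified 80:20 split of the two subgroups, DAPC fit on
    the training split (one discriminant axis), assignment accuracy on the
    hold-out; mean and sd over repetitions.
    """
    labels = np.asarray([str(l) for l in labels])
    pair = (str(pair[0]), str(pair[1]))
    calls = data.calls if isinstance(data, GenotypeDataset) else np.asarray(data)
    sel = np.flatnonzero(np.isin(labels, pair))
    if min((labels[sel] == pair[0]).sum(), (labels[sel] == pair[1]).sum()) < 5:
        raise ValueError("each subgroup of the pair needs at least 5 members")
    calls, labels = calls[sel], labels[sel]
    max_pcs = int(np.floor(len(labels) * training_fraction)) - 1
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} exceeds training rank; capping at {max_pcs}")
        n_pcs = max_pcs
    acc = np.zeros(reps)
    for r, (tr, te) in enumerate(_stratified_splits(labels, training_fraction,
                                                    reps, seed)):
        model = dapc_fit_genotypes(calls[tr], labels[tr], n_pcs=n_pcs, n_da=1)
        pred = dapc_predict(model, calls[te], kind="genotypes")
        acc[r] = float((pred.assigned == labels[te]).mean())
    return PairwiseValidationResult(pair=pair, per_rep_accuracy=acc,
                                    mean=float(acc.mean()),
                                    sd=float(acc.std(ddof=1)) if reps > 1 else 0.0)


def pairwise_validation_matrix(data, labels, n_pcs: int,
                               training_fraction: float = 0.8, reps: int = 10,
                               seed: int = 0) -> pd.DataFrame:
    """Run :func:`pairwise_external_validation` for every subgroup pair."""
    labels_arr = np.asarray([str(l) for l in labels])
    groups = sorted(np.unique(labels_arr))
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            res = pairwise_external_validation(
                data, labels_arr, (a, b), n_pcs=n_pcs,
                training_fraction=training_fraction, reps=reps,
                seed=seed + 7919 * (i * len(groups) + groups.index(b)))
            rows.append({"group_a": a, "group_b": b, "mean": res.mean,
                         "sd": res.sd,
                         **{f"rep{r + 1}": v
                            for r, v in enumerate(res.per_rep_accuracy)}})
    return pd.DataFrame(rows)
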