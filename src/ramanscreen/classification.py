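"""PCA + logistic regression under leave-one-lesion-out cross-validation.

The classifier design follows the one-in-ten rule for a 60-lesion cohort:
candidate models are logistic regressions on every subset of at most 6 of
the first 15 principal components (9,948 subsets). Each candidate is scored
by its lesion-level AUROC under leave-one-lesion-out cross-validation
(LOLO-CV): every fold refits PCA on the training lesions only and projects
the held-out lesion's spectra with the training rotation, so no information
from the held-out lesion leaks into the features.

Training is per spectrum (each measurement carries its lesion's label and
equal weight); evaluation is per lesion, with the lesion posterior defined
as the maximum over its measurements' melanoma probabilities. Thresholding
that maximum is equivalent to the clinical OR rule — call the lesion
suspicious if any single measurement is suspicious.

Because PCA is unsupervised, per-fold projections depend only on the fold
split, not on labels or the PC subset; they are computed once
(:func:`lolo_fold_scores`) and reused across all candidate subsets and all
label permutations. The logistic fits themselves are solved by a damped
Newton iteration on the ridge-penalized Bernoulli log-likelihood, batched
across all folds at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata

from .dataset_io import Label, SpectraDataset
from .errors import ConfigError, FitError, ShapeError

__all__ = [
    "PCAModel",
    "PCSelection",
    "LogisticModel",
    "CVPredictions",
    "ModelSearchResult",
    "FoldScores",
    "fit_pca",
    "project",
    "enumerate_pc_subsets",
    "fit_logistic",
    "lolo_fold_scores",
    "lolo_cv_predict",
    "search_best_subset",
    "lesion_auroc",
]

MAX_PC_INDEX = 15
MAX_SUBSET_SIZE = 6
DEFAULT_REG = 1e-4

_NEWTON_TOL = 1e-11
_NEWTON_MAX_ITER = 200


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Mean-centered PCA by SVD.

    ``components`` rows are orthonormal loadings ordered by decreasing
    explained variance, with the sign convention that each component's
    largest-magnitude loading is positive. ``rank_deficient`` is set when
    the data could not support the requested number of components.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance_fraction: np.ndarray
    n_requested: int
    rank_deficient: bool = False

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(X: np.ndarray, n_components: int) -> PCAModel:
    """Fit PCA on the rows of X (spectra × wavenumbers)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ShapeError(f"need a 2-D matrix with ≥ 2 rows, got shape {X.shape}")
    if n_components < 1 or n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ConfigError(
            f"n_components={n_components} not in [1, min(rows-1, cols)] "
            f"for shape {X.shape}"
        )
    mean = X.mean(axis=0)
    _, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    total_var = float(np.sum(s**2))
    # rank cut: keep directions carrying actual variance
    rank = int(np.sum(s > s[0] * max(X.shape) * np.finfo(float).eps)) if s.size else 0
    k = min(n_components, rank)
    components = vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    for row in components:
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            row *= -1.0
    frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PCAModel(
        mean=mean,
        components=components,
        explained_variance_fraction=frac,
        n_requested=n_components,
        rank_deficient=k < n_components,
    )


def project(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of X onto the fitted components (no refitting)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.mean.size:
        raise ShapeError(
            f"spectrum length {X.shape[1]} does not match model ({model.mean.size})"
        )
    return (X - model.mean) @ model.components.T


# ---------------------------------------------------------------------------
# PC subsets
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class PCSelection:
    """A candidate feature set: 1-based indices into the first 15 PCs, ≤ 6."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        idx = self.indices
        if not 1 <= len(idx) <= MAX_SUBSET_SIZE:
            raise ConfigError(f"subset size must be 1..{MAX_SUBSET_SIZE}, got {len(idx)}")
        if any(not 1 <= i <= MAX_PC_INDEX for i in idx):
            raise ConfigError(f"PC indices must be 1..{MAX_PC_INDEX}, got {idx}")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ConfigError(f"PC indices must be strictly increasing, got {idx}")

    def __len__(self) -> int:
        return len(self.indices)

    def __str__(self) -> str:
        return "PC{" + ",".join(map(str, self.indices)) + "}"


def enumerate_pc_subsets(n_pcs: int = 15, max_size: int = 6) -> list[PCSelection]:
    """All non-empty subsets of {1..n_pcs} of size ≤ max_size, ordered by
    (size, lexicographic)."""
    if not 1 <= max_size <= n_pcs:
        raise ConfigError(f"need 1 ≤ max_size ≤ n_pcs, got {max_size}, {n_pcs}")
    if n_pcs > MAX_PC_INDEX:
        raise ConfigError(f"n_pcs must be ≤ {MAX_PC_INDEX}, got {n_pcs}")
    return [
        PCSelection(combo)
        for size in range(1, max_size + 1)
        for combo in combinations(range(1, n_pcs + 1), size)
    ]


# ---------------------------------------------------------------------------
# Ridge-penalized logistic regression (damped Newton, batched over folds)
# ---------------------------------------------------------------------------


@dataclass
class LogisticModel:
    intercept: float
    coefficients: np.ndarray
    regularization: float

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.coefficients.size:
            raise ShapeError(
                f"{Z.shape[1]} features but model has {self.coefficients.size}"
            )
        return expit(self.intercept + Z @ self.coefficients)


def _batched_newton(
    Z: np.ndarray, y: np.ndarray, mask: np.ndarray, reg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize Σ mask·[log(1+e^η) − y·η] + reg·‖β₁..‖² per fold.

    Z: (F, N, P) design with intercept column first (unpenalized);
    mask: (F, N) in {0,1} selecting each fold's training rows.
    Returns (beta (F, P), converged (F,) bool). Newton direction with
    per-fold step halving; the ridge makes the objective strictly convex.
    """
    F, N, P = Z.shape
    beta = np.zeros((F, P))
    pen = np.zeros(P)
    pen[1:] = 2.0 * reg
    eye = np.eye(P) * 1e-12  # numerical floor for near-degenerate Hessians

    def nll(b: np.ndarray) -> np.ndarray:
        eta = np.einsum("fnp,fp->fn", Z, b)
        return np.einsum("fn,fn->f", mask, np.logaddexp(0.0, eta) - y * eta) + reg * np.sum(
            b[:, 1:] ** 2, axis=1
        )

    current = nll(beta)
    converged = np.zeros(F, dtype=bool)
    for _ in range(_NEWTON_MAX_ITER):
        eta = np.einsum("fnp,fp->fn", Z, beta)
        mu = expit(eta)
        grad = np.einsum("fn,fnp->fp", mask * (mu - y), Z) + pen * beta
        converged = np.max(np.abs(grad), axis=1) < _NEWTON_TOL
        if converged.all():
            break
        w = mask * mu * (1.0 - mu)
        H = np.einsum("fn,fnp,fnq->fpq", w, Z, Z) + np.diag(pen) + eye
        delta = np.linalg.solve(H, grad[..., None])[..., 0]
        # backtracking per fold; increases below float resolution of the
        # NLL are accepted, otherwise quadratic convergence stalls
        slack = 1e-12 * np.maximum(1.0, np.abs(current))
        step = np.ones(F)
        for _ in range(40):
            trial = beta - step[:, None] * delta
            trial_nll = nll(trial)
            worse = trial_nll > current + slack
            if not worse.any():
                break
            step[worse] *= 0.5
        beta = beta - step[:, None] * delta
        current = nll(beta)
    return beta, converged


def fit_logistic(Z: np.ndarray, y: np.ndarray, reg: float = DEFAULT_REG) -> LogisticModel:
    """Fit one ridge-penalized logistic regression (intercept unpenalized).

    Maximizes the Bernoulli log-likelihood minus ``reg·‖coefficients‖²``;
    converged when the gradient's max component drops below 1e-8.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if Z.shape[0] != y.size:
        raise ShapeError(f"{Z.shape[0]} rows of Z but {y.size} labels")
    if len(np.unique(y)) < 2:
        raise FitError("labels contain a single class; cannot fit a classifier")
    if reg < 0:
        raise ConfigError("regularization strength must be ≥ 0")
    design = np.concatenate([np.ones((1, y.size, 1)), Z[None, :, :]], axis=2)
    beta, converged = _batched_newton(design, y[None, :], np.ones((1, y.size)), reg)
    if not converged[0]:
        raise FitError(
            f"logistic fit did not converge within {_NEWTON_MAX_ITER} Newton iterations"
        )
    return LogisticModel(
        intercept=float(beta[0, 0]), coefficients=beta[0, 1:].copy(), regularization=reg
    )


# ---------------------------------------------------------------------------
# Leave-one-lesion-out machinery
# ---------------------------------------------------------------------------


@dataclass
class FoldScores:
    """Cached per-fold PCA projections.

    ``scores[f, i, k]`` is spectrum *i*'s score on component *k+1* in fold
    *f*'s training-data PCA basis; ``test_mask[f, i]`` marks the rows held
    out in fold *f* (the spectra of lesion ``lesion_ids[f]``). Because PCA
    ignores labels, these projections are reusable across every PC subset
    and every label permutation.
    """

    lesion_ids: list[str]
    measurement_ids: list[str]
    lesion_of_row: np.ndarray  # (N,) index into lesion_ids
    scores: np.ndarray  # (F, N, K)
    test_mask: np.ndarray  # (F, N) bool
    n_components_per_fold: np.ndarray  # (F,)
    truncated_folds: list[str] = field(default_factory=list)

    @property
    def n_pcs(self) -> int:
        return self.scores.shape[2]


@dataclass
class CVPredictions:
    """LOLO-CV outputs: per-spectrum probabilities and per-lesion posteriors
    (the max over the lesion's measurements — the OR rule)."""

    spectrum_probabilities: dict[str, float]
    lesion_posteriors: dict[str, float]
    n_folds: int


@dataclass
class ModelSearchResult:
    aurocs: dict[PCSelection, float]
    best_subset: PCSelection
    ties: list[PCSelection]

    @property
    def best_auroc(self) -> float:
        return self.aurocs[self.best_subset]


def _labels_vector(ds: SpectraDataset, fold: FoldScores) -> np.ndarray:
    labels = ds.labels()
    lesion_y = np.array(
        [1.0 if labels[lid] is Label.MELANOMA else 0.0 for lid in fold.lesion_ids]
    )
    if lesion_y.min() == lesion_y.max():
        raise FitError("dataset contains a single class; cannot cross-validate")
    return lesion_y


def lolo_fold_scores(ds: SpectraDataset, n_pcs: int = MAX_PC_INDEX) -> FoldScores:
    """Fit one PCA per leave-one-lesion-out fold and cache projections.

    For each lesion L, PCA is fit on the spectra of all other lesions and
    every spectrum (training and held out) is projected into that basis.
    Folds whose training set cannot support ``n_pcs`` components are
    truncated and flagged.
    """
    if len(ds.lesions) < 3:
        raise ConfigError("need at least 3 lesions for leave-one-lesion-out CV")
    X, measurement_ids = ds.intensity_matrix()
    lesion_ids = ds.lesion_ids
    lesion_index = {lid: i for i, lid in enumerate(lesion_ids)}
    lesion_of_row = np.array([lesion_index[s.lesion_id] for s in ds.spectra])

    F, N = len(lesion_ids), X.shape[0]
    scores = np.zeros((F, N, n_pcs))
    test_mask = np.zeros((F, N), dtype=bool)
    n_comp = np.zeros(F, dtype=int)
    truncated: list[str] = []
    for f in range(F):
        held = lesion_of_row == f
        test_mask[f] = held
        train = X[~held]
        k = min(n_pcs, train.shape[0] - 1, train.shape[1])
        model = fit_pca(train, k)
        if model.n_components < n_pcs:
            truncated.append(lesion_ids[f])
        n_comp[f] = model.n_components
        scores[f, :, : model.n_components] = project(model, X)
    return FoldScores(
        lesion_ids=lesion_ids,
        measurement_ids=measurement_ids,
        lesion_of_row=lesion_of_row,
        scores=scores,
        test_mask=test_mask,
        n_components_per_fold=n_comp,
        truncated_folds=truncated,
    )


def _cv_posteriors(
    fold: FoldScores, lesion_y: np.ndarray, subset: PCSelection, reg: float
) -> tuple[np.ndarray, np.ndarray]:
    """Spectrum probabilities (N,) and lesion posteriors (F,) for one subset."""
    idx = np.array(subset.indices) - 1
    too_few = idx.max() + 1 > fold.n_components_per_fold
    if too_few.any():
        bad = [fold.lesion_ids[f] for f in np.where(too_few)[0]]
        raise FitError(
            f"subset {subset} needs PC {idx.max() + 1} but folds {bad} have fewer components"
        )
    F, N = fold.test_mask.shape
    y_row = lesion_y[fold.lesion_of_row]
    train_mask = (~fold.test_mask).astype(float)
    # folds where training retains a single class cannot be fit
    pos = train_mask @ y_row
    tot = train_mask.sum(axis=1)
    degenerate = (pos == 0) | (pos == tot)
    if degenerate.any():
        bad = [fold.lesion_ids[f] for f in np.where(degenerate)[0]]
        raise FitError(f"single-class training fold(s) after holding out {bad}")

    Zsub = fold.scores[:, :, idx]
    design = np.concatenate([np.ones((F, N, 1)), Zsub], axis=2)
    beta, converged = _batched_newton(design, y_row[None, :], train_mask, reg)
    if not converged.all():
        bad = [fold.lesion_ids[f] for f in np.where(~converged)[0]]
        raise FitError(
            f"logistic fit did not converge within {_NEWTON_MAX_ITER} Newton "
            f"iterations in fold(s) {bad}"
        )
    eta = np.einsum("fnp,fp->fn", design, beta)
    probs_by_fold = expit(eta)
    # each spectrum is held out in exactly one fold
    spectrum_probs = probs_by_fold[fold.lesion_of_row, np.arange(N)]
    posteriors = np.zeros(F)
    for f in range(F):
        posteriors[f] = spectrum_probs[fold.lesion_of_row == f].max()
    return spectrum_probs, posteriors


def lesion_auroc(posteriors: np.ndarray, lesion_y: np.ndarray) -> float:
    """Tie-corrected rank AUROC (Mann–Whitney) of lesion posteriors."""
    ranks = rankdata(posteriors)
    n_pos = int(lesion_y.sum())
    n_neg = lesion_y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise FitError("AUROC undefined with a single class")
    u = ranks[lesion_y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def lolo_cv_predict(
    fold: FoldScores, ds: SpectraDataset, subset: PCSelection, reg: float = DEFAULT_REG
) -> CVPredictions:
    """Cross-validated melanoma probabilities for one PC subset."""
    lesion_y = _labels_vector(ds, fold)
    spectrum_probs, posteriors = _cv_posteriors(fold, lesion_y, subset, reg)
    return CVPredictions(
        spectrum_probabilities=dict(
            zip(fold.measurement_ids, spectrum_probs.tolist())
        ),
        lesion_posteriors=dict(zip(fold.lesion_ids, posteriors.tolist())),
        n_folds=len(fold.lesion_ids),
    )


def search_best_subset(
    fold: FoldScores,
    ds: SpectraDataset,
    subsets: list[PCSelection],
    reg: float = DEFAULT_REG,
) -> ModelSearchResult:
    """Evaluate every candidate subset's lesion-level AUROC; return them all
    plus the maximizer.

    Tie-breaking (AUROCs equal within 1e-12): smallest subset first, then
    lexicographically smallest indices.
    """
    if not subsets:
        raise ConfigError("subset list is empty")
    lesion_y = _labels_vector(ds, fold)
    aurocs: dict[PCSelection, float] = {}
    for subset in subsets:
        try:
            _, posteriors = _cv_posteriors(fold, lesion_y, subset, reg)
        except FitError as exc:
            raise FitError(f"subset {subset}: {exc}") from exc
        aurocs[subset] = lesion_auroc(posteriors, lesion_y)
    best_value = max(aurocs.values())
    ties = sorted(
        (s for s, a in aurocs.items() if best_value - a <= 1e-12),
        key=lambda s: (len(s), s.indices),
    )
    return ModelSearchResult(aurocs=aurocs, best_subset=ties[0], ties=ties)
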