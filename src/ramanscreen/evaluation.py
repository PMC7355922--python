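"""Lesion-level diagnostic accuracy and screening metrics.

The clinical question is not per-spectrum accuracy but per-lesion biopsy
recommendation: ROC curves are built over lesion posteriors, the operating
point of interest is the most specific threshold that still catches every
melanoma (perfect sensitivity — a screening tool must not miss cancers),
and the payoff is summarized as the number needed to treat (NNT, biopsied
lesions per histologically confirmed melanoma) before and after following
the spectroscopic recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import Label
from .errors import DomainError, EvaluationError

__all__ = [
    "ROCResult",
    "ROCBand",
    "ConfusionCounts",
    "ScreeningMetrics",
    "roc_curve",
    "bootstrap_roc_band",
    "full_sensitivity_operating_point",
    "screening_metrics",
    "unnecessary_fraction",
]


def _split_scores(
    posteriors: dict[str, float], labels: dict[str, Label]
) -> tuple[np.ndarray, np.ndarray]:
    ids = list(posteriors)
    scores = np.array([posteriors[i] for i in ids], dtype=float)
    y = np.array([1 if labels[i] is Label.MELANOMA else 0 for i in ids])
    if y.size == 0 or y.min() == y.max():
        raise EvaluationError("both classes must be present to evaluate")
    return scores, y


@dataclass
class ROCResult:
    """An ROC curve over lesion posteriors.

    ``thresholds`` are the unique posterior values in descending order,
    preceded by a +inf sentinel (the all-negative operating point); a lesion
    is called melanoma when its posterior is ≥ the threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float


def roc_curve(posteriors: dict[str, float], labels: dict[str, Label]) -> ROCResult:
    """ROC over lesions; AUROC by the trapezoid rule (equals the
    tie-corrected Mann–Whitney statistic)."""
    scores, y = _split_scores(posteriors, labels)
    uniq = np.unique(scores)[::-1]
    thresholds = np.concatenate([[np.inf], uniq])
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        sens[i] = (pred & (y == 1)).sum() / n_pos
        spec[i] = (~pred & (y == 0)).sum() / n_neg
    auroc = float(np.trapezoid(sens, 1.0 - spec))
    return ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auroc=auroc)


@dataclass
class ROCBand:
    """Percentile bootstrap band of sensitivity on a fixed specificity grid."""

    specificity_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_boot: int
    n_redrawn: int = 0


def _sensitivity_at(roc: ROCResult, spec_grid: np.ndarray) -> np.ndarray:
    # best achievable sensitivity at specificity ≥ g (the ROC upper envelope)
    out = np.zeros_like(spec_grid)
    for j, g in enumerate(spec_grid):
        ok = roc.specificity >= g - 1e-12
        out[j] = roc.sensitivity[ok].max() if ok.any() else 0.0
    return out


def bootstrap_roc_band(
    posteriors: dict[str, float],
    labels: dict[str, Label],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    spec_grid: np.ndarray | None = None,
) -> ROCBand:
    """Stratified lesion bootstrap of the ROC curve.

    Lesions are resampled with replacement within each class (preserving
    class counts), the replicate's ROC envelope is evaluated on a fixed
    specificity grid, and the pointwise percentile band is returned.
    Deterministic given ``seed``.
    """
    scores, y = _split_scores(posteriors, labels)
    ids = list(posteriors)
    if spec_grid is None:
        spec_grid = np.linspace(0.0, 1.0, 101)
    rng = np.random.default_rng(seed)
    pos_idx = np.where(y == 1)[0]
    neg_idx = np.where(y == 0)[0]
    bands = np.empty((n_boot, spec_grid.size))
    n_redrawn = 0
    attempts_left = 10 * n_boot
    b = 0
    while b < n_boot:
        if attempts_left <= 0:
            raise EvaluationError("bootstrap exceeded the redraw cap")
        attempts_left -= 1
        take = np.concatenate(
            [
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ]
        )
        yb = y[take]
        if yb.min() == yb.max():  # unreachable under stratified sampling; kept as a guard
            n_redrawn += 1
            continue
        post_b = {f"b{i}": float(scores[t]) for i, t in enumerate(take)}
        lab_b = {
            f"b{i}": Label.MELANOMA if yb[i] else Label.PIGMENTED
            for i in range(take.size)
        }
        bands[b] = _sensitivity_at(roc_curve(post_b, lab_b), spec_grid)
        b += 1
    alpha = (1.0 - level) / 2.0
    if n_boot == 1:
        lower = upper = bands[0]
    else:
        lower = np.quantile(bands, alpha, axis=0)
        upper = np.quantile(bands, 1.0 - alpha, axis=0)
    return ROCBand(
        specificity_grid=spec_grid,
        lower=lower,
        upper=upper,
        level=level,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )


@dataclass
class ConfusionCounts:
    """Lesion-level confusion counts (melanoma = positive class)."""

    true_positives: int
    false_negatives: int
    true_negatives: int
    false_positives: int

    @property
    def n_melanoma(self) -> int:
        return self.true_positives + self.false_negatives

    @property
    def n_pigmented(self) -> int:
        return self.true_negatives + self.false_positives

    @property
    def total(self) -> int:
        return self.n_melanoma + self.n_pigmented


def full_sensitivity_operating_point(
    posteriors: dict[str, float], labels: dict[str, Label]
) -> tuple[float, ConfusionCounts]:
    """The most specific threshold that still recommends every melanoma.

    The threshold is the minimum melanoma posterior; a lesion is recommended
    for biopsy when its posterior is ≥ that threshold (ties are biopsied —
    the conservative choice for a cancer screen), so sensitivity is 1 and
    the resulting specificity is the best achievable at perfect sensitivity.
    """
    scores, y = _split_scores(posteriors, labels)
    threshold = float(scores[y == 1].min())
    pred = scores >= threshold
    counts = ConfusionCounts(
        true_positives=int((pred & (y == 1)).sum()),
        false_negatives=int((~pred & (y == 1)).sum()),
        true_negatives=int((~pred & (y == 0)).sum()),
        false_positives=int((pred & (y == 0)).sum()),
    )
    return threshold, counts


@dataclass
class ScreeningMetrics:
    """Screening payoff of an operating point, stored at full precision.

    ``nnt_before`` is total biopsied lesions per melanoma under current
    practice (biopsy everything); ``nnt_after`` counts only the lesions the
    classifier recommends. ``biopsies_avoided_pct`` is the share of benign
    lesions spared (identical to specificity as a percentage).
    """

    sensitivity_pct: float
    specificity_pct: float
    nnt_before: float
    nnt_after: float
    biopsies_avoided_pct: float
    nnt_after_defined: bool = True

    def display(self) -> dict[str, float]:
        """Values rounded to one decimal for reporting."""
        return {
            "sensitivity_pct": round(self.sensitivity_pct, 1),
            "specificity_pct": round(self.specificity_pct, 1),
            "nnt_before": round(self.nnt_before, 1),
            "nnt_after": round(self.nnt_after, 1) if self.nnt_after_defined else float("nan"),
            "biopsies_avoided_pct": round(self.biopsies_avoided_pct, 1),
        }


def screening_metrics(counts: ConfusionCounts) -> ScreeningMetrics:
    """NNT before/after and sensitivity/specificity from lesion counts."""
    if counts.n_melanoma == 0 or counts.n_pigmented == 0:
        raise EvaluationError("both classes must be present in the counts")
    tp = counts.true_positives
    nnt_after_defined = tp > 0
    return ScreeningMetrics(
        sensitivity_pct=100.0 * tp / counts.n_melanoma,
        specificity_pct=100.0 * counts.true_negatives / counts.n_pigmented,
        nnt_before=counts.total / counts.n_melanoma,
        nnt_after=(tp + counts.false_positives) / tp if nnt_after_defined else float("nan"),
        biopsies_avoided_pct=100.0 * counts.true_negatives / counts.n_pigmented,
        nnt_after_defined=nnt_after_defined,
    )


def unnecessary_fraction(nnt: float) -> float:
    """Percentage of biopsies that are unnecessary at a given NNT.

    One biopsy in ``nnt`` finds a melanoma, so 100·(1 − 1/NNT) percent of
    biopsies are performed on benign lesions. Full precision is returned;
    round to one decimal for display.
    """
    if nnt < 1:
        raise DomainError(f"NNT must be ≥ 1, got {nnt}")
    return 100.0 * (1.0 - 1.0 / nnt)
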