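"""Label-randomization null for the best-over-subsets AUROC.

Exhaustive subset selection is optimistically biased: even with no real
class difference, the maximum AUROC over thousands of candidate models can
look impressive at n = 60. The null distribution of that *maximum* is
estimated empirically: repeatedly assign the melanoma label to a random
subset of lesions (7 of 60 by default), rerun the entire subset search on
the permuted labels, and record the best AUROC each time. The fraction of
replicates exceeding a cutoff is the chance that selection optimism alone
produces a result that strong.

PCA is unsupervised, so the cached per-fold projections are reused across
permutations — only the logistic stage sees labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classification import (
    DEFAULT_REG,
    FoldScores,
    PCSelection,
    _cv_posteriors,
    lesion_auroc,
    lolo_fold_scores,
)
from .dataset_io import Label, LesionRecord, SpectraDataset
from .errors import ConfigError, FitError

__all__ = [
    "RandomizationSummary",
    "permute_class_labels",
    "randomization_test",
    "exceedance",
]


@dataclass
class RandomizationSummary:
    """Null distribution of the best-over-subsets AUROC."""

    replicate_aurocs: np.ndarray
    best_subsets: list[PCSelection]
    n_replicates: int
    n_positive: int
    seed: int
    n_redrawn: int = 0
    failures: list[str] = field(default_factory=list)


def permute_class_labels(
    ds: SpectraDataset, n_positive: int, rng: np.random.Generator
) -> SpectraDataset:
    """A copy of the dataset with ``n_positive`` uniformly random lesions
    labeled melanoma and the rest pigmented; spectra are untouched."""
    n = len(ds.lesions)
    if not 0 < n_positive < n:
        raise ConfigError(f"n_positive must be in (0, {n}), got {n_positive}")
    chosen = _draw_positive_ids([l.lesion_id for l in ds.lesions], n_positive, rng)
    lesions = [
        LesionRecord(
            lesion_id=l.lesion_id,
            patient_id=l.patient_id,
            label=Label.MELANOMA if l.lesion_id in chosen else Label.PIGMENTED,
            measurement_ids=l.measurement_ids,
        )
        for l in ds.lesions
    ]
    return SpectraDataset(spectra=list(ds.spectra), lesions=lesions)


def _draw_positive_ids(
    lesion_ids: list[str], n_positive: int, rng: np.random.Generator
) -> set[str]:
    # draw against the sorted id list so the assignment depends on the
    # lesion identities, not on the storage order of the input dataset
    ordered = sorted(lesion_ids)
    idx = rng.choice(len(ordered), size=n_positive, replace=False)
    return {ordered[i] for i in idx}


def _best_auroc(
    fold: FoldScores, lesion_y: np.ndarray, subsets: list[PCSelection], reg: float
) -> tuple[float, PCSelection]:
    best_val = -1.0
    best_sub = subsets[0]
    for subset in subsets:
        _, posteriors = _cv_posteriors(fold, lesion_y, subset, reg)
        a = lesion_auroc(posteriors, lesion_y)
        if a > best_val + 1e-12:
            best_val, best_sub = a, subset
    return best_val, best_sub


def randomization_test(
    ds: SpectraDataset,
    subsets: list[PCSelection],
    n_replicates: int = 99,
    n_positive: int = 7,
    reg: float = DEFAULT_REG,
    seed: int = 0,
    fold_scores: FoldScores | None = None,
) -> RandomizationSummary:
    """Best-over-subsets AUROC under random label assignment.

    Each replicate relabels ``n_positive`` random lesions melanoma and runs
    the full subset search (the "fair comparison": the null model gets the
    same selection advantage as the real one). Replicates whose permutation
    produces a degenerate fold are redrawn, capped at 3× ``n_replicates``
    attempts. Deterministic given ``seed``.
    """
    if not subsets:
        raise ConfigError("subset list is empty")
    if n_replicates < 1:
        raise ConfigError("n_replicates must be ≥ 1")
    if fold_scores is None:
        n_pcs = max(max(s.indices) for s in subsets)
        fold_scores = lolo_fold_scores(ds, n_pcs=n_pcs)
    n_lesions = len(fold_scores.lesion_ids)
    if not 0 < n_positive < n_lesions:
        raise ConfigError(f"n_positive must be in (0, {n_lesions}), got {n_positive}")

    aurocs = np.empty(n_replicates)
    best_subsets: list[PCSelection] = []
    failures: list[str] = []
    n_redrawn = 0
    attempts = 0
    rep = 0
    attempt_cap = 3 * n_replicates
    while rep < n_replicates:
        if attempts >= attempt_cap:
            raise FitError(
                f"randomization exceeded {attempt_cap} attempts "
                f"({len(failures)} degenerate replicates)"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(attempts,))
        )
        attempts += 1
        chosen = _draw_positive_ids(fold_scores.lesion_ids, n_positive, rng)
        lesion_y = np.array(
            [1.0 if lid in chosen else 0.0 for lid in fold_scores.lesion_ids]
        )
        try:
            best_val, best_sub = _best_auroc(fold_scores, lesion_y, subsets, reg)
        except FitError as exc:
            failures.append(str(exc))
            n_redrawn += 1
            continue
        aurocs[rep] = best_val
        best_subsets.append(best_sub)
        rep += 1
    return RandomizationSummary(
        replicate_aurocs=aurocs,
        best_subsets=best_subsets,
        n_replicates=n_replicates,
        n_positive=n_positive,
        seed=seed,
        n_redrawn=n_redrawn,
        failures=failures,
    )


def exceedance(summary: RandomizationSummary, cutoff: float) -> float:
    """Fraction of replicate AUROCs strictly greater than ``cutoff``."""
    return float(np.mean(summary.replicate_aurocs > cutoff))
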