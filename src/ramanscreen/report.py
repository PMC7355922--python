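"""Figures and the human-readable run report.

Everything here is regenerated purely from artifacts already on disk in a
run directory (plus in-memory results when called from the pipeline), so a
report is a function of the run directory alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ReportError
from .pipeline import sha256_file

__all__ = ["make_figures", "make_report"]


def make_figures(run_dir, roc, band, pca_model, rand_summary) -> list[Path]:
    """ROC curve with bootstrap band, scree plot, null-AUROC histogram."""
    run_dir = Path(run_dir)
    paths = []

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(1 - roc.specificity, roc.sensitivity, "b-", drawstyle="steps-post",
            label=f"AUROC = {roc.auroc:.3f}")
    ax.fill_between(1 - band.specificity_grid, band.lower, band.upper,
                    alpha=0.25, color="tab:blue",
                    label=f"{band.level:.0%} bootstrap band")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 − specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title("Melanoma vs pigmented lesions (per-lesion ROC)")
    ax.legend(loc="lower right")
    paths.append(run_dir / "roc.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    frac = pca_model.explained_variance_fraction
    ax.bar(np.arange(1, frac.size + 1), 100 * frac, color="tab:gray")
    ax.set_xlabel("Principal component")
    ax.set_ylabel("Explained variance (%)")
    ax.set_title(f"Scree (first {frac.size} PCs: {100 * frac.sum():.1f}% of variance)")
    paths.append(run_dir / "scree.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    if rand_summary is not None:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.hist(rand_summary.replicate_aurocs, bins=np.linspace(0.3, 1.0, 15),
                color="tab:orange", edgecolor="k")
        ax.set_xlabel("Best-over-subsets AUROC (random labels)")
        ax.set_ylabel("Replicates")
        ax.set_title(f"Null distribution ({rand_summary.n_replicates} randomizations)")
        paths.append(run_dir / "randomization_hist.png")
        fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
        plt.close(fig)
    return paths


def _accuracy_table(posteriors: pd.DataFrame, threshold: float) -> list[dict]:
    """Prediction-accuracy table at the reported operating point: one row
    per class plus a total row (correct / false predictions, biopsies)."""
    rows = []
    pred_biopsy = posteriors["posterior"] >= threshold
    for cls, positive in (("Pigmented lesions", False), ("Melanoma", True)):
        sel = posteriors["label"] == ("melanoma" if positive else "pigmented")
        n = int(sel.sum())
        correct = int((pred_biopsy[sel] == positive).sum())
        rows.append(
            {
                "Lesion type": cls,
                "Lesions": n,
                "Correct predictions": f"{correct} ({100 * correct / n:.1f}%)" if n else "0",
                "False predictions": n - correct,
                "Potential biopsies": int(pred_biopsy[sel].sum()),
            }
        )
    rows.append(
        {
            "Lesion type": "Total",
            "Lesions": sum(r["Lesions"] for r in rows),
            "Correct predictions": str(
                sum(int(str(r["Correct predictions"]).split(" ")[0]) for r in rows)
            ),
            "False predictions": sum(r["False predictions"] for r in rows),
            "Potential biopsies": sum(r["Potential biopsies"] for r in rows),
        }
    )
    return rows


def make_report(run_dir) -> str:
    """Render ``report.md`` in a completed run directory and return it."""
    run_dir = Path(run_dir)
    required = ["metrics.json", "posteriors.csv"]
    missing = [f for f in required if not (run_dir / f).exists()]
    if missing:
        raise ReportError(f"run directory {run_dir} is missing artifacts: {missing}")
    with open(run_dir / "metrics.json") as fh:
        metrics = json.load(fh)

    warnings = []
    expected = metrics.get("checksums", {}).get("posteriors.csv")
    actual = sha256_file(run_dir / "posteriors.csv")
    if expected and expected != actual:
        warnings.append(
            "WARNING: checksum mismatch for posteriors.csv — the file was "
            "modified after the run"
        )

    # round_trip parsing: the operating threshold equals one posterior
    # exactly, and the default (fast) parser can be off by one ulp
    posteriors = pd.read_csv(run_dir / "posteriors.csv", float_precision="round_trip")
    threshold = metrics["operating_point"]["threshold"]
    table = _accuracy_table(posteriors, threshold)
    screening = metrics["screening"]

    lines = [
        "# Raman biopsy-screening run report",
        "",
        f"Config hash: `{metrics['config_hash']}`, seed {metrics['seed']}.",
        "",
        *(f"> {w}" for w in warnings),
        "",
        f"Cohort: {metrics['n_lesions']} lesions "
        f"({metrics['n_melanoma']} melanoma), "
        f"{metrics['n_measurements']} measurements.",
        "",
        "## Model selection",
        "",
        f"- candidate PC subsets evaluated: {metrics['n_subsets']}",
        f"- best subset: PCs {metrics['best_subset']} "
        f"({metrics['n_tied_subsets']} tied within 1e-12)",
        f"- lesion-level AUROC (leave-one-lesion-out): {metrics['auroc']:.3f}",
        "",
        "## Operating point at perfect sensitivity",
        "",
        "| Lesion type | Lesions | Correct predictions | False predictions | Potential biopsies |",
        "|---|---|---|---|---|",
        *(
            "| {Lesion type} | {Lesions} | {Correct predictions} | "
            "{False predictions} | {Potential biopsies} |".format(**row)
            for row in table
        ),
        "",
        f"- sensitivity {screening['sensitivity_pct']}%, "
        f"specificity {screening['specificity_pct']}%",
        f"- NNT: {screening['nnt_before']} before → {screening['nnt_after']} after "
        "the spectroscopic recommendation",
        f"- biopsies on benign lesions avoided: {screening['biopsies_avoided_pct']}%",
    ]
    if metrics.get("randomization"):
        r = metrics["randomization"]
        lines += [
            "",
            "## Label-randomization null",
            "",
            f"- {r['n_replicates']} replicates, {r['n_positive']} random positives",
            f"- mean best-over-subsets AUROC: {r['mean_best_auroc']:.3f} "
            f"(max {r['max_best_auroc']:.3f})",
            f"- fraction exceeding {r['cutoff']}: {r['exceedance']:.3f}",
        ]
    text = "\n".join(lines) + "\n"
    with open(run_dir / "report.md", "w") as fh:
        fh.write(text)
    return text
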