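"""AUC-based classification evaluation of gene set scores on simulations.

Replicates a simulation design across seeds, scores each replicate with
one or more method variants, and measures how well the scores separate the
planted signal: informative cells for the block / complex /
self-contained designs, the informative set (pooled over cells and sets)
for the competitive design, and the informative set's overall score pooled
over replicates for the overall-score experiment. Includes a first-PC
(PLAGE-style) baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, sparse
from sklearn.metrics import roc_auc_score

from .core import ExpressionMatrix, ResetParams, center_scale, reset_randomized
from .genesets import AnnotationMatrix
from .simulate import SimulatedDataset, SimulationDesign, log_normalize, simulate_counts

__all__ = [
    "EvaluationResult",
    "auc",
    "plage_baseline",
    "score_method",
    "run_sample_level_experiment",
    "run_overall_experiment",
    "METHOD_PARAMS",
]

#: Scoring variants: deterministic (column-pivoted QR forced by a high
#: random_threshold), randomized (low threshold forces the rangefinder),
#: per-variable adjusted deterministic, and the first-PC baseline.
METHOD_PARAMS: dict[str, dict] = {
    "reset_det": {"random_threshold": 90, "per_var": False},
    "reset_ran": {"random_threshold": 9, "per_var": False},
    "reset_pervar": {"random_threshold": 90, "per_var": True},
    "plage": {},
}


@dataclass
class EvaluationResult:
    """Tidy per-replicate AUC table plus a mean +/- SEM summary."""

    table: pd.DataFrame  # columns: design, parameter, value, method, rep, auc

    def summary(self) -> pd.DataFrame:
        g = self.table.groupby(
            ["design", "parameter", "value", "method"], dropna=False
        )["auc"]
        out = g.agg(mean_auc="mean", sd="std", n_reps="count").reset_index()
        out["sem"] = out["sd"] / np.sqrt(out["n_reps"])
        return out.drop(columns="sd")


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form with midrank ties.

    Equals P(score+ > score-) + 0.5 P(tie). Raises if only one class is
    present.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC requires both positive and negative labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def plage_baseline(X: ExpressionMatrix, A: AnnotationMatrix) -> np.ndarray:
    """First-PC projection scores per set (sign arbitrary).

    Each set's sub-matrix is column-standardized and every sample projected
    onto its first principal component. Degenerate (zero-variance)
    sub-matrices yield zero scores.
    """
    n = X.shape[0]
    S = np.zeros((n, A.n_sets))
    for i in range(A.n_sets):
        Xs = X.values[:, A.indices(i)]
        Xs = center_scale(Xs, center=True, scale=True)
        if not Xs.any():
            continue
        U, s, _ = linalg.svd(Xs, full_matrices=False)
        S[:, i] = U[:, 0] * s[0]
    return S


def score_method(
    method: str,
    normalized: ExpressionMatrix,
    A: AnnotationMatrix,
    reset_params: ResetParams,
    seed: int,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Sample-score matrix for one method; RESET variants also return ``v``."""
    if method == "plage":
        return plage_baseline(normalized, A)
    if method not in METHOD_PARAMS:
        raise ValueError(f"unknown method {method!r}")
    params = replace(reset_params, seed=seed, **METHOD_PARAMS[method])
    scores = reset_randomized(normalized, A, params)
    return scores.S, scores.v


def _replicate_seed(seed: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


def _sample_level_auc(
    method_scores: np.ndarray, ds: SimulatedDataset
) -> float:
    """AUC of the enriched set's scores against the planted labels.

    Block-style designs compare the informative set's cell scores to the
    informative-cell labels. The competitive design (all cells
    informative) pools every (cell, set) score, labeling the enriched
    set's scores positive.
    """
    enriched = int(np.flatnonzero(ds.informative_sets)[0])
    if ds.design.design == "competitive":
        labels = np.zeros(method_scores.shape, dtype=bool)
        labels[:, enriched] = True
        return auc(method_scores.ravel(), labels.ravel())
    return auc(method_scores[:, enriched], ds.informative_cells)


def run_sample_level_experiment(
    base_design: SimulationDesign,
    vary: dict[str, list],
    methods: list[str],
    reps: int = 50,
    seed: int = 0,
    reset_params: ResetParams | None = None,
    scale_factor: float = 1e4,
) -> EvaluationResult:
    """Replicate, score and evaluate across a one-parameter-at-a-time grid.

    ``vary`` maps design field names to value lists; each value is swapped
    into ``base_design`` with all other fields at their base values (use
    ``{"": [None]}``-style single entry to evaluate the base design only).
    Every (parameter, value, replicate) triple gets its own derived seed so
    the grid is reproducible and replicates are independent.
    """
    reset_params = reset_params or ResetParams()
    rows = []
    for pi, (param, values) in enumerate(sorted(vary.items())):
        for vi, value in enumerate(values):
            design = (
                base_design if param == "" else replace(base_design, **{param: value})
            )
            for rep in range(reps):
                rep_seed = _replicate_seed(seed, pi, vi, rep)
                ds = simulate_counts(replace(design, seed=rep_seed))
                normalized = log_normalize(ds.counts, scale_factor)
                for method in methods:
                    out = score_method(
                        method, normalized, ds.annotation, reset_params, rep_seed
                    )
                    S = out[0] if isinstance(out, tuple) else out
                    rows.append(
                        {
                            "design": design.design,
                            "parameter": param or "(base)",
                            "value": value if param else np.nan,
                            "method": method,
                            "rep": rep,
                            "auc": _sample_level_auc(S, ds),
                        }
                    )
    return EvaluationResult(table=pd.DataFrame(rows))


def run_overall_experiment(
    design: SimulationDesign,
    variants: list[str] | None = None,
    reps: int = 50,
    seed: int = 0,
    reset_params: ResetParams | None = None,
    scale_factor: float = 1e4,
) -> pd.DataFrame:
    """Overall-score classification: can ``v`` single out the informative set?

    Requires a design with one informative set among several (block-style
    with a multi-set collection). Each replicate contributes one positive
    (the informative set's overall score) and m - 1 negatives; the AUC is
    computed on the scores pooled across replicates per variant, the only
    well-defined estimator when each replicate has a single positive.
    Returns a frame with one pooled AUC row per variant.
    """
    variants = variants or ["reset_det", "reset_ran", "reset_pervar"]
    reset_params = reset_params or ResetParams()
    if design.resolved_n_sets < 2:
        raise ValueError("overall evaluation needs at least two gene sets")
    pooled: dict[str, list] = {m: [] for m in variants}
    labels: list[np.ndarray] = []
    for rep in range(reps):
        rep_seed = _replicate_seed(seed, rep)
        ds = simulate_counts(replace(design, seed=rep_seed))
        normalized = log_normalize(ds.counts, scale_factor)
        labels.append(ds.informative_sets)
        for method in variants:
            _, v = score_method(method, normalized, ds.annotation, reset_params, rep_seed)
            pooled[method].append(v)
    y = np.concatenate(labels)
    rows = [
        {
            "design": design.design,
            "method": method,
            "n_reps": reps,
            "auc": auc(np.concatenate(pooled[method]), y),
        }
        for method in variants
    ]
    return pd.DataFrame(rows)


def plot_auc_panels(result: EvaluationResult, path: str) -> None:
    """One panel per varied parameter: mean AUC vs value, per method.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summ = result.summary()
    params = [p for p in summ["parameter"].unique() if p != "(base)"]
    if not params:
        params = ["(base)"]
    fig, axes = plt.subplots(1, len(params), figsize=(4 * len(params), 3.2), squeeze=False)
    for ax, param in zip(axes[0], params):
        sub = summ[summ["parameter"] == param]
        for method, grp in sub.groupby("method"):
            ax.errorbar(grp["value"], grp["mean_auc"], yerr=grp["sem"], label=method, marker="o")
        ax.set_xlabel(param)
        ax.set_ylabel("AUC")
        ax.set_ylim(0, 1.05)
        ax.axhline(0.5, color="grey", lw=0.5, ls="--")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
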