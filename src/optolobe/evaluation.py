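"""Model ranking, cross-model parameter statistics, and condition reports.

After multi-restart optimization, the best models (reference: the 10 best of
20 runs) are compared: pairwise Pearson correlation of their physical-scale
parameter vectors shows whether independent runs converged on similar
solutions, and per-parameter mean/variance summarizes the consensus.  The
with-gate vs without-gate comparison quantifies how much the
hyperpolarization-activated conductance improves the fit, alongside the cost
of the ablated (gate switched off post hoc) model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FitResult
from .parameters import constrained_vector

__all__ = [
    "ModelEnsemble",
    "rank_models",
    "parameter_correlation",
    "summarize_parameters",
    "compare_conditions",
]


@dataclass(frozen=True)
class ModelEnsemble:
    """The ``k`` best fit results, sorted by final cost ascending."""

    results: tuple[FitResult, ...]
    k_best: int

    def __post_init__(self) -> None:
        costs = [r.final_cost for r in self.results]
        if costs != sorted(costs):
            raise ValueError("ensemble results must be sorted by final cost")
        if self.k_best != len(self.results):
            raise ValueError("k_best must equal the number of retained results")

    @property
    def costs(self) -> np.ndarray:
        return np.array([r.final_cost for r in self.results])

    @property
    def best(self) -> FitResult:
        return self.results[0]


def rank_models(results: list[FitResult], k: int) -> ModelEnsemble:
    """Retain the ``k`` lowest-cost successful restarts, stable order.

    Ties are broken by restart index; failed restarts are excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ok = [r for r in results if not r.failed]
    if k > len(ok):
        raise ValueError(f"requested {k} models but only {len(ok)} succeeded")
    ranked = sorted(ok, key=lambda r: (r.final_cost, r.restart_index))[:k]
    return ModelEnsemble(results=tuple(ranked), k_best=k)


def parameter_correlation(ensemble: ModelEnsemble) -> np.ndarray:
    """Pairwise Pearson correlation of the models' parameter vectors.

    Entry ``(a, b)`` correlates the constrained (physical-scale) parameter
    vectors of models ``a`` and ``b``; the matrix is symmetric with unit
    diagonal.  A zero-variance parameter vector yields NaN entries (reported
    as missing rather than raising).
    """
    vecs = np.stack([constrained_vector(r.params) for r in ensemble.results])
    k = vecs.shape[0]
    centered = vecs - vecs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    corr = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(k):
            if norms[a] == 0 or norms[b] == 0:
                continue
            corr[a, b] = float(centered[a] @ centered[b] / (norms[a] * norms[b]))
    return corr


def summarize_parameters(ensemble: ModelEnsemble, use_std: bool = False):
    """Elementwise mean and variance of parameters across the ensemble.

    Variance is the population variance (divide by k); set ``use_std`` for
    standard deviation instead.  Computed on the constrained scale.
    """
    if not ensemble.results:
        raise ValueError("empty ensemble")
    vecs = np.stack([constrained_vector(r.params) for r in ensemble.results])
    mean = vecs.mean(axis=0)
    spread = vecs.std(axis=0) if use_std else vecs.var(axis=0)
    return mean, spread


def compare_conditions(
    ensemble_with: ModelEnsemble,
    ensemble_without: ModelEnsemble,
    ablated_cost: float | None = None,
) -> dict:
    """Report best/median costs per condition and their ratio.

    ``ratio`` is ``best_with / best_without``: values below 1 mean the gated
    model fits better (the reference result is a roughly twofold cost
    reduction); an ablated cost far above both shows the fitted network
    relies on the gate.
    """
    report = {
        "best_with": float(ensemble_with.costs[0]),
        "best_without": float(ensemble_without.costs[0]),
        "median_with": float(np.median(ensemble_with.costs)),
        "median_without": float(np.median(ensemble_without.costs)),
        "ratio": float(ensemble_with.costs[0] / ensemble_without.costs[0]),
    }
    if ablated_cost is not None:
        report["ablated_cost"] = float(ablated_cost)
    return report
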