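"""Optional matplotlib panels: receptive fields and ensemble summaries.

Lazy-imports matplotlib (install the ``plot`` extra); everything else in the
package works without it.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ModelEnsemble, parameter_correlation, summarize_parameters
from .protocol import ResponseTensor


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_receptive_fields(model: ResponseTensor, data: ResponseTensor | None = None,
                          types=None):
    """Per-type panels: spatial profile (top) and central time course (bottom).

    Model in red, optional target data in gray, mirroring the standard
    model-vs-data layout.
    """
    plt = _plt()
    names = list(types or model.types)
    fig, axes = plt.subplots(2, len(names), figsize=(2.2 * len(names), 4.5), squeeze=False)
    center = list(model.positions).index(0)
    for i, name in enumerate(names):
        m = model.values[model.types.index(name)]
        spatial_ax, time_ax = axes[0, i], axes[1, i]
        if data is not None and name in data.types:
            d = data.values[data.types.index(name)]
            spatial_ax.plot(data.positions, d[:, -1], color="0.6")
            time_ax.plot(data.times_s, d[center], color="0.6")
        spatial_ax.plot(model.positions, m[:, -1], color="crimson")
        time_ax.plot(model.times_s, m[center], color="crimson")
        spatial_ax.set_title(name)
        spatial_ax.set_xlabel("offset (columns)")
        time_ax.set_xlabel("time (s)")
    axes[0, 0].set_ylabel("late response (mV)")
    axes[1, 0].set_ylabel("response (mV)")
    fig.tight_layout()
    return fig


def plot_ensemble_summary(ensemble: ModelEnsemble):
    """Costs, cross-model parameter correlation matrix, and parameter
    mean +/- variance for the retained best models."""
    plt = _plt()
    fig, (ax_cost, ax_corr, ax_par) = plt.subplots(1, 3, figsize=(12, 3.4))
    k = len(ensemble.results)
    ax_cost.bar(np.arange(k), ensemble.costs, color="steelblue")
    ax_cost.set_xlabel("model rank")
    ax_cost.set_ylabel("final cost")
    corr = parameter_correlation(ensemble)
    im = ax_corr.imshow(corr, vmin=-1, vmax=1, cmap="RdBu_r")
    fig.colorbar(im, ax=ax_corr, label="Pearson r")
    ax_corr.set_xlabel("model")
    ax_corr.set_ylabel("model")
    mean, var = summarize_parameters(ensemble)
    idx = np.arange(mean.size)
    ax_par.errorbar(idx, mean, yerr=var, fmt=".", ms=3, lw=0.8, color="k")
    ax_par.set_xlabel("parameter index")
    ax_par.set_ylabel("mean +/- variance")
    fig.tight_layout()
    return fig
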