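"""Diagnostic plots for a scaling run (model components, normal probability
plot of the normalized deviations, resolution-binned statistics)."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import scipy.stats

from . import reflection_data as rd
from .components import SmoothBComponent, Smooth1DComponent
from .error_model import normalized_deviations


def plot_model_components(state, path) -> None:
    """Scale and B-factor curves per sweep, absorption coefficients."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for sid, model in state.models.items():
        meta = state.sweeps[sid]
        phi = np.linspace(0.0, meta.width, 200)
        scale = model.components.get("scale")
        if isinstance(scale, Smooth1DComponent) and \
                not isinstance(scale, SmoothBComponent):
            from .components import eval_smooth_1d
            v, _, _ = eval_smooth_1d(scale.params, scale.first_position,
                                     phi / scale.spacing, scale.V)
            axes[0].plot(phi + meta.phi_start, v, label=sid)
        decay = model.components.get("decay")
        if isinstance(decay, SmoothBComponent):
            from .components import eval_smooth_1d
            b, _, _ = eval_smooth_1d(decay.params, decay.first_position,
                                     phi / decay.spacing, decay.V)
            axes[1].plot(phi + meta.phi_start, b, label=sid)
        absorption = model.components.get("absorption")
        if absorption is not None and hasattr(absorption, "lmax"):
            axes[2].bar(np.arange(absorption.n_params), absorption.params,
                        alpha=0.6, label=sid)
    axes[0].set_xlabel("phi (deg)")
    axes[0].set_ylabel("inverse scale C")
    axes[1].set_xlabel("phi (deg)")
    axes[1].set_ylabel("relative B (A^2)")
    axes[2].set_xlabel("coefficient index")
    axes[2].set_ylabel("P_lm")
    for ax in axes:
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_normal_probability(state, path) -> None:
    t = state.table
    ok = rd.usable(t)
    sub = t[ok]
    dev = normalized_deviations(sub["group_id"].to_numpy(),
                                sub["I_work"].to_numpy(dtype=float),
                                sub["var_prime"].to_numpy(dtype=float),
                                sub["g"].to_numpy(dtype=float))
    d = np.sort(dev.deltas(1.0, 0.0))
    n = len(d)
    if n == 0:
        return
    q = scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(q, d, ".", ms=2)
    lim = [min(q[0], -4), max(q[-1], 4)]
    ax.plot(lim, lim, "k-", lw=0.8)
    ax.set_xlabel("expected normal quantile")
    ax.set_ylabel("observed delta")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_binned_statistics(state, path) -> None:
    bins = state.report.get("merging", {}).get("bins", [])
    if not bins:
        return
    s = np.array([1.0 / b["d_min"] ** 2 for b in bins])
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, key, label in ((axes[0], "r_meas", "Rmeas"),
                           (axes[1], "cc_half", "CC1/2"),
                           (axes[2], "i_over_sigma", "<I/sig>")):
        y = [b[key] for b in bins]
        ax.plot(s, y, "o-")
        ax.set_xlabel("1/d^2 (1/A^2)")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_plots(state, directory) -> list[str]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = []
    for fn, name in ((plot_model_components, "model_components.png"),
                     (plot_normal_probability, "normal_probability.png"),
                     (plot_binned_statistics, "binned_statistics.png")):
        p = directory / name
        fn(state, p)
        if p.exists():
            out.append(str(p))
    return out
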