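"""Optional diagnostic plots (requires matplotlib)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_solution_path", "plot_pr_curve"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_solution_path(model, feature_names=None, ax=None):
    """Coefficient trajectories against lambda (log axis, reversed)."""
    ax = _ax(ax)
    path = model.path_ if hasattr(model, "path_") else model
    lam = path.lambdas
    for j in range(path.coef.shape[0]):
        if np.any(path.coef[j] != 0):
            name = feature_names[j] if feature_names is not None else f"x{j}"
            ax.plot(lam, path.coef[j], label=str(name))
    ax.set_xscale("log")
    ax.invert_xaxis()
    ax.set_xlabel("lambda")
    ax.set_ylabel("coefficient")
    ax.legend(fontsize="small")
    return ax


def plot_pr_curve(pr, ax=None):
    """Step precision-recall curve with the prevalence baseline."""
    ax = _ax(ax)
    ax.step(np.r_[0.0, pr.recall], np.r_[pr.precision[0], pr.precision], where="post")
    ax.axhline(pr.prevalence, ls="--", color="grey", lw=1)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.05)
    ax.set_title(f"AUC-PR = {pr.auc_pr:.3f}")
    return ax
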