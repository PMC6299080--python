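"""Minimal figures: Kaplan–Meier by risk group and the RMIP bar chart."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def _km_steps(curve, tmax=None):
    t = np.concatenate([[0.0], curve.times])
    s = np.concatenate([[1.0], curve.survival])
    if tmax is not None:
        t = np.append(t, tmax)
        s = np.append(s, s[-1])
    return t, s


def plot_km_by_risk(curves, logrank, path, title=""):
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"low": "tab:blue", "high": "tab:red"}
    tmax = max(c.times.max() for c in curves.values() if c.times.size)
    for g, c in curves.items():
        t, s = _km_steps(c, tmax)
        ax.step(t, s, where="post", label=f"{g} risk (n={int(c.n_risk[0]) if c.n_risk.size else 0})",
                color=colors.get(g))
    ax.set_xlabel("months")
    ax.set_ylabel("progression-free survival")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"{title}  log-rank p={logrank.p:.3g}".strip())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_rmip(rmip_table, path, top: int = 40):
    table = rmip_table.table.sort_values("rank").head(top)
    fig, ax = plt.subplots(figsize=(max(4, 0.22 * len(table)), 4))
    ax.bar(range(len(table)), table["rmip"], color="tab:gray")
    ax.set_xticks(range(len(table)))
    ax.set_xticklabels(table.index, rotation=90, fontsize=7)
    ax.set_ylabel(f"RMIP (B={rmip_table.B})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_cv_curve(cv, path):
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(np.log(cv.lambdas), cv.mean_deviance, yerr=cv.se_deviance,
                fmt="o-", ms=3, lw=1, ecolor="lightgray")
    ax.axvline(np.log(cv.lambda_min), ls="--", color="tab:blue", label="lambda_min")
    ax.axvline(np.log(cv.lambda_1se), ls="--", color="tab:red", label="lambda_1SE")
    ax.set_xlabel("log lambda")
    ax.set_ylabel("CV partial-likelihood deviance")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
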