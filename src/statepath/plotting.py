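"""Standard figures: reactive density map, RC overlays, quasi-potentials and
Fokker-Planck stationary densities.  All functions take an optional Axes and
return it, so they compose into panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_density_map",
    "plot_rc_overlay",
    "plot_quasipotential",
    "plot_fp_solution",
]


def plot_density_map(dmap, ax=None, cmap="viridis"):
    ax = ax or plt.figure(figsize=(5, 4)).add_subplot()
    x = dmap.bin_centers(0)
    y = dmap.bin_centers(1)
    ax.contourf(x, y, dmap.values.T, levels=20, cmap=cmap)
    ax.set_xlabel(f"feature axis {dmap.axes[0]}")
    ax.set_ylabel(f"feature axis {dmap.axes[1]}")
    ax.set_title("reactive trajectory density")
    return ax


def plot_rc_overlay(ensemble, rcs, axes=(0, 1), ax=None, max_traj=40):
    ax = ax or plt.figure(figsize=(5, 4)).add_subplot()
    a, b = axes
    for tr in list(ensemble)[:max_traj]:
        ax.plot(tr.X[:, a], tr.X[:, b], color="0.8", lw=0.5, zorder=1)
    for label, rc in (rcs.items() if isinstance(rcs, dict) else enumerate(rcs, 1)):
        ax.plot(rc.images[:, a], rc.images[:, b], "o-", ms=3, lw=2,
                label=f"RC {label}", zorder=2)
    ax.legend()
    ax.set_xlabel(f"feature axis {a}")
    ax.set_ylabel(f"feature axis {b}")
    return ax


def plot_quasipotential(qp, ax=None, label=None):
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    ok = ~qp.mask
    ax.errorbar(qp.s_grid[ok], qp.phi_cells[ok], yerr=qp.grad_se[ok] * qp.ds,
                fmt="o-", ms=3, label=label)
    ax.set_xlabel("reaction coordinate s")
    ax.set_ylabel("quasi-potential $\\phi(s)$")
    if label:
        ax.legend()
    return ax


def plot_fp_solution(sol, ax=None):
    ax = ax or plt.figure(figsize=(5, 3.5)).add_subplot()
    for t, r in zip(sol.times[:: max(len(sol.times) // 5, 1)],
                    sol.rho[:: max(len(sol.rho) // 5, 1)]):
        ax.plot(sol.s, r, color="0.7", lw=0.8)
    ax.plot(sol.s, sol.rho_ss, "k-", lw=2, label="stationary")
    ax.set_xlabel("reaction coordinate s")
    ax.set_ylabel("density $\\rho(s)$")
    ax.legend()
    return ax
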