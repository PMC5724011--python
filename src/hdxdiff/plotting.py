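"""Figures: differential heat maps, uptake charts, FP decay curves."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .consolidate import ResidueMap  # noqa: E402
from .fp import FPSeries  # noqa: E402
from .uptake import UptakeStat  # noqa: E402

__all__ = ["heatmap", "uptake_chart", "fp_chart"]


def heatmap(rmap: ResidueMap, path, vlim: Optional[float] = None, cmap: str = "RdBu_r"):
    """Residues x times heat map of rel_frac_delta, gaps shown blank.

    Color limits are symmetric about zero (red = more exchange in the
    perturbed state), at ``vlim`` or the map's max |value|.
    """
    data = rmap.values.T  # times as rows, residues as columns
    if vlim is None:
        finite = data[np.isfinite(data)]
        vlim = float(np.abs(finite).max()) if finite.size else 1.0
        vlim = vlim or 1.0
    fig, ax = plt.subplots(figsize=(max(6, rmap.length / 25), 2.2))
    masked = np.ma.masked_invalid(data)
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("lightgray")
    im = ax.imshow(masked, aspect="auto", cmap=cm, vmin=-vlim, vmax=vlim,
                   extent=(0.5, rmap.length + 0.5, len(rmap.times) - 0.5, -0.5))
    ax.set_yticks(range(len(rmap.times)))
    ax.set_yticklabels([f"{t:g}" for t in rmap.times])
    ax.set_xlabel("residue")
    ax.set_ylabel("labeling time (min)")
    ax.set_title(rmap.protein_id)
    fig.colorbar(im, ax=ax, label="rel. fractional difference")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def uptake_chart(per_state: Mapping[str, Mapping[float, UptakeStat]], path,
                 title: str = "", max_uptake: Optional[float] = None):
    """Mean uptake vs labeling time per state, replicate SD as error bars."""
    fig, ax = plt.subplots(figsize=(4.2, 3.2))
    for state, by_time in per_state.items():
        times = sorted(by_time)
        means = [by_time[t].mean for t in times]
        sds = [by_time[t].sd for t in times]
        ax.errorbar(times, means, yerr=sds, marker="o", capsize=3, label=state)
    if max_uptake:
        ax.axhline(max_uptake, ls=":", color="gray", lw=1)
    ax.set_xscale("log")
    ax.set_xlabel("labeling time (min)")
    ax.set_ylabel("deuterium uptake (Da)")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def fp_chart(series: Sequence[FPSeries], path):
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for s in series:
        ax.plot(s.time_h, s.mP, marker="o", ms=3, label=s.label or None)
    ax.set_xlabel("time after UV exposure (h)")
    ax.set_ylabel("polarization (mP)")
    if any(s.label for s in series):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
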