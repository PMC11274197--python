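"""PV-loop and strain bar charts (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .postprocess import REGION_NAMES  # noqa: E402

__all__ = ["plot_pv_loops", "plot_regional_strain"]

_COLORS = {"A": "tab:blue", "B": "tab:red", "C": "tab:green"}


def plot_pv_loops(results: dict, path):
    """Overlayed LV pressure-volume loops of the scenario results."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for s, r in results.items():
        ax.plot(r.trace.v_lv, r.trace.p_lv, color=_COLORS.get(s, "k"),
                label=f"{s}")
    ax.set_xlabel("LV volume (mL)")
    ax.set_ylabel("LV pressure (mmHg)")
    ax.legend(title="scenario")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_regional_strain(results: dict, path):
    """Grouped bars of regional longitudinal strain per scenario."""
    fig, ax = plt.subplots(figsize=(6, 4))
    width = 0.8 / max(len(results), 1)
    for i, (s, r) in enumerate(results.items()):
        reg = r.strain.regional_longitudinal()
        xs = [j + i * width for j in range(len(REGION_NAMES))]
        ax.bar(xs, [reg[n] for n in REGION_NAMES], width,
               color=_COLORS.get(s, "k"), label=s)
    ax.set_xticks([j + width for j in range(len(REGION_NAMES))])
    ax.set_xticklabels(REGION_NAMES)
    ax.set_ylabel("longitudinal strain")
    ax.legend(title="scenario")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
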