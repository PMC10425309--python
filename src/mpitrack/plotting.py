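"""Summary figures for cohort results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort import FOV_MODES, CohortResult, detection_rate

__all__ = ["plot_cohort_summary"]


def plot_cohort_summary(result: CohortResult):
    """Two-panel overview: per-mode detection rate and in-vivo vs ex-vivo
    concordance of the focused scan (detectable pairs only)."""
    fig, (ax_rate, ax_scatter) = plt.subplots(1, 2, figsize=(9, 4))

    rates = [detection_rate(result, m) for m in FOV_MODES]
    ax_rate.bar(FOV_MODES, rates, color=["#888888", "#2a9d8f", "#264653"])
    ax_rate.set_ylim(0, 1.05)
    ax_rate.set_ylabel("detection rate (SNR > 5)")
    ax_rate.set_title("pLN detectability by scan mode")

    t = result.table
    foc = t[(t["fov_mode"] == "focused2") & t["detectable"]]
    exv = t[(t["fov_mode"] == "exvivo") & t["detectable"]]
    pairs = foc.merge(exv, on=["mouse", "side"], suffixes=("_f", "_e"))
    if not pairs.empty:
        x = pairs["cell_estimate_e"].to_numpy(float)
        y = pairs["cell_estimate_f"].to_numpy(float)
        ax_scatter.scatter(x, y, c="#2a9d8f")
        lim = [0, 1.1 * max(x.max(), y.max())]
        ax_scatter.plot(lim, lim, "k--", lw=1, label="identity")
        ax_scatter.legend()
    ax_scatter.set_xlabel("ex vivo cell estimate")
    ax_scatter.set_ylabel("focused-FOV cell estimate")
    ax_scatter.set_title("in vivo vs ex vivo concordance")
    fig.tight_layout()
    return fig
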