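"""Per-well diagnostic plot: blanked trace with the accepted window."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

import numpy as np  # noqa: E402

from .phase_detection import DetectionResult  # noqa: E402
from .preprocessing import BlankedCurve  # noqa: E402

__all__ = ["plot_detection"]


def plot_detection(curve: BlankedCurve, det: DetectionResult, path,
                   title: str = "") -> None:
    """Time vs blanked backscatter with the accepted exponential window
    highlighted and a log-scale inset of the fitted segment."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.time, curve.value, ".", ms=3, color="0.6", label="blanked BS")
    s, e = det.start_index, det.end_index
    ax.plot(curve.time[s:e + 1], curve.value[s:e + 1], ".", ms=4,
            color="tab:red", label="accepted window")
    if det.fit is not None and det.converged:
        tt = curve.time[s:e + 1]
        ax.plot(tt, np.exp(det.fit.intercept + det.fit.mu * tt), "-",
                color="tab:blue", lw=1,
                label=f"fit: mu = {det.fit.mu:.3f} 1/h")
        inset = ax.inset_axes([0.55, 0.1, 0.4, 0.35])
        inset.semilogy(tt, curve.value[s:e + 1], ".", ms=2, color="tab:red")
        inset.set_xticks([])
    ax.set_xlabel("time [h]")
    ax.set_ylabel("blanked backscatter [a.u.]")
    ax.legend(loc="upper left", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
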