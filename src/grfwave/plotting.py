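"""Limit-curve plots: mean stance waveform vs per-PC ±SD limits.

One panel per retained component, mean as a solid line, the upper
(plus SD) limit marked "+" and the lower (minus SD) limit marked a
down-triangle, following the conventional presentation of PCA modes of
gait waveforms.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pca import WaveformPCA


def plot_limit_curves(
    model: WaveformPCA, path: str | Path, title: str | None = None
) -> None:
    k = max(model.n_retained_, 1)
    fig, axes = plt.subplots(k, 1, figsize=(6, 2.4 * k), sharex=True)
    axes = np.atleast_1d(axes)
    p = np.arange(model.mean_.size)
    for pc, ax in enumerate(axes, start=1):
        if pc > model.n_retained_:
            ax.plot(p, model.mean_, "k-")
            continue
        rec = model.reconstruct_limits(pc)
        ax.plot(p, rec.mean, "k-", label="mean")
        ax.plot(p[::4], rec.upper[::4], "r+", ms=5, label="upper (+SD)")
        ax.plot(p[::4], rec.lower[::4], "bv", ms=4, label="lower (-SD)")
        ax.set_ylabel("force (BW)")
        ax.set_title(
            f"PC{pc} ({100 * rec.variance_fraction:.2f}% of variance)",
            fontsize=9,
        )
        if pc == 1:
            ax.legend(fontsize=7, loc="upper right")
    axes[-1].set_xlabel("stance (%)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
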