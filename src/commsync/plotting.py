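"""Basic heatmap export for wavelet modulus ratio maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .wavelets import SignificanceMask, WMRMap, fourier_period


def plot_wmr(
    rho_map: WMRMap,
    mask: SignificanceMask | None = None,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Render rho(t, s) as a heatmap (blue = compensation, red = synchrony).

    Significance masks, if given, are drawn as contour outlines.  Returns
    the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    periods = fourier_period(rho_map.scales)
    t = np.arange(rho_map.n_times)
    pcm = ax.pcolormesh(
        t, periods, rho_map.rho, cmap="RdBu_r", vmin=0, vmax=1, shading="nearest"
    )
    fig.colorbar(pcm, ax=ax, label=r"wavelet modulus ratio $\rho$")
    if mask is not None:
        if mask.low_mask.any():
            ax.contour(t, periods, mask.low_mask.astype(float), levels=[0.5], colors="blue")
        if mask.high_mask.any():
            ax.contour(t, periods, mask.high_mask.astype(float), levels=[0.5], colors="red")
    ax.set_yscale("log", base=2)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("period (months)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
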