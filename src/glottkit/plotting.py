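"""Quick-look plots for glottal kinematics and source spectra."""

from __future__ import annotations

import numpy as np


def plot_gvg(gvg, ax=None, cmap="viridis"):
    """Glottovibrogram heatmap: AP position (posterior up) against time.

    Returns the matplotlib Axes.
    """
    from matplotlib import pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    n_frames = gvg.width.shape[1]
    extent = (0.0, 1e3 * n_frames / gvg.fps, 1.0, 0.0)
    im = ax.imshow(gvg.width, aspect="auto", origin="upper",
                   extent=extent, cmap=cmap, interpolation="nearest")
    ax.set_xlabel("time [ms]")
    ax.set_ylabel("AP position (0 = posterior)")
    ax.figure.colorbar(im, ax=ax, label="glottal width [px]")
    return ax


def plot_flow_spectrum(freqs, level_db, f_o=None, ax=None, floor_db=-80.0):
    """Normalized magnitude spectrum of the glottal flow, in dB re max.

    Marks the first two harmonics when ``f_o`` is given; returns the
    Axes.
    """
    from matplotlib import pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    keep = level_db >= floor_db
    ax.plot(np.asarray(freqs)[keep] / 1e3, np.asarray(level_db)[keep],
            lw=0.8)
    if f_o is not None:
        for k in (1, 2):
            ax.axvline(k * f_o / 1e3, color="k", ls=":", lw=0.8)
    ax.set_xlabel("frequency [kHz]")
    ax.set_ylabel("level [dB re max]")
    ax.set_ylim(floor_db, 3)
    return ax
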