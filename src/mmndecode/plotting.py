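"""Quick-look figures for the decoding workflow (matplotlib)."""

from __future__ import annotations

import numpy as np

from .containers import EpochSet
from .decode import DecoderResults
from .evaluate import AucMap


def plot_erp(epochs: EpochSet, channels=None, ax=None):
    """Grand-average standard/deviant ERPs and their difference wave."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    idx = (epochs.montage.eeg_indices if channels is None
           else epochs.montage.indices(channels))
    y = epochs.y
    std = epochs.data[y == -1][:, idx].mean(axis=(0, 1))
    dev = epochs.data[y == 1][:, idx].mean(axis=(0, 1))
    ax.plot(epochs.times, std, label="standard")
    ax.plot(epochs.times, dev, label="deviant")
    ax.plot(epochs.times, dev - std, "--", label="difference")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("amplitude (μV)")
    ax.legend()
    return ax


def plot_weight_map(results: DecoderResults, ax=None):
    """Decoder weights as a channel × time image."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    W = results.weight_map()
    lim = np.abs(W).max() or 1.0
    im = ax.imshow(W, aspect="auto", cmap="RdBu_r", vmin=-lim, vmax=lim)
    ax.set_xlabel("time sample")
    ax.set_ylabel("channel")
    ax.figure.colorbar(im, ax=ax, label="weight")
    return ax


def plot_auc_map(amap: AucMap, ax=None):
    """Per-feature AUC image with the 0.5 no-discrimination midpoint."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(amap.auc, aspect="auto", cmap="RdBu_r", vmin=0.0, vmax=1.0)
    ax.set_xlabel("time sample")
    ax.set_ylabel("channel")
    ax.figure.colorbar(im, ax=ax, label="AUC")
    return ax


def plot_tracking(tracker, ax=None):
    """Emitted fused posteriors over trial index."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if tracker.emissions:
        idx, _, post, _ = zip(*tracker.emissions)
        ax.step(idx, post, where="post")
    ax.axhline(0.5, color="k", lw=0.5, ls=":")
    ax.set_ylim(0, 1)
    ax.set_xlabel("trial index")
    ax.set_ylabel("p(deviant)")
    return ax
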