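"""Diagnostic plots."""

from __future__ import annotations

import numpy as np

from .artifact import ArtifactMask
from .preprocess import SelectedChannel

__all__ = ["plot_artifact_detection"]


def plot_artifact_detection(channel: SelectedChannel, mask: ArtifactMask, ax=None):
    """Three panels: smoothed envelope, envelope vs adaptive threshold,
    and the resulting artifact labels over the channel."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(3, 1, sharex=True, figsize=(10, 6))
    t = np.arange(channel.samples.size) / channel.frame_rate
    ax[0].plot(t, mask.envelope, lw=0.8)
    ax[0].set_ylabel("SG envelope")
    ax[1].plot(t, mask.envelope, lw=0.8, label="envelope")
    ax[1].plot(t, mask.threshold, lw=0.8, label="adaptive threshold")
    ax[1].legend(loc="upper right", fontsize=8)
    ax[1].set_ylabel("amplitude")
    ax[2].plot(t, channel.samples, lw=0.5)
    ax[2].fill_between(t, *ax[2].get_ylim(), where=mask.flags, alpha=0.3,
                       color="tab:red", label="artifact")
    ax[2].set_xlabel("time (s)")
    ax[2].set_ylabel("channel")
    ax[2].legend(loc="upper right", fontsize=8)
    return ax
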