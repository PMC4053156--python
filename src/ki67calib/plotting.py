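"""Diagnostic plots for method comparison (matplotlib)."""

from __future__ import annotations

import numpy as np

from .method_comparison import BlandAltmanResult, ConfidenceEllipse


def bland_altman_plot(result: BlandAltmanResult, ax=None, label: str = ""):
    """Difference-vs-mean scatter with bias line and limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.means, result.differences, s=12, alpha=0.7, label=label)
    ax.axhline(result.mean_difference, color="k", lw=1)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of methods (%)")
    ax.set_ylabel("difference (%)")
    return ax


def variability_plot(profile, ax=None):
    """Inter-observer SD against the mean, per spot."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(profile["mean"], profile["sd"], s=12, alpha=0.7)
    ax.set_xlabel("mean of observers (%)")
    ax.set_ylabel("SD of observers (%)")
    return ax


def ellipse_plot(ellipse: ConfidenceEllipse, ax=None, **kwargs):
    """Outline of a confidence ellipse (and its major axis)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.linspace(0, 2 * np.pi, 200)
    a, b = ellipse.major_axis_length / 2, ellipse.minor_axis_length / 2
    th = np.radians(ellipse.tilt_deg)
    x = ellipse.centre[0] + a * np.cos(t) * np.cos(th) - b * np.sin(t) * np.sin(th)
    y = ellipse.centre[1] + a * np.cos(t) * np.sin(th) + b * np.sin(t) * np.cos(th)
    ax.plot(x, y, **kwargs)
    return ax
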