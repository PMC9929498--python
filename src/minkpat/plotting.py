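"""Plotting helpers for threshold-sweep curves."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends beforehand
import matplotlib.pyplot as plt

from .minkowski import MinkowskiCurve

__all__ = ["plot_p2_over_a_curves", "plot_minkowski_curves"]


def plot_p2_over_a_curves(curves: Mapping[str, MinkowskiCurve], ax=None):
    """P²/A against threshold level for one or more specimens.

    Heavily scribbled patterns ride high across mid thresholds; compact
    blotched patterns stay near the isoperimetric floor of 4π.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for label, curve in curves.items():
        ax.plot(curve.levels, curve.p2_over_a_curve, label=label)
    ax.set_xlabel("threshold level")
    ax.set_ylabel(r"$P^2/A$")
    ax.legend(frameon=False)
    return ax


def plot_minkowski_curves(curve: MinkowskiCurve, axes=None):
    """P(t), A(t) and χ(t) panels for a single specimen."""
    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(10, 3))
    for ax, (name, vals) in zip(axes, [("P", curve.P), ("A", curve.A), (r"$\chi$", curve.chi)]):
        ax.plot(curve.levels, vals)
        ax.set_xlabel("threshold level")
        ax.set_ylabel(name)
    return axes
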