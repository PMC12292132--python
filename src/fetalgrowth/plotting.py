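"""Minimal static plots (requires matplotlib, not a hard dependency)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .polynomial import polyval_ascending
from .reference import GrowthReference


def plot_reference(
    ref: GrowthReference, records: pd.DataFrame | None = None, ax=None
):
    """Mean curve with its ±2σ band, optionally over a scatter of records.

    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    days = np.arange(int(ref.ga_range[0]), int(ref.ga_range[1]) + 1, dtype=float)
    ax.plot(days, polyval_ascending(ref.mean_coeffs, days), "r-", label="mean")
    ax.plot(days, polyval_ascending(ref.upper_coeffs, days), "b--", label="+2σ")
    ax.plot(days, polyval_ascending(ref.lower_coeffs, days), "g--", label="−2σ")
    if records is not None:
        sub = records[records["parameter"] == ref.parameter.value]
        ax.plot(sub["ga_days"], sub["value"], "k.", ms=2, alpha=0.4)
    ax.set_xlabel("gestational age (days)")
    ax.set_ylabel(f"{ref.parameter.value} ({ref.units})")
    ax.legend()
    return ax
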