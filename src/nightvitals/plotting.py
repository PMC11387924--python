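"""Diagnostic figures: Bland-Altman scatter, error CDFs, time courses."""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np


def plot_error_cdf(quantile_sets: Dict[str, tuple], ax=None):
    """Empirical CDFs of absolute error, one curve per label.

    ``quantile_sets`` maps a label to ``(sorted_abs_errors, cdf_probs)`` as
    returned by :func:`nightvitals.agreement.abs_error_quantiles`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, (x, cdf) in quantile_sets.items():
        ax.step(x, cdf, where="post", label=label)
    ax.set_xlabel("absolute error")
    ax.set_ylabel("cumulative probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_time_course(table, ax=None, device_label: str = "device",
                     reference_label: str = "reference"):
    """Hourly mean-centered vitals, device vs reference, with SD bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    hours = table["hour"].to_numpy()
    ax.errorbar(hours, table["ref_mean"], yerr=table["ref_sd"], fmt="o-",
                label=reference_label, capsize=2)
    ax.errorbar(hours + 0.1, table["device_mean"], yerr=table["device_sd"],
                fmt="s--", label=device_label, capsize=2)
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("hour from lights-off")
    ax.set_ylabel("mean-centered value")
    ax.legend()
    return ax
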