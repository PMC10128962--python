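"""Optional diagnostic plots (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np

from .model import NO_SHRINKAGE, FollowUp, ModelParams, radius_at, regrowth_time


def plot_followup_fit(
    fu: FollowUp,
    params: Optional[ModelParams] = None,
    path: Union[str, Path, None] = None,
):
    """Measured radii with error bars and, optionally, the fitted curve.

    Returns the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(fu.times, fu.radii, yerr=fu.sigma, fmt="o", color="k",
                capsize=2, label="measurements")
    if params is not None:
        lo = min(fu.times.min(), -0.5)
        hi = max(fu.times.max(), 1.0) * 1.05
        tt = np.linspace(lo, hi, 400)
        ax.plot(tt, radius_at(params, tt), "r-", label="model")
        t_min = regrowth_time(params)
        if t_min is not NO_SHRINKAGE:
            ax.axvline(t_min, color="r", ls="--", lw=1, label=f"$t_{{min}}$ = {t_min:.2f} yr")
    ax.axvline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("time since RT start (yr)")
    ax.set_ylabel("mean tumor radius (mm)")
    ax.set_title(f"patient {fu.patient_id}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return ax
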