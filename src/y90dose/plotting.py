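"""Boxplot-style summaries of DVH error sweeps (optional figure export)."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

from .dvh import SweepResult


def error_boxplot(result: SweepResult, sphere: float,
                  out: Optional[Union[str, Path]] = None):
    """Mean / quartiles / extremes of the DVH error vs PSF FWHM for one
    sphere, LDM and DPK side by side.  Returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    colors = {"LDM": "tab:blue", "DPK": "tab:red"}
    for method in result.methods:
        summaries = result.summaries(sphere, method)
        if not summaries:
            continue
        f = [s.psf_fwhm for s in summaries]
        ax.plot(f, [s.mean for s in summaries], "-o", ms=3,
                color=colors.get(method), label=f"{method} mean")
        ax.fill_between(f, [s.q25 for s in summaries], [s.q75 for s in summaries],
                        alpha=0.25, color=colors.get(method))
        ax.plot(f, [s.min for s in summaries], ":", lw=0.8, color=colors.get(method))
        ax.plot(f, [s.max for s in summaries], ":", lw=0.8, color=colors.get(method))
    ax.axhline(0.0, color="k", lw=0.6)
    ax.set_xlabel("PSF FWHM (mm)")
    ax.set_ylabel("DVH error (%)")
    ax.set_title(f"{sphere:g} mm hot sphere, {result.voxel_size:g} mm voxels")
    ax.legend()
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
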