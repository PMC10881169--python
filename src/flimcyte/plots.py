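"""Optional figures mirroring the standard displays of the analysis:
a phasor-plane density plot with the universal semicircle, the axial
(per-Z) fraction-bound profile, and the area-vs-fraction-bound scatter.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cellmetrics import CellRecord, z_profile
from .config import PipelineConfig

__all__ = ["phasor_density_plot", "z_profile_plot", "area_scatter_plot",
           "pipeline_figures"]


def phasor_density_plot(g: np.ndarray, s: np.ndarray, valid: np.ndarray,
                        path: str | Path, bins: int = 200) -> Path:
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist2d(g[valid], s[valid], bins=bins, range=[[0, 1], [0, 0.6]],
              cmap="inferno", cmin=1)
    th = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(th), 0.5 * np.sin(th), "w--", lw=1)
    ax.set(xlabel="g", ylabel="s", title="phasor plot (first harmonic)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def z_profile_plot(records: list[CellRecord], path: str | Path,
                   acq=None) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for cond, color in (("control", "tab:blue"), ("activated", "tab:red")):
        prof = z_profile(records, condition=cond, acq=acq)
        if prof.empty:
            continue
        x = prof["z_um"] if prof["z_um"].notna().all() else prof["z_index"]
        ax.errorbar(x, prof["mean"], yerr=prof["sd"], label=cond,
                    color=color, marker="o", capsize=3)
    ax.set(xlabel="Z (µm)", ylabel="fraction bound NAD(P)H",
           title="axial profile (mean ± SD across cells)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def area_scatter_plot(records: list[CellRecord], path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    for cond, color in (("control", "tab:blue"), ("activated", "tab:red")):
        sel = [r for r in records if r.condition == cond
               and np.isfinite(r.volume_mean_fbound)]
        if not sel:
            continue
        ax.scatter([r.area_um2 for r in sel],
                   [r.volume_mean_fbound for r in sel],
                   s=12, alpha=0.7, color=color, label=cond)
    ax.set(xlabel="cell area (µm²)", ylabel="fraction bound NAD(P)H",
           title="area vs metabolic state")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def pipeline_figures(records: list[CellRecord], cfg: PipelineConfig,
                     out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    z_profile_plot(records, out / "z_profile.png", acq=cfg.acquisition)
    area_scatter_plot(records, out / "area_scatter.png")
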