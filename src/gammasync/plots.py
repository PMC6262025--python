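"""Publication-style figures for pipeline outputs (PNG)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_map(tfmap, path: str | Path, title: str = "") -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    vmax = np.nanmax(np.abs(tfmap.values)) or 1.0
    im = ax.pcolormesh(tfmap.times, tfmap.freqs, tfmap.values,
                       cmap="RdBu_r", vmin=-vmax, vmax=vmax,
                       shading="nearest")
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time from stimulus (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(title or tfmap.kind)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_band_test(result, path: str | Path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(result.lags_ms, result.observed, color="tab:green",
            label="observed (median-subtracted)")
    ax.fill_between(result.lags_ms, result.threshold_lo,
                    result.threshold_hi, color="gray", alpha=0.4,
                    label="5th-95th surrogate")
    sig = result.significant_pos | result.significant_neg
    if sig.any():
        ax.plot(result.lags_ms[sig], result.observed[sig], "r.", ms=4,
                label="significant")
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("r")
    ax.set_title(f"{result.condition}: sync vs "
                 f"{result.band[0]:.0f}-{result.band[1]:.0f} Hz LFP")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_xcorr(xc, path: str | Path) -> None:
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.2))
    vmax = np.nanmax(np.abs(xc.r)) or 1.0
    im = ax.pcolormesh(xc.lags_ms, xc.freqs, xc.r, cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax, shading="nearest")
    ax.set_xlabel("lag (ms)")
    ax.set_ylabel("frequency (Hz)")
    ax.set_title(f"sync-LFP correlation, {xc.condition}")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_pipeline_figures(results: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    for region, m in results.get("amplitude_maps", {}).items():
        plot_map(m, out / f"amplitude_{region}.png",
                 f"{region} amplitude change (%)")
    if "ppc_map" in results:
        plot_map(results["ppc_map"], out / "ppc.png", "dLGN-V1 PPC")
    if "synchrony_spectrogram" in results:
        plot_map(results["synchrony_spectrogram"],
                 out / "synchrony_spectrogram.png",
                 "spike-synchrony rhythmicity (%)")
    for cond, xc in results.get("xcorr", {}).items():
        plot_xcorr(xc, out / f"xcorr_{cond}.png")
    for cond, bt in results.get("band_test", {}).items():
        plot_band_test(bt, out / f"band_test_{cond}.png")
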