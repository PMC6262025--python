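"""End-to-end orchestration of the analysis stages.

Stage order: time-frequency amplitude maps for both regions -> time-resolved
PPC -> PPC-amplitude correlation test -> spike synchrony (raw, corrected,
event-triggered, spectrogram) -> condition split -> synchrony-LFP
cross-correlation and the 50-90 Hz Monte Carlo band test per condition.

All stochastic stages draw their seeds from one master seed through
``numpy.random.SeedSequence``; identical bundle + seed give byte-identical
JSON/CSV outputs (timestamps go to the run log, never into result files).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .core import ParameterError, pool_trains
from .phasesync import ppc_amplitude_correlation, time_resolved_ppc
from .session_io import RunManifest, SessionBundle, config_hash, file_checksum
from .spectral import analytic_decompose, design_filter_bank, \
    event_locked_amplitude_change
from .spikesync import (SynchronyParams, event_triggered_synchrony,
                        synchrony_series, synchrony_spectrogram)
from .synccorr import band_monte_carlo_test, split_by_condition, \
    xcorr_synchrony_lfp

log = logging.getLogger(__name__)

STAGES = ("tfmap", "ppc", "ppc_amplitude_test", "spikesync",
          "synchrony_spectrogram", "condition_split", "xcorr", "band_test")


@dataclass
class PipelineConfig:
    """Resolved parameter tree of a full run."""

    f_lo: float = 20.0
    f_hi: float = 100.0
    window_pre_s: float = 0.25
    window_post_s: float = 0.5
    #: wider window for the PPC-amplitude correlation test: the circular-shift
    #: surrogate null needs a shift range long relative to the evoked response
    corr_pre_s: float = 0.75
    corr_post_s: float = 1.25
    baseline_s: float = 1.0
    ppc_surrogates: int = 2000
    band: tuple[float, float] = (50.0, 90.0)
    band_surrogates: int = 1000
    max_lag_ms: float = 50.0
    response_s: float = 0.5
    guard_s: float = 0.5
    synchrony: SynchronyParams = field(default_factory=SynchronyParams)
    make_plots: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        return d


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(bundle: SessionBundle, out_dir: str | Path, seed: int = 0,
                 config: PipelineConfig | None = None) -> dict:
    """Run every analysis stage on a session and write all outputs.

    Returns a dict of the in-memory stage results (maps, test results,
    series) keyed by stage name.
    """
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg.to_dict())

    ss = np.random.SeedSequence(seed)
    stage_rngs = {name: np.random.default_rng(child)
                  for name, child in zip(STAGES, ss.spawn(len(STAGES)))}
    manifest = RunManifest(
        tool_version=__version__, config_hash=chash, seed=seed,
        input_checksums=(
            {p.name: file_checksum(p)
             for p in sorted(bundle.source_dir.iterdir()) if p.is_file()}
            if bundle.source_dir else {}),
        stage_seeds={name: int(child.generate_state(1)[0] % (2 ** 31))
                     for name, child in zip(STAGES, ss.spawn(len(STAGES)))},
    )
    manifest.write(out / "manifest.json")

    results: dict = {"config_hash": chash}
    events = bundle.events
    if len(events) < 2:
        raise ParameterError("pipeline needs at least two events")

    def done(stage: str) -> None:
        manifest.stages_completed.append(stage)
        log.info("stage %s complete", stage)

    try:
        # 1. time-frequency amplitude maps, both regions
        bank = design_filter_bank(bundle.lfp_v1.fs, cfg.f_lo, cfg.f_hi)
        dec_v1 = analytic_decompose(bundle.lfp_v1, bank)
        dec_lgn = analytic_decompose(bundle.lfp_lgn, bank)
        win = (cfg.window_pre_s, cfg.window_post_s)
        amp_v1 = event_locked_amplitude_change(
            dec_v1, events, window=win, baseline_s=cfg.baseline_s)
        amp_lgn = event_locked_amplitude_change(
            dec_lgn, events, window=win, baseline_s=cfg.baseline_s)
        amp_v1.meta["config_hash"] = chash
        amp_lgn.meta["config_hash"] = chash
        amp_v1.to_hdf5(out / "maps.h5", "amplitude_V1")
        amp_lgn.to_hdf5(out / "maps.h5", "amplitude_dLGN")
        results["amplitude_maps"] = {"V1": amp_v1, "dLGN": amp_lgn}
        done("tfmap")

        # 2. time-resolved PPC
        ppc_map = time_resolved_ppc(dec_v1, dec_lgn, events, window=win)
        ppc_map.meta["config_hash"] = chash
        ppc_map.to_hdf5(out / "maps.h5", "ppc")
        results["ppc_map"] = ppc_map
        done("ppc")

        # 3. PPC-amplitude correlation with circular-shift surrogates,
        # on maps spanning the wider correlation window
        corr_win = (cfg.corr_pre_s, cfg.corr_post_s)
        ppc_corr_map = time_resolved_ppc(dec_v1, dec_lgn, events,
                                         window=corr_win)
        amp_corr_map = event_locked_amplitude_change(
            dec_v1, events, window=corr_win, baseline_s=cfg.baseline_s)
        ppc_amp = ppc_amplitude_correlation(
            ppc_corr_map, amp_corr_map, n_surrogates=cfg.ppc_surrogates,
            rng=stage_rngs["ppc_amplitude_test"])
        frame = ppc_amp.to_frame()
        frame.insert(0, "config_hash", chash)
        frame.to_csv(out / "ppc_amplitude_correlation.csv", index=False,
                     float_format="%.6g")
        _dump_json({
            "config_hash": chash,
            "peak_freq_hz": ppc_amp.peak_freq,
            "r_squared_at_peak": ppc_amp.r_squared_at_peak,
            "n_surrogates": ppc_amp.n_surrogates,
            "n_significant_pos": int(ppc_amp.significant_pos.sum()),
            "n_significant_neg": int(ppc_amp.significant_neg.sum()),
        }, out / "ppc_amplitude_test.json")
        results["ppc_amplitude"] = ppc_amp
        done("ppc_amplitude_test")

        # 4. spike synchrony
        v1_train = pool_trains(bundle.spikes_v1, "V1")
        lgn_train = pool_trains(bundle.spikes_lgn, "dLGN")
        sync = synchrony_series(v1_train, lgn_train, cfg.synchrony,
                                span=bundle.span,
                                rng=stage_rngs["spikesync"])
        _write_sync_h5(sync, out / "synchrony.h5", chash)
        wave = event_triggered_synchrony(sync, events, window=win)
        _write_waveform_csv(wave, out / "synchrony_waveform.csv", chash)
        results["synchrony"] = sync
        results["waveform"] = wave
        done("spikesync")

        # 5. synchrony rhythmicity spectrogram
        spec_map = synchrony_spectrogram(sync, events, window=win,
                                         baseline_s=cfg.window_pre_s)
        spec_map.meta["config_hash"] = chash
        spec_map.to_hdf5(out / "maps.h5", "synchrony_spectrogram")
        results["synchrony_spectrogram"] = spec_map
        done("synchrony_spectrogram")

        # 6. condition split
        gray, checker = split_by_condition(events, bundle.span,
                                           cfg.response_s, cfg.guard_s)
        results["segments"] = {"gray": gray, "checkerboard": checker}
        done("condition_split")

        # 7-8. per-condition cross-correlation and band Monte Carlo test
        results["xcorr"] = {}
        results["band_test"] = {}
        band_summaries = {}
        for seg in (gray, checker):
            if not seg.intervals:
                log.info("skipping %s: no segments", seg.condition)
                continue
            try:
                xc = xcorr_synchrony_lfp(sync, dec_v1, seg, cfg.max_lag_ms)
                results["xcorr"][seg.condition] = xc
            except ParameterError as e:
                log.info("xcorr skipped for %s: %s", seg.condition, e)
            try:
                bt = band_monte_carlo_test(
                    bundle.lfp_v1, v1_train, lgn_train, seg, cfg.band,
                    cfg.synchrony, n_surrogates=cfg.band_surrogates,
                    max_lag_ms=cfg.max_lag_ms,
                    rng=stage_rngs["band_test"], sync=sync)
                results["band_test"][seg.condition] = bt
                band_summaries[seg.condition] = {
                    "band_hz": list(bt.band),
                    "n_surrogates": bt.n_surrogates,
                    "n_significant_lags": bt.n_significant,
                    "n_significant_pos": int(bt.significant_pos.sum()),
                    "n_significant_neg": int(bt.significant_neg.sum()),
                    "peak_observed": float(np.nanmax(bt.observed)),
                    "trough_observed": float(np.nanmin(bt.observed)),
                }
            except ParameterError as e:
                log.info("band test skipped for %s: %s", seg.condition, e)
        done("xcorr")
        _dump_json({"config_hash": chash, "conditions": band_summaries},
                   out / "band_test.json")
        done("band_test")
    except Exception:
        manifest.write(out / "manifest.json")  # partial: stays stale
        raise

    if cfg.make_plots:
        from . import plots

        plots.save_pipeline_figures(results, out)

    manifest.stale = False
    manifest.write(out / "manifest.json")
    return results


def _write_sync_h5(sync, path: Path, chash: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("times", "raw", "corrected", "surrogate_mean",
                     "surrogate_sd"):
            f.create_dataset(name, data=getattr(sync, name))
        for k, v in asdict(sync.params).items():
            f.attrs[k] = v
        f.attrs["config_hash"] = chash


def _write_waveform_csv(wave, path: Path, chash: str) -> None:
    import pandas as pd

    df = pd.DataFrame({
        "latency_s": wave.latencies,
        "mean": wave.mean,
        "se": wave.se,
    })
    df.insert(0, "config_hash", chash)
    df.to_csv(path, index=False, float_format="%.6g")
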