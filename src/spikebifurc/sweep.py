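"""Amplitude/offset sweeps, bifurcation-candidate flagging, full pipeline.

The sweep simulates an ensemble of trials at each stimulus condition,
computes the R-reliability and the spike-count mean/SD across trials, and
smooths the reliability curve with a three-point running average.
Bifurcation candidates are interior local minima of the smoothed
reliability that co-locate with a change in the rounded mean spike count:
at such points a small change in the drive produces a discrete shift in
the spike sequence, so multiple patterns coexist and the pairwise
similarity dips while the spike count steps between plateaus.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import SpikeTrainEnsemble, write_spikes_csv
from .metrics import r_reliability, vp_distance_matrix
from .neuron import NeuronParams, SimConfig, simulate_ensemble
from .stimulus import StimulusWaveform, scale_stimulus

__all__ = [
    "ScanResult",
    "trial_seed",
    "scan_amplitude",
    "scan_offset",
    "detect_bifurcation_candidates",
    "smooth3",
    "run_full_analysis",
]

log = logging.getLogger("spikebifurc")


@dataclass
class ScanResult:
    """Per-condition reliability and spike-count statistics."""

    conditions: pd.DataFrame        # columns a, b (one row per condition)
    R_raw: np.ndarray
    R_smoothed: np.ndarray
    count_mean: np.ndarray
    count_sd: np.ndarray
    bifurcation_candidates: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = self.conditions.copy()
        df["R_raw"] = self.R_raw
        df["R_smoothed"] = self.R_smoothed
        df["count_mean"] = self.count_mean
        df["count_sd"] = self.count_sd
        df["bifurcation_candidate"] = [
            i in self.bifurcation_candidates for i in range(len(df))
        ]
        return df


def smooth3(x: np.ndarray) -> np.ndarray:
    """Three-point running average; endpoints average available neighbors."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    for i in range(x.size):
        lo, hi = max(i - 1, 0), min(i + 2, x.size)
        out[i] = x[lo:hi].mean()
    return out


def trial_seed(base_seed: int, condition_index: int, trial_index: int) -> int:
    """Deterministic, collision-free per-trial seed below 2^31."""
    ss = np.random.SeedSequence([base_seed, condition_index, trial_index])
    return int(ss.generate_state(1)[0] % (2**31))


def _scan(
    params: NeuronParams,
    h: StimulusWaveform,
    conditions: list[tuple[float, float]],  # (a, b)
    nu: float,
    n_trials: int,
    lam: float,
    sigma: float,
    base_seed: int,
    dt: float = 0.05,
) -> ScanResult:
    R_raw = np.empty(len(conditions))
    cmean = np.empty(len(conditions))
    csd = np.empty(len(conditions))
    for ci, (a, b) in enumerate(conditions):
        stim = scale_stimulus(h, nu=nu, a=a, b=b)
        seeds = [trial_seed(base_seed, ci, t) for t in range(n_trials)]
        ens = simulate_ensemble(
            params, stim, n_trials,
            SimConfig(dt=dt, lam=lam),
            seed_list=seeds,
            condition={"condition_id": ci, "a": a, "b": b, "nu": nu},
        )
        counts = ens.spike_counts()
        cmean[ci] = counts.mean()
        csd[ci] = counts.std(ddof=1) if n_trials > 1 else 0.0
        if np.all(counts == 0):
            R_raw[ci] = np.nan  # no spikes: reliability undefined, flagged
        else:
            R_raw[ci] = r_reliability(ens, sigma=sigma).R
    cond = pd.DataFrame(conditions, columns=["a", "b"])
    return ScanResult(
        conditions=cond,
        R_raw=R_raw,
        R_smoothed=smooth3(R_raw),
        count_mean=cmean,
        count_sd=csd,
    )


def scan_amplitude(
    params: NeuronParams,
    h: StimulusWaveform,
    amplitudes,
    offset: float,
    n_trials: int = 25,
    lam: float = 0.00025,
    sigma: float = 1.0,
    base_seed: int = 0,
    nu: float = 1.0,
) -> ScanResult:
    """Sweep the relative amplitude b at fixed offset a.

    Defaults follow the model protocol: noise intensity lambda = 2.5e-4
    mV^2/ms and sigma = 1 ms for the reliability of model spike trains.
    """
    amplitudes = sorted(amplitudes)
    res = _scan(
        params, h, [(offset, b) for b in amplitudes], nu, n_trials, lam,
        sigma, base_seed,
    )
    if len(amplitudes) >= 3:
        res.bifurcation_candidates = detect_bifurcation_candidates(res)
    return res


def scan_offset(
    params: NeuronParams,
    h: StimulusWaveform,
    offsets,
    amplitude: float,
    n_trials: int = 25,
    lam: float = 0.00025,
    sigma: float = 1.0,
    base_seed: int = 0,
    nu: float = 1.0,
) -> ScanResult:
    """Sweep the offset a at fixed relative amplitude b."""
    offsets = sorted(offsets)
    res = _scan(
        params, h, [(a, amplitude) for a in offsets], nu, n_trials, lam,
        sigma, base_seed,
    )
    if len(offsets) >= 3:
        res.bifurcation_candidates = detect_bifurcation_candidates(res)
    return res


def detect_bifurcation_candidates(
    scan: ScanResult,
    min_depth: float = 0.02,
    require_count_step: bool = True,
    count_step_tolerance: int = 1,
) -> list[int]:
    """Interior local minima of smoothed R that co-locate with count steps.

    A candidate is a strict interior local minimum of the smoothed
    reliability, at least ``min_depth`` below the lower of its flanking
    values, whose rounded mean spike count changes within
    ``count_step_tolerance`` conditions of the dip.
    """
    R = scan.R_smoothed
    n = R.size
    if n < 3:
        raise ValueError("need at least three conditions")
    rounded = np.round(scan.count_mean).astype(int)
    steps = np.flatnonzero(np.diff(rounded) != 0)  # step between i and i+1
    out = []
    for i in range(1, n - 1):
        if np.isnan(R[i - 1]) or np.isnan(R[i]) or np.isnan(R[i + 1]):
            continue
        if not (R[i] < R[i - 1] and R[i] < R[i + 1]):
            continue
        if min(R[i - 1], R[i + 1]) - R[i] < min_depth:
            continue
        if require_count_step:
            if not np.any(np.abs(steps - i) <= count_step_tolerance) and not np.any(
                np.abs(steps + 1 - i) <= count_step_tolerance
            ):
                continue
        out.append(i)
    return out


# -- full pipeline ----------------------------------------------------------


def run_full_analysis(config: dict, out_dir) -> dict:
    """Run the configured pipeline end to end and write all artifacts.

    ``config`` mirrors the CLI configuration file: a ``source`` section
    (``simulate`` with stimulus/neuron/noise settings, or ``synthetic``
    with pattern specs), an ``analysis`` section (q, t_ISI, t_ROC, sigma,
    k_max, segment length) and optional ``scan``/``reconstruct``
    sections.  Artifacts (CSV tables and a JSON manifest) are written to
    ``out_dir``; the manifest records stage timings.
    """
    from . import patterns as pat
    from .info import class_distribution, entropy
    from .metrics import spike_triggered_average
    from .reconstruct import event_based_reconstruction, reconstruction_quality
    from .stimulus import generate_fm_waveform, generate_frozen_noise

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "config": config}
    t_all = time.time()

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append({"name": name, "t_start": time.time() - t_all})

    try:
        stage("source")
        src = config.get("source", {})
        kind = src.get("kind", "synthetic")
        stimulus = None
        if kind == "simulate":
            stim_cfg = src.get("stimulus", {})
            if stim_cfg.get("kind", "frozen_noise") == "fm":
                h = generate_fm_waveform(
                    [tuple(s) for s in stim_cfg["segments"]],
                    fs=stim_cfg.get("fs", 10000.0),
                    amplitude=stim_cfg.get("amplitude", 1.0),
                )
            else:
                h = generate_frozen_noise(
                    seed=stim_cfg.get("seed", 0),
                    n_keep=stim_cfg.get("n_keep", 10500),
                    fs=stim_cfg.get("fs", 10000.0),
                )
            stimulus = scale_stimulus(
                h, nu=src.get("nu", 1.0), a=src.get("a", 0.2), b=src.get("b", 0.5)
            )
            params = NeuronParams(**src.get("neuron", {}))
            ens = simulate_ensemble(
                params,
                stimulus,
                src.get("n_trials", 25),
                SimConfig(lam=src.get("lam", 0.00025), seed=src.get("seed", 0)),
                seed_list=[
                    trial_seed(src.get("seed", 0), 0, t)
                    for t in range(src.get("n_trials", 25))
                ],
            )
        elif kind == "synthetic":
            from .synth import PatternSpec, generate_pattern_ensemble

            specs = [PatternSpec(**s) for s in src["patterns"]]
            ens, truth = generate_pattern_ensemble(
                specs,
                n_trials=src.get("n_trials", 60),
                noise_rate=src.get("noise_rate", 0.0),
                duration=src.get("duration", 1000.0),
                seed=src.get("seed", 0),
            )
        else:
            raise ValueError(f"unknown source kind {kind!r}")
        write_spikes_csv(out / "spikes.csv", ens)

        ana = config.get("analysis", {})
        q = ana.get("q", 0.5)
        stage("clustering")
        D = vp_distance_matrix(ens, q)
        k = ana.get("N_c") or pat.select_n_clusters(
            D, k_max=ana.get("k_max", 6), seed=ana.get("seed", 0)
        )
        assign = pat.fcm_cluster(D, k, seed=ana.get("seed", 0))
        pd.DataFrame(
            {"trial": np.arange(ens.n_trials), "pattern": assign.labels}
        ).to_csv(out / "labels.csv", index=False)

        stage("events")
        events = pat.find_events(
            ens, assign, t_isi=ana.get("t_ISI", 3.0), t_roc=ana.get("t_ROC", 0.5)
        )
        stats = pat.event_statistics(events) if events.events else pd.DataFrame()
        stats.to_csv(out / "events.csv", index=False)
        occ = pat.pattern_occupation(assign, ens.condition_ids)
        occ.to_csv(out / "occupation.csv", index=False)

        stage("information")
        p = class_distribution(assign.labels)
        manifest["pattern_entropy_bits"] = entropy(p)

        if stimulus is not None and events.events:
            stage("reconstruction")
            sta = spike_triggered_average(ens, stimulus)
            recon = event_based_reconstruction(events, sta, ens.duration)
            manifest["reconstruction_r"] = reconstruction_quality(recon, stimulus)
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        failed = manifest["stages"][-1]["name"] if manifest["stages"] else "init"
        log.error("pipeline failed in stage %s: %s", failed, exc)
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    manifest["elapsed_s"] = time.time() - t_all
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
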