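"""Synthetic spike-train ensembles with known pattern/event structure.

Each trial expresses one of a set of spike patterns; a pattern is a list
of events with a mean time, a Gaussian jitter SD and a reliability (the
probability that a trial expressing the pattern contributes a spike to the
event).  Homogeneous Poisson contaminant spikes model unassigned "noise"
spikes.  Because the generator records which pattern each trial expressed
and which event produced each spike, every stage of the event-finding
pipeline can be tested against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import SpikeTrainEnsemble

__all__ = ["PatternSpec", "GroundTruth", "generate_pattern_ensemble"]


@dataclass
class PatternSpec:
    """Ground-truth description of one spike pattern.

    ``occupation`` is the probability that a trial expresses this pattern;
    occupations across the spec list must sum to 1.
    """

    event_times: list[float]
    event_reliabilities: list[float]
    event_jitters: list[float]
    occupation: float

    def __post_init__(self) -> None:
        n = len(self.event_times)
        if len(self.event_reliabilities) != n or len(self.event_jitters) != n:
            raise ValueError("event lists must have equal length")
        if any(j < 0 for j in self.event_jitters):
            raise ValueError("jitters must be non-negative")
        if not all(0.0 <= r <= 1.0 for r in self.event_reliabilities):
            raise ValueError("reliabilities must be in [0, 1]")


@dataclass
class GroundTruth:
    """True per-trial pattern labels and per-spike event provenance."""

    pattern_labels: np.ndarray  # per trial, index into specs
    spike_events: pd.DataFrame  # trial, t_ms, pattern, event (-1 = noise)


def generate_pattern_ensemble(
    specs: list[PatternSpec],
    n_trials: int,
    noise_rate: float = 0.0,
    duration: float = 1000.0,
    seed: int = 0,
):
    """Draw an ensemble of trials from the given pattern specs.

    Each trial picks a pattern according to the occupations, emits each of
    that pattern's events with probability equal to its reliability at a
    time ~ Normal(event_time, jitter) (truncated to the trial window), and
    adds Poisson contaminant spikes at ``noise_rate`` Hz.

    Returns ``(SpikeTrainEnsemble, GroundTruth)``.
    """
    occ = np.array([s.occupation for s in specs], dtype=float)
    if abs(occ.sum() - 1.0) > 1e-9:
        raise ValueError("occupations must sum to 1")
    for s in specs:
        hi = max(
            (t + 5 * j for t, j in zip(s.event_times, s.event_jitters)),
            default=0.0,
        )
        if hi > duration:
            raise ValueError("duration must cover all event times +/- 5 jitters")
        order = np.argsort(s.event_times)
        times = np.asarray(s.event_times, dtype=float)[order]
        jit = np.asarray(s.event_jitters, dtype=float)[order]
        gaps = np.diff(times)
        if gaps.size and np.any(gaps < np.maximum(jit[:-1], jit[1:])):
            warnings.warn("events closer than one jitter: ambiguous by construction")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(specs), size=n_trials, p=occ)
    trains, rows = [], []
    for trial, lab in enumerate(labels):
        spec = specs[lab]
        spikes = []
        for ev, (t, r, j) in enumerate(
            zip(spec.event_times, spec.event_reliabilities, spec.event_jitters)
        ):
            if rng.uniform() < r:
                s = rng.normal(t, j) if j > 0 else t
                s = min(max(s, 0.0), np.nextafter(duration, 0.0))
                spikes.append(s)
                rows.append((trial, s, int(lab), ev))
        if noise_rate > 0:
            n_noise = rng.poisson(noise_rate * duration / 1000.0)
            for s in rng.uniform(0.0, duration, size=n_noise):
                spikes.append(s)
                rows.append((trial, s, int(lab), -1))
        trains.append(np.sort(spikes))
    conditions = pd.DataFrame(
        {"condition_id": np.zeros(n_trials, dtype=int), "true_pattern": labels}
    )
    ens = SpikeTrainEnsemble(trains, duration=duration, conditions=conditions)
    truth = GroundTruth(
        pattern_labels=labels,
        spike_events=pd.DataFrame(rows, columns=["trial", "t_ms", "pattern", "event"]),
    )
    return ens, truth
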