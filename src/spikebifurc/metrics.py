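"""Spike-train metrics: similarity, R-reliability, VP distance, PSTH, STA.

The R-reliability (Schreiber measure) smooths each train with a Gaussian
of width sigma and averages the cosine similarity over all distinct trial
pairs.  The cosine between two smoothed trains is computed analytically:
the inner product of two unit-area Gaussians centered at spike times t and
s is proportional to exp(-(t-s)^2 / (4 sigma^2)), so no waveform is ever
materialized.  The Victor-Purpura distance is the minimum-cost edit
distance with insertion/deletion cost 1 and shift cost q per ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import SpikeTrainEnsemble
from .stimulus import StimulusWaveform

__all__ = [
    "DistanceMatrix",
    "ReliabilityResult",
    "similarity_pair",
    "r_reliability",
    "vp_distance",
    "vp_distance_matrix",
    "psth",
    "firing_rate",
    "spike_triggered_average",
]


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise VP distances at cost parameter q."""

    d: np.ndarray
    q: float
    trial_ids: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)


@dataclass
class ReliabilityResult:
    R: float
    sigma: float
    S_ij: np.ndarray  # condensed upper-triangle pair similarities


def _gauss_inner(a: np.ndarray, b: np.ndarray, sigma: float, cutoff: bool) -> float:
    """Sum of exp(-(t-s)^2/(4 sigma^2)) over spike pairs (t in a, s in b)."""
    if a.size == 0 or b.size == 0:
        return 0.0
    dt = a[:, None] - b[None, :]
    if cutoff:
        dt = dt[np.abs(dt) < 6.0 * sigma]
    if dt.size == 0:
        return 0.0
    return float(np.sum(np.exp(-(dt**2) / (4.0 * sigma**2))))


def similarity_pair(
    train_a, train_b, sigma: float, cutoff: bool = True
) -> float:
    """Cosine similarity of two Gaussian-smoothed spike trains, in [0, 1].

    Spike pairs separated by more than six sigma are skipped when
    ``cutoff`` is set (their contribution is below exp(-9) ~ 1e-4 of a
    coincident pair).  By convention the similarity is 0 if either train
    is empty.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = np.asarray(train_a, dtype=float)
    b = np.asarray(train_b, dtype=float)
    if a.size == 0 or b.size == 0:
        return 0.0
    num = _gauss_inner(a, b, sigma, cutoff)
    den = np.sqrt(_gauss_inner(a, a, sigma, cutoff) * _gauss_inner(b, b, sigma, cutoff))
    if den == 0.0:
        return 0.0
    return min(num / den, 1.0)


def r_reliability(
    ensemble: SpikeTrainEnsemble | list, sigma: float = 3.0, cutoff: bool = True
) -> ReliabilityResult:
    """Mean pairwise similarity across all distinct trial pairs.

    sigma (ms) sets the timescale below which two spikes count as
    coincident; sigma -> 0 gives R = 0 for non-identical trains and
    sigma much larger than the trial length gives R = 1.
    """
    trains = ensemble.trains if isinstance(ensemble, SpikeTrainEnsemble) else [
        np.asarray(t, dtype=float) for t in ensemble
    ]
    n = len(trains)
    if n < 2:
        raise ValueError("need at least two trials")
    sims = []
    for i in range(n):
        for j in range(i + 1, n):
            sims.append(similarity_pair(trains[i], trains[j], sigma, cutoff))
    S = np.array(sims)
    return ReliabilityResult(R=float(S.mean()), sigma=sigma, S_ij=S)


# -- Victor-Purpura ---------------------------------------------------------


def vp_distance(train_a, train_b, q: float) -> float:
    """Victor-Purpura edit distance between two spike trains.

    Dynamic program over the sorted trains: deleting or inserting a spike
    costs 1, shifting a spike by Delta-t costs q*|Delta-t|.  q = 0 reduces
    to the spike-count difference; large q approaches counting
    non-coincident spikes.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    a = np.sort(np.asarray(train_a, dtype=float))
    b = np.sort(np.asarray(train_b, dtype=float))
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        return float(na + nb)
    # G[i, j]: distance between a[:i] and b[:j]
    prev = np.arange(nb + 1, dtype=float)
    for i in range(1, na + 1):
        cur = np.empty(nb + 1)
        cur[0] = i
        for j in range(1, nb + 1):
            cur[j] = min(
                prev[j] + 1.0,
                cur[j - 1] + 1.0,
                prev[j - 1] + q * abs(a[i - 1] - b[j - 1]),
            )
        prev = cur
    return float(prev[nb])


def vp_distance_matrix(ensemble: SpikeTrainEnsemble, q: float) -> DistanceMatrix:
    """Pairwise VP distances between all trials of an ensemble."""
    trains = ensemble.trains
    n = len(trains)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = vp_distance(trains[i], trains[j], q)
    return DistanceMatrix(d=d, q=q, trial_ids=np.arange(n))


# -- rate descriptions ------------------------------------------------------


def psth(
    ensemble: SpikeTrainEnsemble,
    bin_width: float = 0.5,
    smooth_sd_bins: float = 4.0,
):
    """Peristimulus time histogram in Hz, Gaussian-smoothed.

    Spikes are counted in half-open bins [t, t + bin_width), normalized by
    trial count and bin width in seconds, then smoothed with a Gaussian
    kernel of SD ``smooth_sd_bins`` bins (truncated at +/-4 SD, kernel
    renormalized at the edges so flat regions stay flat).

    Returns (bin_centers_ms, rate_hz).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(ensemble.duration / bin_width))
    edges = ensemble.t0 + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for train in ensemble.trains:
        idx = np.floor((train - ensemble.t0) / bin_width).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1.0)
    rate = counts / (ensemble.n_trials * bin_width / 1000.0)
    if smooth_sd_bins > 0:
        half = int(np.ceil(4 * smooth_sd_bins))
        x = np.arange(-half, half + 1)
        kern = np.exp(-(x**2) / (2.0 * smooth_sd_bins**2))
        kern /= kern.sum()
        # truncated kernel with per-point renormalization at the edges
        num = np.convolve(rate, kern, mode="same")
        den = np.convolve(np.ones_like(rate), kern, mode="same")
        rate = num / den
    centers = edges[:-1] + bin_width / 2.0
    return centers, rate


def firing_rate(ensemble: SpikeTrainEnsemble):
    """Mean and sample SD (over trials) of per-trial rate in Hz."""
    dur_s = ensemble.duration / 1000.0
    rates = ensemble.spike_counts() / dur_s
    sd = float(rates.std(ddof=1)) if rates.size > 1 else 0.0
    return float(rates.mean()), sd


def spike_triggered_average(
    ensemble: SpikeTrainEnsemble,
    stimulus: StimulusWaveform,
    window_ms: float = 25.0,
) -> StimulusWaveform:
    """Average stimulus segment in the ``window_ms`` preceding each spike.

    Spikes with less than ``window_ms`` of stimulus history are excluded.
    Returns a waveform on the stimulus grid with lag axis [-window, 0] ms
    (t0 = -window_ms).
    """
    n_lag = int(round(window_ms / stimulus.dt))
    acc = np.zeros(n_lag + 1)
    count = 0
    for train in ensemble.trains:
        for t in train:
            k = int(round((t - stimulus.t0) / stimulus.dt))
            if k - n_lag < 0 or k >= stimulus.n:
                continue
            acc += stimulus.samples[k - n_lag : k + 1]
            count += 1
    if count == 0:
        raise ValueError("no spikes with sufficient stimulus history")
    return StimulusWaveform(acc / count, dt=stimulus.dt, t0=-window_ms)
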