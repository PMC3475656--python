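"""Frozen-noise and frequency-modulated stimulus waveforms.

The injected current used throughout the package is built from a fixed
("frozen") aperiodic waveform ``h(t)`` that is normalized to zero mean and
unit variance, then scaled as ``I(t) = nu * (a + b * h(t))`` where ``a`` is
the relative DC offset, ``b`` the relative fluctuation amplitude and ``nu``
an overall gain.  A frequency-modulated sinusoid with piecewise-constant
instantaneous frequency is provided for reconstruction experiments, where a
drive made of discrete, equal-amplitude upswings is easier to interpret.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusWaveform",
    "generate_frozen_noise",
    "lowpass_then_boxcar",
    "scale_stimulus",
    "generate_fm_waveform",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_waveform_npz",
    "write_waveform_npz",
]


@dataclass
class StimulusWaveform:
    """A uniformly sampled current trace.

    Parameters
    ----------
    samples : ndarray
        Current values.  Dimensionless for an unscaled frozen-noise
        waveform; physical units (e.g. uA/cm^2) after scaling.
    dt : float
        Sample interval in ms.
    t0 : float
        Time of the first sample in ms.
    """

    samples: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Total covered time in ms."""
        return self.n * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def value_at(self, t: float | np.ndarray) -> np.ndarray:
        """Zero-order-hold lookup of the waveform at time(s) ``t`` (ms).

        A small epsilon guards the floor against float error at exact
        grid points.
        """
        raw = (np.asarray(t) - self.t0) / self.dt + 1e-9
        idx = np.clip(np.floor(raw).astype(int), 0, self.n - 1)
        return self.samples[idx]


# -- frozen noise -----------------------------------------------------------

#: First-order recursive low-pass coefficient; corner frequency ~100 Hz at
#: a 10 kHz sampling rate for y[n] = x[n] + 0.99 y[n-1].
_LOWPASS_POLE = 0.99
#: Length of the causal running average (5 ms at 10 kHz).
_BOXCAR_LEN = 50
#: Leading transient samples discarded after filtering (50 ms at 10 kHz).
_DISCARD = 500


def lowpass_then_boxcar(x: np.ndarray) -> np.ndarray:
    """Apply the two-stage smoothing used to build the frozen waveform.

    Stage 1 is the causal direct-form recursion ``y[n] = x[n] + 0.99 y[n-1]``
    with zero initial state; stage 2 is a causal 50-sample running average.
    Exposed separately as a test hook.
    """
    from scipy.signal import lfilter

    y = lfilter([1.0], [1.0, -_LOWPASS_POLE], np.asarray(x, dtype=float))
    return lfilter(np.full(_BOXCAR_LEN, 1.0 / _BOXCAR_LEN), [1.0], y)


def normalize_waveform(x: np.ndarray) -> np.ndarray:
    """Center on zero and divide by the population standard deviation."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    sd = np.sqrt(np.mean(x**2))
    if sd == 0:
        raise ValueError("cannot normalize a zero-variance waveform")
    return x / sd


def generate_frozen_noise(
    seed: int, n_keep: int = 10000, fs: float = 10000.0
) -> StimulusWaveform:
    """Generate the normalized frozen-noise waveform ``h(t)``.

    Uniform white noise on [0, 1] is low-pass filtered (recursive filter
    with pole 0.99, i.e. ~100 Hz corner at 10 kHz), smoothed by a 50-sample
    running average, the first 500 transient samples are discarded, and the
    remainder is normalized to zero mean and unit (population) variance.

    Parameters
    ----------
    seed : int
        PRNG seed; the same seed reproduces the waveform bit-for-bit.
    n_keep : int
        Number of samples retained after the transient discard.
    fs : float
        Sampling rate in Hz (default 10 kHz, i.e. dt = 0.1 ms).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_keep < 1:
        raise ValueError("n_keep must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=n_keep + _DISCARD)
    y = lowpass_then_boxcar(x)[_DISCARD:]
    if y.size < n_keep:
        raise ValueError(
            f"requested {n_keep} samples but only {y.size} remain after discard"
        )
    h = normalize_waveform(y[:n_keep])
    return StimulusWaveform(h, dt=1000.0 / fs)


def scale_stimulus(
    h: StimulusWaveform, nu: float, a: float, b: float
) -> StimulusWaveform:
    """Scale a normalized waveform into an injected current.

    Returns ``I`` with samples ``nu * (a + b * h)``, so the mean current is
    ``nu * a`` and its standard deviation ``nu * |b|``.
    """
    for name, v in (("nu", nu), ("a", a), ("b", b)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    return StimulusWaveform(nu * (a + b * h.samples), dt=h.dt, t0=h.t0)


# -- frequency-modulated drive ----------------------------------------------


def generate_fm_waveform(
    segment_frequencies: list[tuple[float, float]],
    fs: float = 10000.0,
    amplitude: float = 1.0,
) -> StimulusWaveform:
    """Sinusoid with piecewise-constant instantaneous frequency.

    ``segment_frequencies`` is a list of ``(duration_ms, frequency_Hz)``
    pairs.  The phase is continuous across segment boundaries, so every
    upswing reaches the same peak ``amplitude`` while intervals and slopes
    between upswings vary with the local frequency.
    """
    if not segment_frequencies:
        raise ValueError("segment list must not be empty")
    if fs <= 0:
        raise ValueError("fs must be positive")
    dt = 1000.0 / fs
    freq = []
    for dur, f in segment_frequencies:
        if dur <= 0 or f <= 0:
            raise ValueError("durations and frequencies must be positive")
        freq.append(np.full(int(round(dur / dt)), f))
    f_inst = np.concatenate(freq)  # Hz, per sample
    # phase(t) = 2*pi * integral f dt'; cumulative sum keeps it continuous
    phase = 2.0 * np.pi * np.cumsum(f_inst) * (dt / 1000.0)
    return StimulusWaveform(amplitude * np.sin(phase), dt=dt)


# -- I/O ---------------------------------------------------------------------


def write_waveform_csv(path, wave: StimulusWaveform) -> None:
    """Write a two-column (t_ms, value) CSV."""
    import pandas as pd

    pd.DataFrame({"t_ms": wave.times, "value": wave.samples}).to_csv(
        path, index=False
    )


def read_waveform_csv(path) -> StimulusWaveform:
    import pandas as pd

    df = pd.read_csv(path)
    t = df["t_ms"].to_numpy()
    if len(t) < 2:
        raise ValueError("waveform CSV needs at least two samples")
    dt = float(t[1] - t[0])
    return StimulusWaveform(df["value"].to_numpy(), dt=dt, t0=float(t[0]))


def write_waveform_npz(path, wave: StimulusWaveform) -> None:
    np.savez(path, samples=wave.samples, dt=wave.dt, t0=wave.t0)


def read_waveform_npz(path) -> StimulusWaveform:
    with np.load(path) as z:
        return StimulusWaveform(z["samples"], dt=float(z["dt"]), t0=float(z["t0"]))
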