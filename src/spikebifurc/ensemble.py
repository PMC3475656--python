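"""Spike-train ensemble container and CSV I/O.

An ensemble holds one spike-time list per trial (ms, sorted) together with
a per-trial condition record (relative offset ``a``, relative amplitude
``b``, gain ``nu``, noise intensity ``lam``, seed).  Trials recorded under
several stimulus conditions live in a single ensemble and are selected by
condition id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpikeTrainEnsemble", "read_spikes_csv", "write_spikes_csv"]


@dataclass
class SpikeTrainEnsemble:
    """Ordered spike-time lists per trial with condition tags.

    Parameters
    ----------
    trains : list of ndarray
        Spike times in ms, one sorted array per trial.
    duration : float
        Trial length in ms.
    conditions : DataFrame, optional
        One row per trial; columns are free-form condition tags
        (``condition_id``, ``a``, ``b``, ``nu``, ``lam``, ``seed`` by
        convention).  Defaults to a single condition 0 for every trial.
    t0 : float
        Trial start time in ms.
    """

    trains: list[np.ndarray]
    duration: float
    conditions: pd.DataFrame | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.trains = [np.sort(np.asarray(t, dtype=float).ravel()) for t in self.trains]
        if self.conditions is None:
            self.conditions = pd.DataFrame({"condition_id": np.zeros(len(self.trains), dtype=int)})
        self.conditions = self.conditions.reset_index(drop=True)
        if len(self.conditions) != len(self.trains):
            raise ValueError("conditions must have one row per trial")

    @property
    def n_trials(self) -> int:
        return len(self.trains)

    @property
    def condition_ids(self) -> np.ndarray:
        return self.conditions["condition_id"].to_numpy()

    def spike_counts(self) -> np.ndarray:
        return np.array([t.size for t in self.trains])

    def select(self, condition_ids) -> "SpikeTrainEnsemble":
        """Sub-ensemble of the trials whose condition id is in the given set."""
        wanted = set(np.atleast_1d(condition_ids).tolist())
        mask = [cid in wanted for cid in self.condition_ids]
        return self.subset(np.flatnonzero(mask))

    def subset(self, trial_indices) -> "SpikeTrainEnsemble":
        idx = np.atleast_1d(trial_indices)
        return SpikeTrainEnsemble(
            [self.trains[i] for i in idx],
            duration=self.duration,
            conditions=self.conditions.iloc[idx],
            t0=self.t0,
        )

    def window(self, t_start: float, t_end: float) -> "SpikeTrainEnsemble":
        """Restrict every train to the half-open window [t_start, t_end)."""
        trains = [t[(t >= t_start) & (t < t_end)] for t in self.trains]
        return SpikeTrainEnsemble(
            trains, duration=t_end - t_start, conditions=self.conditions, t0=t_start
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, train in enumerate(self.trains):
            cid = int(self.condition_ids[i])
            for t in train:
                rows.append((i, cid, t))
        return pd.DataFrame(rows, columns=["trial", "condition_id", "t_ms"])


def write_spikes_csv(path, ensemble: SpikeTrainEnsemble) -> None:
    """Write one row per spike: trial, condition_id, t_ms."""
    ensemble.to_frame().to_csv(path, index=False)


def read_spikes_csv(path, duration: float, n_trials: int | None = None) -> SpikeTrainEnsemble:
    """Read a (trial, condition_id, t_ms) CSV into an ensemble.

    ``n_trials`` allows trailing silent trials that contribute no rows.
    """
    df = pd.read_csv(path)
    n = int(df["trial"].max()) + 1 if len(df) else 0
    if n_trials is not None:
        n = max(n, n_trials)
    trains = [df.loc[df["trial"] == i, "t_ms"].to_numpy() for i in range(n)]
    cids = np.zeros(n, dtype=int)
    for i in range(n):
        sub = df.loc[df["trial"] == i, "condition_id"]
        if len(sub):
            cids[i] = int(sub.iloc[0])
    return SpikeTrainEnsemble(
        trains, duration=duration, conditions=pd.DataFrame({"condition_id": cids})
    )
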