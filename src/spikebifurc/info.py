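"""Entropy and mutual information of trial classifications.

A classification assigns each trial to one of N_c classes (e.g. the spike
pattern it expressed).  Diversity is the plug-in entropy of the class
distribution in bits; resampling the distribution at the observed trial
count gives the bias and standard deviation of the estimate.  The
normalized mutual information between two classifications divides the
plug-in MI by the larger of the two entropies, so identical
classifications score exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Classification",
    "class_distribution",
    "entropy",
    "entropy_resample",
    "mutual_information",
    "normalized_mi",
]


@dataclass
class Classification:
    """Per-trial class labels (0-based) with a fixed class count."""

    labels: np.ndarray
    N_c: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size < 1:
            raise ValueError("need at least one trial")
        if self.labels.min() < 0 or self.labels.max() >= self.N_c:
            raise ValueError("labels out of range")


def _as_classification(c) -> Classification:
    if isinstance(c, Classification):
        return c
    labels = np.asarray(c, dtype=int)
    return Classification(labels, int(labels.max()) + 1)


def class_distribution(c) -> np.ndarray:
    """Fraction of trials in each class (may contain zeros)."""
    c = _as_classification(c)
    return np.bincount(c.labels, minlength=c.N_c) / c.labels.size


def entropy(p) -> float:
    """Shannon entropy -sum p log2 p in bits; 0 log 0 taken as 0."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def entropy_resample(
    p, n_trials: int, n_resamples: int = 1000, seed: int = 0
):
    """Bias and SD of the plug-in entropy at a finite trial count.

    Treating ``p`` as exact, ``n_resamples`` multinomial data sets of
    ``n_trials`` trials are drawn; bias is the mean resampled entropy
    minus the entropy of ``p`` (negative for the plug-in estimator), and
    std is the SD across resamples.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    p = np.asarray(p, dtype=float)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_trials, p, size=n_resamples)
    s = np.array([entropy(c / n_trials) for c in counts])
    return float(s.mean() - entropy(p)), float(s.std(ddof=0))


def _joint(c: Classification, d: Classification) -> np.ndarray:
    if c.labels.size != d.labels.size:
        raise ValueError("classifications must have the same trial count")
    joint = np.zeros((c.N_c, d.N_c))
    np.add.at(joint, (c.labels, d.labels), 1.0)
    return joint / c.labels.size


def mutual_information(c, d) -> float:
    """Plug-in mutual information between two classifications, bits."""
    c, d = _as_classification(c), _as_classification(d)
    p = _joint(c, d)
    pc = p.sum(axis=1)
    pd_ = p.sum(axis=0)
    mask = p > 0
    return float(
        np.sum(p[mask] * np.log2(p[mask] / np.outer(pc, pd_)[mask]))
    )


def normalized_mi(c, d) -> float:
    """Mutual information divided by max(S(c), S(d)); in [0, 1].

    Identical classifications give exactly 1.  If both entropies vanish
    (single-class degenerate case) the value is 1 when the labels agree
    and 0 otherwise.
    """
    c, d = _as_classification(c), _as_classification(d)
    sc = entropy(class_distribution(c))
    sd = entropy(class_distribution(d))
    denom = max(sc, sd)
    if denom == 0.0:
        return 1.0 if np.array_equal(c.labels, d.labels) else 0.0
    return mutual_information(c, d) / denom
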