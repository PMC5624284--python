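"""Seed-substream derivation and small shared numerics."""
from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for a named substream of a master seed.

    The stream index is derived by hashing ``name``, so adding or removing one
    consumer of randomness never shifts the draws of another.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    idx = int.from_bytes(digest[:4], "little")
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, idx])


def derived_seed(seed: int, name: str) -> int:
    """A deterministic integer seed (< 2**31) for a named substream."""
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return (int(seed) ^ int.from_bytes(digest[:4], "little")) & 0x7FFFFFFF


def match_labels(truth, predicted):
    """Best agreement rate between two label vectors, up to label permutation.

    Solved as a linear assignment on the confusion matrix.
    """
    from scipy.optimize import linear_sum_assignment

    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    t_levels = np.unique(truth)
    p_levels = np.unique(predicted)
    conf = np.zeros((len(t_levels), len(p_levels)))
    for i, t in enumerate(t_levels):
        for j, p in enumerate(p_levels):
            conf[i, j] = np.sum((truth == t) & (predicted == p))
    rows, cols = linear_sum_assignment(-conf)
    return conf[rows, cols].sum() / truth.size
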