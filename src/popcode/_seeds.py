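"""Deterministic hierarchical seed derivation.

Every source of randomness in the package draws from a Generator obtained via
:func:`child_rng`, keyed by a master seed plus a tuple of small integers that
identify the consumer (stream id, class index, density, condition, trial, ...).
This makes results reproducible regardless of execution order and lets
different pipeline cells share draws intentionally (e.g. stimulus traces are
shared across afferent classes).
"""

from __future__ import annotations

import numpy as np

# Stream identifiers; keep stable, they are part of the reproducibility contract.
STREAM_PLACEMENT = 1
STREAM_STIMULUS = 2
STREAM_NEURAL = 3
STREAM_SPLIT = 4
STREAM_NMF = 5
STREAM_DECODER = 6
STREAM_PERTURB = 7

_CLASS_INDEX = {"SA1": 0, "RA": 1, "PC": 2}


def class_index(label: str) -> int:
    """Stable small-integer id for an afferent class label."""
    try:
        return _CLASS_INDEX[label]
    except KeyError:
        # unknown labels (e.g. in tests) get a stable hash-free fallback
        return 10 + sum(ord(c) for c in label) % 1000


def density_key(density: float) -> int:
    """Quantize a density (afferents/cm^2) to a stable integer key."""
    return int(round(float(density) * 1000))


def child_seed_sequence(master_seed: int, *keys: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master_seed)] + [int(k) for k in keys])


def child_rng(master_seed: int, *keys: int) -> np.random.Generator:
    """Generator derived deterministically from ``master_seed`` and ``keys``."""
    return np.random.default_rng(child_seed_sequence(master_seed, *keys))


def child_int_seed(master_seed: int, *keys: int) -> int:
    """A plain integer seed (< 2**31) for libraries that take ``random_state``."""
    return int(child_seed_sequence(master_seed, *keys).generate_state(1)[0] % (2**31 - 1))
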