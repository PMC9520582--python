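"""Deterministic sub-seed derivation from a single master seed.

Every stochastic stage of the pipeline receives its own named stream so that
subsample b, imputation chain m and classifier fold all reproduce bit-for-bit
from one integer, and parallel execution (if any) matches sequential results.
"""

from __future__ import annotations

import numpy as np

_MAX_SEED = 2**31 - 1


def derive_seed(master: int, *path: int) -> int:
    """Derive a child integer seed from ``master`` and a tuple of indices.

    Uses :class:`numpy.random.SeedSequence` keyed on the full path, so
    (master, b) and (master, b, j) give independent, reproducible streams.
    The result is kept below 2**31 for portability.
    """
    ss = np.random.SeedSequence([int(master)] + [int(p) for p in path])
    return int(ss.generate_state(1)[0] % _MAX_SEED)


def rng_from(master: int, *path: int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` on the stream named by ``path``."""
    return np.random.default_rng(np.random.SeedSequence([int(master)] + [int(p) for p in path]))
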