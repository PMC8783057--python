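"""Deterministic seed fan-out.

Every stochastic operation in the package takes an explicit integer seed.
Sub-streams (per molecule, per restart, per bootstrap) are derived through
:func:`rng_for`, which hashes ``(seed, *keys)`` through a
``numpy.random.SeedSequence`` so that streams are independent and the whole
pipeline is bit-reproducible from a single master seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_for"]


def rng_for(seed: int, *keys: int) -> np.random.Generator:
    """Return a Generator for the stream identified by ``(seed, *keys)``."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, keys))))
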