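"""Deterministic seed derivation.

All randomness in a run flows from one master seed; sub-seeds for individual
simulations, oracle calls and variance evaluations are derived through
``numpy.random.SeedSequence`` so that runs are bit-reproducible and
sub-streams are statistically independent.
"""

from __future__ import annotations

import numpy as np


def child_seed(seed: int, *keys: int) -> int:
    """Derive a 64-bit child seed from ``seed`` and an integer key path."""
    entropy = [int(seed) & 0xFFFFFFFFFFFFFFFF] + [int(k) & 0xFFFFFFFFFFFFFFFF for k in keys]
    return int(np.random.SeedSequence(entropy).generate_state(2, np.uint32).view(np.uint64)[0])
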