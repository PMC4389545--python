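"""Deterministic seed derivation from a root seed.

Every source of randomness in the package derives its generator from a root
seed plus a stable string context, so full runs reproduce bit-for-bit.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(root_seed: int, *context: object) -> int:
    """Stable 63-bit seed from a root seed and arbitrary context tokens."""
    h = hashlib.sha256()
    h.update(str(int(root_seed)).encode())
    for token in context:
        h.update(b"\x00")
        h.update(str(token).encode())
    return int.from_bytes(h.digest()[:8], "little") & (2**63 - 1)


def derived_rng(root_seed: int, *context: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root_seed, *context))
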