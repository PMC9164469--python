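"""Deterministic derivation of named RNG substreams.

Every stochastic component of a run draws from a substream derived from
(root seed, *string/number keys), so that e.g. the perturbed dataset fed
to two classifier families at the same sweep level is bit-identical.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed_sequence", "derive_rng", "derive_int"]


def _key_to_int(key: object) -> int:
    """Map an arbitrary key to a stable 64-bit integer."""
    if isinstance(key, (int, np.integer)) and not isinstance(key, bool):
        return int(key) & 0xFFFFFFFFFFFFFFFF
    digest = hashlib.sha256(repr(key).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def derive_seed_sequence(root_seed: int, *keys: object) -> np.random.SeedSequence:
    """Build a SeedSequence from a root seed plus a tuple of named keys."""
    entropy = [int(root_seed) & 0xFFFFFFFFFFFFFFFF]
    entropy.extend(_key_to_int(k) for k in keys)
    return np.random.SeedSequence(entropy)


def derive_rng(root_seed: int, *keys: object) -> np.random.Generator:
    """A Generator seeded from the derived substream."""
    return np.random.default_rng(derive_seed_sequence(root_seed, *keys))


def derive_int(root_seed: int, *keys: object) -> int:
    """A deterministic 32-bit integer seed (for libraries wanting an int)."""
    return int(derive_seed_sequence(root_seed, *keys).generate_state(1)[0])
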