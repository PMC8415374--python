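"""Named random substreams derived from a single root seed.

Every stochastic component of the package draws from its own named
substream so that any component can be regenerated independently and the
whole pipeline is bit-reproducible under one root seed.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_seed"]


def substream_seed(root_seed: int, name: str) -> int:
    """Derive a deterministic 31-bit seed for the named substream."""
    if root_seed < 0:
        raise ValueError("root seed must be nonnegative")
    digest = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Return a Generator seeded from ``root_seed`` and a component name."""
    return np.random.default_rng(substream_seed(root_seed, name))
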