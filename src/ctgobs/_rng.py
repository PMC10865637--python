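"""Keyed random streams.

Every stochastic draw in the package comes from a generator keyed by a
(seed, *entity ids) tuple hashed through BLAKE2b. Streams for distinct keys
are independent, and a stream depends only on its own key — adding a rater,
or reordering calls, never perturbs the draws for existing entities.
"""

from __future__ import annotations

import hashlib

import numpy as np

_SEP = b"\x1f"


def keyed_rng(*keys: object) -> np.random.Generator:
    """A ``numpy.random.Generator`` deterministically derived from ``keys``."""
    payload = _SEP.join(str(k).encode("utf-8") for k in keys)
    digest = hashlib.blake2b(payload, digest_size=16).digest()
    return np.random.default_rng(int.from_bytes(digest, "little"))
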