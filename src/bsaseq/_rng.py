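"""Hierarchical, keyed random streams.

One global integer seed expands into named substreams so any stage (or any
individual x locus slice of the simulator) can be re-run in isolation and
still be byte-reproducible. String keys are hashed to integers with a stable
digest so stream identity does not depend on Python's randomized hash.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(part: int | str) -> int:
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError(f"stream key parts must be non-negative, got {part}")
        return int(part)
    digest = hashlib.sha256(str(part).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big")


def substream(seed: int, *key: int | str) -> np.random.Generator:
    """Return a Generator for the (seed, *key) stream.

    Streams with different keys are statistically independent; the same
    (seed, key) always yields the same stream.
    """
    seq = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key_to_int(k) for k in key))
    return np.random.default_rng(seq)
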