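"""Deterministic seed splitting.

All randomness in the package flows from one user-facing integer seed.
Stages derive independent child generators from (seed, *path) where the path
elements are short strings naming the stage (e.g. ``("simulate", "AF", "FA")``).
Hashing the path into a ``SeedSequence`` spawn key keeps stages independently
reproducible: rerunning one stage never consumes another stage's stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _key(part: object) -> int:
    return zlib.crc32(str(part).encode("utf-8"))


def child_seed(seed: int, *path: object) -> np.random.SeedSequence:
    """Return a ``SeedSequence`` for stage ``path`` under the master ``seed``."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return np.random.SeedSequence(int(seed), spawn_key=tuple(_key(p) for p in path))


def child_rng(seed: int, *path: object) -> np.random.Generator:
    """Return an independent ``Generator`` for stage ``path``."""
    return np.random.default_rng(child_seed(seed, *path))
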