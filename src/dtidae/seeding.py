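"""Deterministic seed derivation.

One master seed governs every source of randomness; per-stage generators are
derived from ``SeedSequence([master, crc32(token), ...])`` so that partial
re-runs (a single CV fold, one pipeline stage) reproduce bit-identically.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derived_rng"]


def _token_to_int(token: int | str) -> int:
    if isinstance(token, (int, np.integer)):
        return int(token)
    return zlib.crc32(str(token).encode("utf-8"))


def derive_seed(master_seed: int, *tokens: int | str) -> int:
    """A stable 63-bit seed for the stage identified by ``tokens``."""
    seq = np.random.SeedSequence([int(master_seed)] + [_token_to_int(t) for t in tokens])
    return int(seq.generate_state(1, dtype=np.uint64)[0] >> 1)


def derived_rng(master_seed: int, *tokens: int | str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, *tokens))
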