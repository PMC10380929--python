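"""Shared helpers: deterministic seed derivation and validation utilities."""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "check_finite"]


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a child seed from a global seed and a sequence of stage tokens.

    The derivation hashes ``(seed, tokens...)`` with SHA-256 and truncates to
    31 bits, so every stage of a pipeline gets an independent, reproducible
    stream from one user-facing seed.
    """
    payload = repr((int(seed),) + tuple(str(t) for t in tokens)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def check_finite(x: np.ndarray, name: str = "input") -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite values")
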