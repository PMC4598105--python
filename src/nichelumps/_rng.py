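"""Seed plumbing: named, reproducible substreams derived from one user seed."""

from __future__ import annotations

import hashlib

import numpy as np


def substream_seed(seed: int, name: str) -> int:
    """Derive a deterministic child seed for a named substream.

    Mixing the stream name through SHA-256 keeps substreams statistically
    independent while remaining reproducible across platforms and sessions.
    The result is a non-negative int below 2**31.
    """
    digest = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """A numpy Generator for the named substream of ``seed``."""
    return np.random.default_rng(substream_seed(seed, name))
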