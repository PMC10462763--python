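"""Shared helpers: seeded stream derivation, labelled errors, small I/O utilities."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["PromdivergeError", "stream_rng", "reverse_complement"]


class PromdivergeError(ValueError):
    """Labelled error raised on invalid inputs anywhere in the pipeline."""


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent random stream derived from a global seed and a stream name.

    Each generator in the pipeline draws from its own stream so that adding
    draws to one stage never perturbs another stage run under the same seed.
    """
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
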