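"""Named, independent random streams derived from one master seed.

Paired counterfactual runs (baseline vs. intervention) must share every
source of randomness that the intervention does not touch — common random
numbers.  Each consumer asks for a stream by name (and optional integer
subkeys); streams with different names are statistically independent, and
the same (seed, name, keys) always yields the same generator.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_words(*keys: str | int) -> list[int]:
    words: list[int] = []
    for k in keys:
        if isinstance(k, str):
            words.append(zlib.crc32(k.encode("utf-8")))
        else:
            words.append(int(k) & 0xFFFFFFFF)
    return words


def stream(seed: int, *keys: str | int) -> np.random.Generator:
    """Return a Generator for the named stream under ``seed``."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *_key_words(*keys)])
    return np.random.default_rng(ss)


def derive_seed(seed: int, *keys: str | int) -> int:
    """A reproducible integer sub-seed (< 2**31) for nested components."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *_key_words(*keys)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
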