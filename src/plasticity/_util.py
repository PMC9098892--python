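"""Shared helpers: seed derivation and undefined-value markers.

Undefined quantities (e.g. a turnover rate with zero spines in the previous
session) are carried as ``numpy.nan`` and excluded from aggregation with an
explicit exclusion count; they are never coerced to zero.
"""

from __future__ import annotations

import zlib

import numpy as np

#: marker for quantities that are undefined for a given unit (degenerate input)
UNDEFINED = float("nan")


def child_seed(seed: int, name: str) -> int:
    """Derive a stable per-module child seed from one global seed.

    The scheme hashes the module name with CRC-32 and folds it into a
    ``numpy.random.SeedSequence`` together with the global seed, so every
    module draws from an independent stream while the whole run stays
    reproducible from a single integer.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_from(seed: int, name: str | None = None) -> np.random.Generator:
    if name is not None:
        seed = child_seed(seed, name)
    return np.random.default_rng(seed)


def is_undefined(x) -> bool:
    try:
        return bool(np.isnan(x))
    except TypeError:
        return False
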