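"""Seed-substream derivation and small shared helpers.

Every source of randomness in the package flows from one top-level integer
seed through named substreams, so that e.g. the single-timepoint draw and the
cross-validation fold shuffle are independent but individually reproducible.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(seed: int, name: str) -> int:
    """Deterministic child seed (< 2**31) for a named substream."""
    h = hashlib.sha256(f"{int(seed)}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, name))


def pearson_r(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
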