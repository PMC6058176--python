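"""Small shared helpers: display rounding and deterministic seeding."""
from __future__ import annotations

import hashlib

import numpy as np


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1).

    numpy/python round() use banker's rounding; reported tables round
    halves away from zero, which matters for e.g. 3649.5 -> 3650.
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if out.ndim == 0:
        val = float(out)
        return int(val) if decimals == 0 else val
    return out


def derive_seed(master_seed: int, *tags) -> int:
    """Deterministically derive a sub-seed (< 2**31) from a master seed and tags."""
    h = hashlib.sha256(repr((int(master_seed),) + tuple(tags)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31 - 1)


def config_hash(obj) -> str:
    """Stable short hash of a (nested, JSON-serialisable) configuration."""
    import json

    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
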