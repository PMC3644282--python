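"""Deterministic seed derivation.

Every source of randomness in the package draws its seed through
:func:`derive_seed`, so that independent stages (consensus runs, permutation
subsets, simulator samples) never share or collide streams while remaining
fully reproducible from a single base seed.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MOD = 2**31


def derive_seed(*parts: object) -> int:
    """Fold an arbitrary tuple of hashable labels into a 31-bit seed.

    SHA-256 of the tuple's repr, truncated. Stable across processes and
    Python versions (no reliance on ``hash()`` randomisation).
    """
    digest = hashlib.sha256(repr(parts).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD
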