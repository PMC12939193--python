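"""Deterministic seed derivation.

A single master seed fans out into independent per-stage streams (per-K
clustering replicates, per-state permutation tests, per-scan simulations).
The derivation hashes the master seed together with string/int tokens so
streams are reproducible and independent of Python's hash randomization.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MOD = 2**31  # keep derived seeds in the int32 range accepted everywhere


def derive_seed(master: int, *tokens: object) -> int:
    """Derive a child seed from ``master`` and a tuple of hashable tokens.

    The same (master, tokens) pair always yields the same seed; distinct
    token tuples yield (with overwhelming probability) distinct streams.
    """
    payload = repr((int(master),) + tuple(tokens)).encode("utf-8")
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "little") % _MOD
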