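"""Deterministic seed derivation.

Child seeds are derived from a master seed and a stage name with blake2b, so
every stage is reproducible in isolation and independent of execution order.
All derived seeds stay below 2**31 for portability.
"""

from __future__ import annotations

import hashlib


def child_seed(master: int, stage: str) -> int:
    """Derive a stage-specific 31-bit seed from a master seed."""
    digest = hashlib.blake2b(f"{int(master)}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)
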