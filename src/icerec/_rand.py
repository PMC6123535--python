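"""Seed plumbing: every stochastic stage draws its own 31-bit sub-seed from
the master seed and a stage label, so inserting a stage never perturbs the
random stream of another."""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic 31-bit sub-seed for stage ``label`` under ``master_seed``."""
    digest = hashlib.sha256(f"{int(master_seed)}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
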