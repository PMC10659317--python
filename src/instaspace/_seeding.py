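"""Deterministic sub-seed derivation.

Every stochastic stage derives its own seed from the master seed and a stage
name, so stages are independently reproducible and adding a stage never
perturbs the randomness of another.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> int:
    """A stable 31-bit seed for one named stage."""
    h = hashlib.sha256(f"{int(master_seed)}::{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))
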