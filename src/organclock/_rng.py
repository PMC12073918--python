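"""Stage-scoped random number streams.

Every stochastic stage of the pipeline draws from its own
``numpy.random.Generator`` derived from the master seed plus a stable
string label, so regenerating one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stage integer seed (< 2**31)."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(label.encode("utf-8"))) % (2**31 - 1)


def stage_rng(master_seed: int, label: str) -> np.random.Generator:
    """Generator for one named pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode("utf-8"))]))
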