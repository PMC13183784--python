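"""Small shared numerics helpers."""

from __future__ import annotations

import numpy as np


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (0.5 -> 1).

    Python's built-in round() uses banker's rounding; harvest and census
    counts need a fixed, direction-stable convention instead.
    """
    return int(np.floor(x + 0.5))


def child_rngs(master_seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed."""
    seqs = np.random.SeedSequence(master_seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


class ConfigError(ValueError):
    """Raised when a configuration field fails validation; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")
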