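"""Seed-and-stream policy for byte-identical cohort regeneration.

A single master seed is expanded, via :class:`numpy.random.SeedSequence`
spawning, into one named substream per stochastic stage of the pipeline, in a
fixed order. Because every stage draws only from its own substream, editing a
coefficient that consumes no randomness (or whose stage comes later) leaves
every earlier draw unchanged — this is what makes the baseline table invariant
to the structural coefficients and enables common-random-number calibration.
"""

from __future__ import annotations

import numpy as np

from ._errors import ConfigError

#: Stage order is part of the reproducibility contract; never reorder.
STREAM_NAMES: tuple[str, ...] = (
    "demographics",
    "density",
    "exposure",
    "likert_baseline",
    "oxload_noise",
    "outcome_noise",
    "likert_week24",
)


class RNGPolicy:
    """Named, independent random substreams derived from one master seed."""

    def __init__(self, seed: int):
        seed = int(seed)
        if seed < 0:
            raise ConfigError("seed must be a non-negative integer")
        self.seed = seed
        children = np.random.SeedSequence(seed).spawn(len(STREAM_NAMES))
        self._streams = {
            name: np.random.Generator(np.random.PCG64(ss))
            for name, ss in zip(STREAM_NAMES, children)
        }

    def stream(self, name: str) -> np.random.Generator:
        try:
            return self._streams[name]
        except KeyError:
            raise ConfigError(f"unknown rng substream {name!r}") from None

    def __repr__(self) -> str:  # pragma: no cover
        return f"RNGPolicy(seed={self.seed})"
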