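"""Named, independent random substreams derived from one master seed.

Every stochastic operation takes either an integer seed or a
``numpy.random.Generator``.  A single master seed spawns independent
named substreams (calls, noise, lfp, spikes, ...) so that e.g. the LFP
can be regenerated without consuming the spike stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_generator"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The mapping (seed, name) -> stream is stable across runs and
    platforms; distinct names give statistically independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
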