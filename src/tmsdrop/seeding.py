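"""Named, independent random substreams derived from one base seed.

Every stochastic operation in the package draws from a substream keyed by a
short name ("pool", "radii", "partition", "noise", ...), so that e.g.
regenerating an emulsion with a different noise model leaves the sampled
radii untouched.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream *name* of base seed *seed*.

    The (seed, name) pair fully determines the stream; different names give
    statistically independent streams via SeedSequence spawn keys.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
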