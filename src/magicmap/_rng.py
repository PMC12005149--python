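"""Named random substreams derived from a single root seed.

Every stochastic step in the package draws from a generator obtained via
:func:`rng_for`, so a run is reproducible from one integer and no hidden
global state is involved.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, *names) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    Distinct name tuples give statistically independent streams; the same
    tuple always gives the same stream.
    """
    keys = [int(seed) % (2**31)]
    keys.extend(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(keys))
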