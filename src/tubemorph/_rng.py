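"""Named random substreams derived from one root seed.

Every stochastic step in the package draws from a substream keyed by a
module/step name, so adding draws to one step never perturbs another and
a single root seed reproduces an entire run bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream `name` under root `seed`."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def child_seed(seed: int, name: str) -> int:
    """A derived integer seed (< 2**31) for handing to nested components."""
    key = zlib.crc32(name.encode("utf-8"))
    return int(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]).generate_state(1)[0] & 0x7FFFFFFF)
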