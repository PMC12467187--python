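"""Named-substream seed derivation.

One global seed fans out to per-module streams keyed by a name, so adding
a consumer never perturbs another's draws. Derived seeds stay below 2^31.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(seed: int, name: str) -> int:
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode("utf-8"))])
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))
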