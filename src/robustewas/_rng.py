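"""Named random substreams.

Every stochastic component of the package draws from a generator keyed by
(stream constant, user seed).  Keeping the streams separate means, e.g.,
adding features to a dataset or simulating more scenarios never perturbs
the fold assignment produced for a given seed.
"""

from __future__ import annotations

import numpy as np

# Fixed per-purpose stream constants; never reuse one for a new purpose.
_STREAMS = {
    "folds": 0x666F6C64,
    "split_half": 0x73706C74,
    "sim_data": 0x64617461,
    "sim_outliers": 0x6F75746C,
    "sim_engine": 0x656E6769,
    "fixture": 0x66697874,
}


def substream(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Return the generator for the named substream under ``seed``.

    ``extra`` integers (e.g. a fold count) key further independent
    children of the same named stream.
    """
    return np.random.default_rng([_STREAMS[name], int(seed), *map(int, extra)])
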