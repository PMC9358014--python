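"""Small shared helpers: reporting-precision rounding and seeded substreams."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as printed reports in this field do.

    Python's built-in ``round`` is banker's rounding; Mb lengths, percentages
    and densities here are reported half-up at a fixed number of decimals.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# Fixed substream offsets: adding a generator must never perturb the draws of
# an existing one, so each generator owns a constant key under the root seed.
STREAM_ASSEMBLY = 1
STREAM_EVIDENCE = 2
STREAM_GENOTYPES = 3
STREAM_GENES = 4
STREAM_DEG = 5
STREAM_SYNTENY = 6


def substream(seed: int, key: int) -> np.random.Generator:
    """Independent PRNG substream for generator ``key`` under a root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(key),)))
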