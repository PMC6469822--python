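"""Deterministic stream splitting.

All randomness in the package flows from one master seed.  Each stage draws
from an independent child stream identified by a fixed integer key path, so a
stage can be regenerated in isolation and inserting a new stage never shifts
the draws of an existing one.
"""

from __future__ import annotations

import numpy as np

# fixed key registry; never renumber
STREAMS = {
    "field_survey": 1,
    "dietary_survey": 2,
    "concentration": 3,
    "compound_table": 4,
    "spray_variability": 5,
    "spray_uncertainty": 6,
    "nondietary_assign": 7,
    "resident_imputation": 8,
    "link": 9,
    "mixtures": 10,
    "bootstrap": 11,
}


def substream(seed: int, *keys: int | str) -> np.random.Generator:
    """Return a Generator for the child stream ``(seed, *keys)``.

    String keys are looked up in the :data:`STREAMS` registry; integer keys are
    used verbatim (e.g. per-crop or per-cycle indices).
    """
    resolved = tuple(STREAMS[k] if isinstance(k, str) else int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=resolved))
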