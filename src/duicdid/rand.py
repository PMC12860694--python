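"""Seeded, stage-addressed random streams.

All randomness in the package flows from one integer seed through a
counter-based Philox generator. Each pipeline stage gets its own substream
keyed by a fixed stage id, so toggling one stage on or off never perturbs
the draws of another.
"""

from __future__ import annotations

import numpy as np

#: Stable stage ids; append only, never renumber.
STAGE_IDS = {
    "generate": 0,
    "artifacts": 1,
    "recode": 2,
    "impute": 3,
    "bootstrap": 4,
    "power": 5,
    "burden": 6,
    "fixture": 7,
    "screen": 8,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Philox substream for (seed, stage); deterministic and independent."""
    try:
        stage_id = STAGE_IDS[stage]
    except KeyError:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGE_IDS)}")
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage_id,))
    return np.random.Generator(np.random.Philox(ss))
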