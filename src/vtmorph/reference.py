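"""Published reference values for a cohort of 13 male singing students.

The per-subject difference of the Hammarberg index between speech-like and
singing phonation (delta_HI = HI_speech_like - HI_singing, in dB) for the
cohort of thirteen male singing students at the start of their academic solo
training, with age, years of prior singing lessons and voice category.
These printed values serve as a worked example and as an oracle for the
aggregation code: their mean is +4.5 dB and exactly three subjects show
negative values.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_delta_hi"]

_ROWS = [
    (1, 20, 10, "baritone", -4.1),
    (2, 20, 4, "baritone", 6.9),
    (3, 21, 3, "tenor", 2.1),
    (4, 21, 6, "tenor", 6.3),
    (5, 21, 10, "baritone", 5.0),
    (6, 19, 1, "baritone", 4.7),
    (7, 20, 4, "baritone", 2.9),
    (8, 19, 10, "baritone", 17.6),
    (9, 21, 10, "tenor", 3.7),
    (10, 19, 10, "tenor", -0.1),
    (11, 20, 1, "baritone", 13.5),
    (12, 20, 3, "tenor", 2.9),
    (13, 20, 2, "baritone", -2.5),
]


def reference_delta_hi() -> pd.DataFrame:
    """Per-subject delta-HI reference table (columns: subject, age_yr,
    lessons_yr, voice_category, delta_hi)."""
    return pd.DataFrame(
        _ROWS, columns=["subject", "age_yr", "lessons_yr", "voice_category", "delta_hi"]
    )
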