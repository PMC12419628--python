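"""Ordinal engagement ladder shared by patients and clinicians.

Engagement with the learning network is an ordinal state: agents progress
(or regress) one rung at a time.  The integer codes are used throughout the
engine; the names appear in configs and CSV output.
"""

UNAWARE = 0
AWARE = 1
PARTICIPATING = 2
CONTRIBUTING = 3
OWNING = 4

LEVEL_NAMES = ("unaware", "aware", "participating", "contributing", "owning")
N_LEVELS = 5


def level_code(name: str) -> int:
    """Map an engagement level name to its integer code."""
    try:
        return LEVEL_NAMES.index(name.strip().lower())
    except ValueError:
        raise ValueError(
            f"unknown engagement level {name!r}; expected one of {LEVEL_NAMES}"
        ) from None
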