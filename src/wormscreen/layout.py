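"""96-well plate vocabulary: well coordinates, content classes, control roster.

Screens of this design array one RNAi clone per well in columns 2-12 of a
96-well plate and reserve column 1 (wells A1-H1) for controls:

* empty feeding vector (L4440) and ``hil-5`` dsRNA -- negative controls with
  no lethality in either strain;
* ``plk-1`` dsRNA -- an RNAi-efficacy control causing 100% embryonic
  lethality in both strains;
* ``dli-1`` dsRNA -- the positive control, enhancing lethality specifically
  in the kinesin-5 mutant background.
"""

from __future__ import annotations

import re
from typing import Iterable

from .errors import LayoutError

ROWS = "ABCDEFGH"
N_COLUMNS = 12

# content classes (internal tokens) and the Data-Record description strings
SAMPLE = "sample"
NEG_CONTROL = "neg_control"
POS_CONTROL = "pos_control"
LETHALITY_CONTROL = "lethality_control"
CONTENT_CLASSES = (SAMPLE, NEG_CONTROL, POS_CONTROL, LETHALITY_CONTROL)

DESCRIPTION_TO_CONTENT = {
    "sample": SAMPLE,
    "neg": NEG_CONTROL,
    "pos": POS_CONTROL,
    "other": LETHALITY_CONTROL,
}
CONTENT_TO_DESCRIPTION = {v: k for k, v in DESCRIPTION_TO_CONTENT.items()}

# strains: the myo-2::gfp marker strain ("wild type") and the same marker in
# the bmk-1(ok391) deletion background ("mutant")
WILD_TYPE = "wild_type"
MUTANT = "mutant"
STRAINS = (WILD_TYPE, MUTANT)

EMPTY_VECTOR = "L4440"
NEG_GENE = "hil-5"
LETHAL_GENE = "plk-1"
POS_GENE = "dli-1"

#: default assignment of the eight column-1 wells
DEFAULT_CONTROL_ROSTER = {
    "A01": (NEG_CONTROL, EMPTY_VECTOR),
    "B01": (NEG_CONTROL, EMPTY_VECTOR),
    "C01": (NEG_CONTROL, NEG_GENE),
    "D01": (NEG_CONTROL, NEG_GENE),
    "E01": (LETHALITY_CONTROL, LETHAL_GENE),
    "F01": (LETHALITY_CONTROL, LETHAL_GENE),
    "G01": (POS_CONTROL, POS_GENE),
    "H01": (POS_CONTROL, POS_GENE),
}

_WELL_RE = re.compile(r"^\s*([A-Ha-h])\s*0?(\d{1,2})\s*$")


def normalize_well(well: str) -> str:
    """Normalize a well coordinate to row letter + zero-padded column ("B8" -> "B08").

    Raises :class:`LayoutError` for coordinates outside the 96-well A-H x 1-12 grid.
    """
    m = _WELL_RE.match(str(well))
    if not m:
        raise LayoutError(f"unparseable well coordinate: {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if not 1 <= col <= N_COLUMNS:
        raise LayoutError(f"well column out of range 1-{N_COLUMNS}: {well!r}")
    return f"{row}{col:02d}"


def well_column(well: str) -> int:
    """Column number (1-12) of a normalized well coordinate."""
    return int(well[1:])


def well_row(well: str) -> str:
    """Row letter (A-H) of a normalized well coordinate."""
    return well[0]


def sample_wells() -> list[str]:
    """All 88 sample-well coordinates (columns 2-12), row-major."""
    return [f"{r}{c:02d}" for r in ROWS for c in range(2, N_COLUMNS + 1)]


def control_wells() -> list[str]:
    """The eight column-1 control wells A01-H01."""
    return [f"{r}01" for r in ROWS]


def well_sort_key(well: str) -> tuple[str, int]:
    return well_row(well), well_column(well)


def sorted_wells(wells: Iterable[str]) -> list[str]:
    return sorted(wells, key=well_sort_key)
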