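"""Grade labels for the ordinal Ashcroft scale plus the non-alveolar class.

The Ashcroft system grades pulmonary fibrosis on an ordinal 0-8 scale, from
normal alveolar architecture (0) to total fibrous obliteration (8).  Tiles
showing non-alveolar tissue (large bronchi, blood vessels) form a tenth
class that is excluded from whole-section scoring.

Internally labels are stored as integer codes 0..9 where 9 encodes the
non-alveolar class; user-facing labels are the ints 0..8 and the string
``"NA"``.
"""

from __future__ import annotations

from typing import Union

#: Sentinel label for the non-alveolar (bronchus / large vessel) class.
NON_ALVEOLAR: str = "NA"

#: The nine ordinal fibrosis grades.
GRADES: tuple[int, ...] = tuple(range(9))

#: Fixed class order used everywhere: grades 0..8 then non-alveolar.
CLASS_ORDER: tuple[Union[int, str], ...] = GRADES + (NON_ALVEOLAR,)

#: Integer code reserved for the non-alveolar class.
NON_ALVEOLAR_CODE: int = 9

N_CLASSES: int = len(CLASS_ORDER)

Label = Union[int, str]


def to_code(label: Label) -> int:
    """Map a user-facing label (0..8 or ``"NA"``) to its integer code."""
    if label == NON_ALVEOLAR:
        return NON_ALVEOLAR_CODE
    if isinstance(label, (int,)) and not isinstance(label, bool) and 0 <= label <= 8:
        return int(label)
    # numpy integers
    try:
        i = int(label)
    except (TypeError, ValueError):
        raise ValueError(f"unknown grade label: {label!r}") from None
    if 0 <= i <= 8 and i == label:
        return i
    raise ValueError(f"unknown grade label: {label!r}")


def to_label(code: int) -> Label:
    """Inverse of :func:`to_code`."""
    code = int(code)
    if code == NON_ALVEOLAR_CODE:
        return NON_ALVEOLAR
    if 0 <= code <= 8:
        return code
    raise ValueError(f"unknown grade code: {code!r}")
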