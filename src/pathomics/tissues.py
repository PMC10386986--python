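"""The six histological tissue categories of HCC whole-slide images.

Abbreviations follow digital-pathology usage: TR tumor region, NLT normal
liver tissue, PA portal area, FT fibrous tissue, HNT hemorrhagic/necrotic
tissue, IC immune cells.
"""

from __future__ import annotations

from enum import Enum


class TissueClass(str, Enum):
    TR = "TR"
    NLT = "NLT"
    PA = "PA"
    FT = "FT"
    HNT = "HNT"
    IC = "IC"

    def __str__(self) -> str:  # keep CSV/JSON serialization terse
        return self.value


#: Canonical ordering used for probability vectors and weight maps.
CLASS_ORDER: tuple[TissueClass, ...] = (
    TissueClass.TR,
    TissueClass.NLT,
    TissueClass.PA,
    TissueClass.FT,
    TissueClass.HNT,
    TissueClass.IC,
)


def as_tissue_class(value) -> TissueClass:
    """Coerce a string or TissueClass to TissueClass, rejecting unknowns."""
    if isinstance(value, TissueClass):
        return value
    try:
        return TissueClass(str(value))
    except ValueError as exc:
        valid = ", ".join(c.value for c in CLASS_ORDER)
        raise ValueError(
            f"unknown tissue class {value!r}; expected one of: {valid}"
        ) from exc
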