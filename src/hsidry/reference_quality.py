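"""Reference quality indicators: gravimetric moisture and CIELAB color difference.

The wet-basis moisture content of a sample dried to constant mass is

    X = (m1 - m2) / (m1 - m3) * 100        [% , g/100 g]

where ``m1`` and ``m2`` are the masses of the weighing bottle plus sample
before and after oven drying and ``m3`` is the bottle alone.  Color change
relative to a fresh reference is expressed as the Euclidean CIE76 distance

    dE = sqrt(dL*^2 + da*^2 + db*^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass
class MoistureMeasurement:
    """One gravimetric moisture determination (all masses in grams)."""

    m1: float
    m2: float
    m3: float
    X: float = field(init=False)

    def __post_init__(self) -> None:
        self.X = moisture_content(self.m1, self.m2, self.m3)


@dataclass
class QualityRecord:
    """Reference indicators for one sample at one drying level.

    Units: moisture %, CIELAB for L*/a*/b*/delta_e, hardness and
    adhesiveness in N, elasticity in mm, stickiness and chewiness in mJ.
    """

    sample_id: str
    level: int
    moisture: float
    L: float
    a: float
    b: float
    delta_e: float
    hardness: float
    adhesiveness: float
    elasticity: float
    stickiness: float
    chewiness: float

    INDICATORS = (
        "moisture", "L", "a", "b", "hardness", "adhesiveness",
        "elasticity", "stickiness", "chewiness",
    )

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "level": self.level,
            "moisture": self.moisture,
            "L": self.L,
            "a": self.a,
            "b": self.b,
            "delta_e": self.delta_e,
            "hardness": self.hardness,
            "adhesiveness": self.adhesiveness,
            "elasticity": self.elasticity,
            "stickiness": self.stickiness,
            "chewiness": self.chewiness,
        }


def moisture_content(m1: float, m2: float, m3: float) -> float:
    """Wet-basis moisture percentage from bottle+sample masses.

    Parameters
    ----------
    m1, m2 : float
        Bottle plus sample mass before / after drying to constant mass (g).
    m3 : float
        Empty bottle mass (g).

    Raises
    ------
    ValueError
        If there is no sample mass (``m1 <= m3``) or the sample gained
        mass during drying (``m2 > m1``).
    """
    if m1 <= m3:
        raise ValueError(f"no sample mass: m1={m1} must exceed bottle mass m3={m3}")
    if m2 > m1:
        raise ValueError(f"mass gain during drying: m2={m2} > m1={m1}")
    if m2 < m3:
        raise ValueError(f"residual mass below bottle mass: m2={m2} < m3={m3}")
    return (m1 - m2) / (m1 - m3) * 100.0


def delta_e(lab: tuple[float, float, float], lab_ref: tuple[float, float, float]) -> float:
    """CIE76 color difference between two (L*, a*, b*) triples."""
    dl = lab[0] - lab_ref[0]
    da = lab[1] - lab_ref[1]
    db = lab[2] - lab_ref[2]
    if not all(math.isfinite(v) for v in (dl, da, db)):
        raise ValueError("non-finite CIELAB coordinates")
    return math.sqrt(dl * dl + da * da + db * db)
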