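"""Sample-consumption bookkeeping for shot-averaged diffraction images.

Laser-driven ablation ejects a known volume per shot; a diffraction image
averages a known number of shots.  The per-image consumption is their exact
product, converted from picolitres to nanolitres.  The arithmetic runs on
integer femtolitres so that decimal inputs (e.g. 27 pl x 2750 shots =
74.25 nl) stay exact instead of accumulating binary float dust.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from fractions import Fraction

__all__ = ["ConsumptionEstimate", "consumption"]


@dataclass(frozen=True)
class ConsumptionEstimate:
    """Exact per-image sample consumption."""

    per_shot_pl: float
    shots_per_image: int
    per_image_nl: float

    def __str__(self) -> str:
        return (
            f"{self.per_shot_pl} pl/shot x {self.shots_per_image} shots = "
            f"{self.per_image_nl} nl per image"
        )


def consumption(per_shot_pl, shots: int) -> ConsumptionEstimate:
    """Per-image consumed volume: ``per_shot_pl`` x ``shots``, reported in nl.

    ``per_shot_pl`` may be int, float or decimal string; it is interpreted at
    its decimal face value (1 pl = 1000 fl internally), so the product is
    exact for any input with at most three decimal places.
    """
    per_shot = Fraction(Decimal(str(per_shot_pl)))
    if per_shot <= 0:
        raise ValueError("per-shot volume must be positive")
    shots = int(shots)
    if shots <= 0:
        raise ValueError("shot count must be positive")
    femtolitres = per_shot * 1000 * shots
    per_image_nl = Fraction(femtolitres, 10**6)
    return ConsumptionEstimate(
        per_shot_pl=float(per_shot),
        shots_per_image=shots,
        per_image_nl=float(per_image_nl),
    )
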