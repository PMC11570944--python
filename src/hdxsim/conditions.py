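"""Solvent conditions for amide hydrogen exchange.

Acidity can be supplied on three operational scales: a pH measured in H2O,
a glass-electrode reading taken in D2O, or a pD value directly. Readings in
D2O understate the deuterium-ion activity; the conventional correction is

    pD = (electrode reading) + 0.4

which is applied exactly once, at construction time, so downstream code only
ever sees a true pH or pD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "AcidityScale",
    "Direction",
    "ExchangeConditions",
    "pd_from_reading",
    "PD_ELECTRODE_OFFSET",
]

#: Conventional offset between a pH-electrode reading taken in D2O and pD.
PD_ELECTRODE_OFFSET = 0.4


class AcidityScale(enum.Enum):
    """Operational scale on which an acidity value is reported."""

    PH_IN_H2O = "pH_in_H2O"
    READING_IN_D2O = "reading_in_D2O"
    PD = "pD"


class Direction(enum.Enum):
    """Isotopic direction of the exchange reaction."""

    H_TO_D = "H_to_D"  #: labeling, NH -> ND in D2O
    D_TO_H = "D_to_H"  #: back exchange, ND -> NH in H2O


def pd_from_reading(reading: float) -> float:
    """Convert a pH-electrode reading taken in D2O to pD.

    Parameters
    ----------
    reading : float
        Uncorrected meter reading in D2O, in [0, 14].

    Returns
    -------
    float
        ``reading + 0.4``.
    """
    if not 0.0 <= reading <= 14.0:
        raise ValueError(f"electrode reading {reading!r} outside [0, 14]")
    return reading + PD_ELECTRODE_OFFSET


@dataclass(frozen=True)
class ExchangeConditions:
    """Acidity, temperature, and solvent isotope of an exchange step.

    Parameters
    ----------
    acidity_value : float
        Acidity on the scale given by `acidity_scale`, in [0, 14].
    acidity_scale : AcidityScale or str
        ``pH_in_H2O``, ``reading_in_D2O``, or ``pD``.
    temperature : float
        Absolute temperature in kelvin (physiological-to-quench range).
    direction : Direction or str
        ``H_to_D`` for labeling in D2O, ``D_to_H`` for back exchange in H2O.
    heavy_fraction : float, optional
        Mole fraction of deuterium in the exchanging solvent. Defaults to
        1.0 for labeling and 0.0 for back exchange (pure-solvent
        assumption); carried as metadata for equilibrium targets.
    """

    acidity_value: float
    acidity_scale: AcidityScale
    temperature: float
    direction: Direction
    heavy_fraction: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "acidity_scale", AcidityScale(self.acidity_scale))
        object.__setattr__(self, "direction", Direction(self.direction))
        if self.heavy_fraction is None:
            default = 1.0 if self.direction is Direction.H_TO_D else 0.0
            object.__setattr__(self, "heavy_fraction", default)
        if not 0.0 <= self.acidity_value <= 14.0:
            raise ValueError(f"acidity_value {self.acidity_value!r} outside [0, 14]")
        if not 150.0 < self.temperature < 400.0:
            raise ValueError(
                f"temperature {self.temperature!r} K outside the plausible "
                "(150, 400) K range"
            )
        if not 0.0 <= self.heavy_fraction <= 1.0:
            raise ValueError("heavy_fraction must lie in [0, 1]")
        if self.direction is Direction.H_TO_D and self.heavy_fraction == 0.0:
            raise ValueError("H_to_D labeling requires heavy_fraction > 0")
        if (
            self.direction is Direction.D_TO_H
            and self.acidity_scale is not AcidityScale.PH_IN_H2O
        ):
            raise ValueError(
                "D_to_H back exchange takes place in H2O; acidity must be "
                "given as pH_in_H2O"
            )
        if (
            self.direction is Direction.H_TO_D
            and self.acidity_scale is AcidityScale.PH_IN_H2O
        ):
            raise ValueError(
                "H_to_D labeling takes place in D2O; give the acidity as pD "
                "or as reading_in_D2O"
            )

    @property
    def effective_acidity(self) -> float:
        """The acidity on the solvent's native scale (pH in H2O, pD in D2O).

        Applies the +0.4 electrode correction exactly once, for
        ``reading_in_D2O`` input only.
        """
        if self.acidity_scale is AcidityScale.READING_IN_D2O:
            return pd_from_reading(self.acidity_value)
        return self.acidity_value
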