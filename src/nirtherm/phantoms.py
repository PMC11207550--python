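"""Tissue-simulating phantom definitions.

A phantom is a gelatin/Intralipid/water block engineered to mimic the
near-infrared absorption and scattering of the dermal layer of skin.  Each
phantom in the study design carries its own five-step temperature profile in
the 20-24 degC window (the gelatin matrix liquefies above 24 degC, which caps
the usable range).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import ConfigError

__all__ = ["PhantomSpec", "STUDY_PHANTOMS", "study_phantoms"]


@dataclass(frozen=True)
class PhantomSpec:
    """Composition (weight-percent) and temperature step profile of one phantom.

    Parameters
    ----------
    phantom_id : int
        Identifier, 1-7 in the standard design.
    gelatin_pct, intralipid_pct, water_pct : float
        Weight-percent of each constituent; they must sum to 100 within 0.5.
    step_profile_C : tuple of float
        The five Peltier set-point temperatures, in acquisition order, each in
        [20, 24] degC.
    """

    phantom_id: int
    gelatin_pct: float
    intralipid_pct: float
    water_pct: float
    step_profile_C: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        total = self.gelatin_pct + self.intralipid_pct + self.water_pct
        if abs(total - 100.0) > 0.5:
            raise ConfigError(
                f"phantom {self.phantom_id}: constituents sum to {total:.2f}, "
                "expected 100 +/- 0.5"
            )
        if len(self.step_profile_C) != 5:
            raise ConfigError(
                f"phantom {self.phantom_id}: step profile must have exactly 5 "
                f"set points, got {len(self.step_profile_C)}"
            )
        for t in self.step_profile_C:
            if not (20.0 <= t <= 24.0):
                raise ConfigError(
                    f"phantom {self.phantom_id}: set point {t} degC outside [20, 24]"
                )

    @property
    def water_fraction(self) -> float:
        return self.water_pct / 100.0

    @property
    def gelatin_fraction(self) -> float:
        return self.gelatin_pct / 100.0


def study_phantoms() -> list[PhantomSpec]:
    """The seven-phantom study design: compositions and step profiles."""
    rows = [
        (1, 28.1, 9.4, 62.5, (24, 20, 21, 22, 23)),
        (2, 26.6, 9.2, 64.1, (24, 23, 20, 21, 22)),
        (3, 25.9, 9.9, 64.2, (20, 23, 21, 24, 22)),
        (4, 25.4, 9.0, 65.6, (24, 20, 21, 23, 22)),
        (5, 22.2, 9.7, 68.1, (20, 21, 22, 24, 23)),
        (6, 19.4, 11.1, 69.5, (23, 20, 22, 24, 21)),
        (7, 19.0, 9.8, 71.1, (23, 20, 24, 21, 22)),
    ]
    return [
        PhantomSpec(pid, g, il, w, tuple(float(t) for t in prof))
        for pid, g, il, w, prof in rows
    ]


#: Module-level copy of the standard design for convenience.
STUDY_PHANTOMS: list[PhantomSpec] = study_phantoms()
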