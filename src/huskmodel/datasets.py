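"""Bundled reference parameter set for the Korean hemp-seed archetype.

These are the central values measured/assumed for the study seed lot: the
husk occupies 10 % of the seed volume at 1.5x the kernel density and carries
300 mg/kg Delta9-THC, while the kernel carries 2 mg/kg.
"""

from __future__ import annotations

from dataclasses import dataclass

from .composition import MaterialComposition
from .errors import DomainError


@dataclass(frozen=True)
class SeedModel:
    """Geometry-free composition archetype of one seed lot."""

    f_H: float = 0.10          # husk volume fraction
    rho_ratio: float = 1.5     # husk density / kernel density
    C_H_mg_kg: float = 300.0   # husk THC concentration
    C_C_mg_kg: float = 2.0     # kernel THC concentration

    def composition(self, rho_c: float = 1.0) -> MaterialComposition:
        return MaterialComposition(
            rho_c=rho_c,
            rho_H=self.rho_ratio * rho_c,
            C_H_THC=self.C_H_mg_kg,
            C_C_THC=self.C_C_mg_kg,
            f_H=self.f_H,
        )


#: The in-study archetype used by the demo pipeline and the simulators.
REFERENCE_SEED = SeedModel()


def husk_kernel_ratio(seed: SeedModel = REFERENCE_SEED) -> float:
    """Husk-to-kernel THC concentration ratio (dimensionless).

    For the reference lot this is 300/2 = 150: the husk carries two orders of
    magnitude more THC than the kernel, which is what makes selective husk
    extraction worthwhile.
    """
    if seed.C_C_mg_kg <= 0:
        raise DomainError("kernel concentration must be positive for a ratio")
    return seed.C_H_mg_kg / seed.C_C_mg_kg
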