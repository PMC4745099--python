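"""Load capacity of termite clay walls and hollow-cylinder flexural rigidity.

Two small structural checks.  First, whether a clay wall of measured
compressive strength and cross-sectional area can carry the imposed load:
force = strength x area, converted to an equivalent supported mass.  Second,
why hollowing a cylinder (as termites do when eating a tree from the roots
upward) need not weaken it in bending: at equal mass, an annular
cross-section has a strictly larger second moment of area than the solid one,
so the flexural rigidity EI grows with the hollow.
"""

from __future__ import annotations

from dataclasses import dataclass

from claysub.energetics import GRAVITY

__all__ = ["WallSpec", "LoadCapacity", "load_capacity", "rigidity_ratio"]


@dataclass(frozen=True)
class WallSpec:
    """A clay wall: compressive strength (MPa), supporting cross-section (cm^2),
    and the mass (kg) it must carry."""

    compressive_strength_mpa: float
    cross_section_cm2: float
    imposed_load_kg: float

    def __post_init__(self) -> None:
        if min(self.compressive_strength_mpa, self.cross_section_cm2, self.imposed_load_kg) <= 0:
            raise ValueError("all wall parameters must be positive")


@dataclass(frozen=True)
class LoadCapacity:
    force_n: float
    mass_equivalent_kg: float
    supports_load: bool


def load_capacity(wall: WallSpec, g: float = GRAVITY) -> LoadCapacity:
    """Maximum supported force and mass of the wall, and whether the load holds.

    1 MPa x 1 cm^2 = 100 N, so ``force = strength * area * 100``; the mass
    equivalent divides by g.  The contract is the comparison against the
    imposed load, not the trailing digits of the capacity.
    """
    force = wall.compressive_strength_mpa * 1e6 * wall.cross_section_cm2 * 1e-4
    mass = force / g
    return LoadCapacity(
        force_n=force,
        mass_equivalent_kg=mass,
        supports_load=bool(mass >= wall.imposed_load_kg),
    )


def rigidity_ratio(outer_r: float, inner_r: float, comparison: str = "equal_mass") -> float:
    """Second-moment-of-area ratio of a hollow cylinder to a solid reference.

    ``comparison='equal_mass'`` (default) compares against the solid cylinder
    of the same cross-sectional area: I_hollow / I_solid =
    (r_o^2 + r_i^2) / (r_o^2 - r_i^2), which is 1 for a solid section and
    strictly increases with the hollow.  ``comparison='equal_outer'``
    compares against the solid cylinder of the same outer radius:
    1 - (r_i / r_o)^4 (always <= 1; the hollow section is less stiff but
    much lighter).
    """
    if outer_r <= 0:
        raise ValueError("outer radius must be positive")
    if not (0 <= inner_r < outer_r):
        raise ValueError("need 0 <= inner_r < outer_r")
    ro2, ri2 = outer_r**2, inner_r**2
    if comparison == "equal_mass":
        return (ro2 + ri2) / (ro2 - ri2)
    if comparison == "equal_outer":
        return 1.0 - (ri2 / ro2) ** 2
    raise ValueError(f"unknown comparison {comparison!r}")
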