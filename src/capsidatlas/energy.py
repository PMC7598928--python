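"""Geometrized pair potentials and configuration energies.

Each candidate interaction between one atom of the fixed unit and one atom of
the mobile unit is a short-range Lennard-Jones pair potential discretized into
three intervals: distances below the hard-sphere contact are forbidden,
distances inside the well [lo, hi] contribute the low energy E_l, and larger
distances contribute the high energy E_h.  A configuration with N_a of the N
candidate pairs inside their wells therefore has energy

    E = N * E_h - N_a * (E_h - E_l),

and, relative to the landscape constant exp(-N*E_h/kT) that cancels in every
normalized quantity, contributes the Boltzmann weight

    w(N_a) = (exp((E_h - E_l) / (k_B * T)))**N_a.

With the default energy gap of 0.997 kJ/mol at 298.15 K the base of this
weight is about 1.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .geometry import DEFAULT_VDW_RADIUS

K_B = 0.0083145  # kJ / (mol K)
DEFAULT_DELTA_E = 0.997  # kJ/mol, E_h - E_l
DEFAULT_TEMPERATURE = 298.15  # K


@dataclass(frozen=True)
class DiscretizedWell:
    """One discretized Lennard-Jones well between a cross-unit atom pair."""

    atom_a: str  # atom id in the fixed unit
    atom_b: str  # atom id in the mobile unit
    lo: float  # Angstrom, >= vdW contact distance
    hi: float  # Angstrom
    interaction_id: str
    residue_pair: tuple[int, int] = (0, 0)
    vdw_sum: float = 2 * DEFAULT_VDW_RADIUS

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"well {self.interaction_id}: need lo < hi")
        if self.lo < self.vdw_sum - 1e-12:
            raise ValueError(
                f"well {self.interaction_id}: lo={self.lo} below vdW contact "
                f"{self.vdw_sum}"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


def classify_pair_distance(well: DiscretizedWell, d: float) -> str:
    """Classify a pair distance as 'forbidden', 'active' or 'inactive'.

    A distance below the hard-sphere contact is forbidden; a distance inside
    the closed well interval is active; anything else is inactive.  Interval
    endpoints count as active (ties resolve toward the more constrained
    region).
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d < well.vdw_sum:
        return "forbidden"
    if well.lo <= d <= well.hi:
        return "active"
    return "inactive"


def configuration_energy(N: int, N_a: int, E_l: float, E_h: float) -> float:
    """Potential energy of a configuration with N_a of N constraints active."""
    if N_a > N:
        raise ValueError(f"N_a={N_a} exceeds N={N}")
    if N_a < 0 or N < 0:
        raise ValueError("counts must be non-negative")
    return N * E_h - N_a * (E_h - E_l)


def boltzmann_weight(N_a: int, delta_E: float = DEFAULT_DELTA_E,
                     temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Per-configuration weight (exp(delta_E / k_B T)) ** N_a.

    The landscape constant exp(-N E_h / kT) is never computed; it cancels in
    every normalized partition function.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if N_a < 0:
        raise ValueError("N_a must be non-negative")
    base = math.exp(delta_E / (K_B * temperature))
    return base ** N_a


@dataclass(frozen=True)
class EnergyModel:
    """A set of discretized wells plus the landscape constants."""

    wells: tuple[DiscretizedWell, ...]
    E_l: float = -DEFAULT_DELTA_E
    E_h: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE
    well_by_id: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.E_h > self.E_l:
            raise ValueError("need E_h > E_l")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        object.__setattr__(self, "wells", tuple(self.wells))
        ids = [w.interaction_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise ValueError("interaction ids must be unique")
        object.__setattr__(self, "well_by_id", {w.interaction_id: w for w in self.wells})

    @property
    def delta_E(self) -> float:
        return self.E_h - self.E_l

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    @property
    def weight_base(self) -> float:
        return math.exp(self.delta_E / (K_B * self.temperature))

    def energy(self, N_a: int) -> float:
        return configuration_energy(self.n_wells, N_a, self.E_l, self.E_h)

    def weight(self, N_a: int) -> float:
        return boltzmann_weight(N_a, self.delta_E, self.temperature)
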