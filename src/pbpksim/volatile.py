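"""Alveolar gas-exchange front end for volatile lipophilic solutes.

A volatile anesthetic enters and leaves the body through a single
well-mixed alveolar gas store ventilated at a continuous rate.  Mixed
venous blood equilibrates with the alveolar gas, so arterial blood enters
the lung tissue at the alveolar partial pressure, and the only obligatory
clearance route is expiration -- the kinetics are fixed by the ventilation
rate and the blood/air partition, with zero subject-specific adjustable
parameters.

Tissue partitioning is expressed through air-referenced coefficients:
``k_water_air`` and ``k_fat_water`` give a tissue/air partition
``(f_l * k_fat_water + (1 - f_l)) * k_water_air`` for a tissue of lipid
fraction ``f_l``, and dividing by ``k_blood_air`` gives the tissue/blood
partition used by the circulation model.  Dead space and breath-by-breath
cycling are ignored; the expired output is the end-tidal (alveolar)
partial pressure.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "VolatileParams",
    "volatile_tissue_air_partition",
    "volatile_tissue_blood_partition",
    "simulate_volatile",
]


@dataclass(frozen=True)
class VolatileParams:
    """Partition coefficients and respiratory parameters of a volatile solute.

    ``ventilation`` (alveolar ventilation, l/min) and ``alveolar_volume``
    (l) default to round standard-human values; they are ordinary config
    fields and can be varied to study, e.g., the effect of respiration
    rate on induction.
    """

    k_blood_air: float
    k_water_air: float
    k_fat_water: float
    ventilation: float = 5.0
    alveolar_volume: float = 3.0

    def __post_init__(self) -> None:
        for attr in ("k_blood_air", "k_water_air", "k_fat_water", "ventilation", "alveolar_volume"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be > 0, got {getattr(self, attr)}")


def volatile_tissue_air_partition(f_l_tissue: float, params: VolatileParams) -> float:
    """Tissue/air partition (liters of gas at 1 atm per liter of tissue per atm)."""
    if not 0.0 <= f_l_tissue <= 1.0:
        raise ValueError("f_l_tissue must be in [0,1]")
    return (f_l_tissue * params.k_fat_water + (1.0 - f_l_tissue)) * params.k_water_air


def volatile_tissue_blood_partition(f_l_tissue: float, params: VolatileParams) -> float:
    """Tissue/blood partition of a volatile solute.

    Reduces to ``k_water_air / k_blood_air`` for lipid-free tissue and
    ``k_fat_water * k_water_air / k_blood_air`` for pure lipid.
    """
    return volatile_tissue_air_partition(f_l_tissue, params) / params.k_blood_air


def simulate_volatile(body, solute, inhalation, time_grid, **options):
    """Simulate wash-in/wash-out of a volatile solute.

    Thin wrapper over :func:`pbpksim.core.simulate` that insists on
    volatile mode and inhalation-only dosing.  The returned result carries
    per-compartment partial pressures (atm) plus the
    ``expired_over_inspired`` ratio.
    """
    from .core import simulate

    if solute.mode != "volatile":
        raise ValueError(f"simulate_volatile requires a volatile solute, got mode '{solute.mode}'")
    for ev in inhalation.events:
        if ev.kind != "inhalation":
            raise ValueError(f"volatile mode accepts inhalation events only, got '{ev.kind}'")
    return simulate(body, solute, inhalation, time_grid, **options)
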