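"""Closed-form tissue/blood partition predictors and time-constant analytics.

Two solute classes admit a priori partition prediction:

* **Highly lipid-soluble (HLS)** solutes (lipid/water partition
  ``P_L/W >= ~100``): tissue binding is dominated by the tissue lipid
  fraction, so the tissue/blood partition coefficient is

  ``K = (f_l_tissue * P + (1 - f_l_tissue)) / (f_l_blood * P + (1 - f_l_blood))``

  which saturates at ``K_max = f_l_tissue / f_l_blood`` for large ``P``.
  Composing ``K_max`` with the perfusion-limited equilibration time
  constant ``T = K / perfusion`` bounds how slowly a flow-limited adipose
  depot can possibly wash out.

* **Extracellular (ECS)** solutes (cannot cross cell membranes):
  distribution is plasma plus interstitium, and since both phases bind
  the solute via albumin, the interstitial/plasma partition is

  ``K_EC = f_p + (1 - f_p) * K_alb``

  where ``f_p`` is the free (unbound) plasma fraction and ``K_alb`` the
  interstitial/plasma albumin concentration ratio.

Capillary-permeability limitation is quantified by ``fclr``, the fraction
of plasma solute equilibrating with the interstitium in a single capillary
pass, related to the permeability-surface-area product through the
Crone-Renkin expression ``fclr = 1 - exp(-f_p * PS / F_plasma)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .physiology import OrganSpec

__all__ = [
    "HlsParams",
    "EcsParams",
    "hls_partition",
    "hls_partition_max",
    "apparent_blood_lipid_fraction",
    "ecs_partition",
    "organ_distribution_volume",
    "adipose_time_constant",
    "max_washout_time_constant",
    "extraction_fraction",
    "fclr_from_permeability",
]

#: Default apparent blood lipid fraction.  The directly measured blood
#: lipid fraction is about 0.005, but plasma protein binding adds to the
#: apparent blood binding; 0.015 (the vein/artery row of the parameter
#: table) is the default starting estimate.
DEFAULT_BLOOD_LIPID_FRACTION = 0.015


@dataclass(frozen=True)
class HlsParams:
    """Physicochemical parameters of a highly lipid-soluble solute.

    ``free_plasma_fraction``, when given, overrides ``f_l_blood`` with the
    apparent blood lipid fraction that reproduces the measured free
    fraction (see :func:`apparent_blood_lipid_fraction`).
    """

    p_lw: float
    f_l_blood: float = DEFAULT_BLOOD_LIPID_FRACTION
    free_plasma_fraction: float | None = None

    def __post_init__(self) -> None:
        if not self.p_lw > 0:
            raise ValueError(f"p_lw must be > 0, got {self.p_lw}")
        if not 0.0 < self.f_l_blood < 1.0:
            raise ValueError(f"f_l_blood must be in (0,1), got {self.f_l_blood}")
        if self.free_plasma_fraction is not None and not 0.0 < self.free_plasma_fraction <= 1.0:
            raise ValueError("free_plasma_fraction must be in (0,1]")

    @property
    def effective_f_l_blood(self) -> float:
        if self.free_plasma_fraction is not None:
            return apparent_blood_lipid_fraction(self.p_lw, self.free_plasma_fraction)
        return self.f_l_blood


@dataclass(frozen=True)
class EcsParams:
    """Parameters of an extracellular solute.

    ``fclr_muscle`` is the single-pass muscle extraction fraction
    (``None`` or 1.0 means infinite capillary permeability, i.e. the
    flow-limited model).  Other tissues get ``fclr_muscle`` times the
    per-tissue ratio in ``fclr_ratios`` (default 1.0 for every exchanging
    tissue).
    """

    f_p: float
    fclr_muscle: float | None = None
    fclr_ratios: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.f_p <= 1.0:
            raise ValueError(f"f_p must be in (0,1], got {self.f_p}")
        if self.fclr_muscle is not None and not 0.0 < self.fclr_muscle <= 1.0:
            raise ValueError(f"fclr_muscle must be in (0,1], got {self.fclr_muscle}")
        if self.fclr_ratios is not None:
            for name, r in self.fclr_ratios.items():
                if r <= 0:
                    raise ValueError(f"fclr ratio for {name} must be > 0, got {r}")


def hls_partition(p_lw: float, f_l_tissue: float, f_l_blood: float) -> float:
    """Tissue/blood partition coefficient of an HLS solute.

    Each phase is treated as lipid plus water in proportion to its lipid
    fraction, with the solute partitioned ``p_lw``-fold into lipid.
    ``p_lw = inf`` is accepted and returns the saturated ratio
    ``f_l_tissue / f_l_blood`` (error if ``f_l_blood`` is 0).
    """
    if not 0.0 <= f_l_tissue <= 1.0 or not 0.0 <= f_l_blood <= 1.0:
        raise ValueError("lipid fractions must be in [0,1]")
    if math.isinf(p_lw):
        if f_l_blood == 0.0:
            raise ValueError("p_lw = inf with f_l_blood = 0 is an undefined limit")
        return f_l_tissue / f_l_blood
    if not p_lw > 0:
        raise ValueError(f"p_lw must be > 0, got {p_lw}")
    return (f_l_tissue * p_lw + (1.0 - f_l_tissue)) / (f_l_blood * p_lw + (1.0 - f_l_blood))


def hls_partition_max(f_l_tissue: float, f_l_blood: float) -> float:
    """Saturation value of the HLS partition for very large ``p_lw``:
    ``f_l_tissue / f_l_blood``."""
    if f_l_blood <= 0:
        raise ValueError(f"f_l_blood must be > 0, got {f_l_blood}")
    return f_l_tissue / f_l_blood


def apparent_blood_lipid_fraction(p_lw: float, free_plasma_fraction: float) -> float:
    """Apparent blood lipid fraction implied by a measured free plasma fraction.

    The free (aqueous) fraction of the blood content is
    ``(1 - f_L) / (f_L * P + (1 - f_L))``; solving for ``f_L`` given the
    measured free fraction yields
    ``f_L = (1 - f_p) / (P * f_p + (1 - f_p))``.  This folds albumin and
    other plasma binding into an equivalent lipid phase.
    """
    if not 0.0 < free_plasma_fraction <= 1.0:
        raise ValueError("free_plasma_fraction must be in (0,1]")
    if not p_lw > 0:
        raise ValueError("p_lw must be > 0")
    fp = free_plasma_fraction
    return (1.0 - fp) / (p_lw * fp + (1.0 - fp))


def ecs_partition(f_p: float, k_alb: float) -> float:
    """Interstitial/plasma partition coefficient of an ECS solute:
    ``K_EC = f_p + (1 - f_p) * k_alb``.

    At ``f_p = 1`` (no albumin binding) the interstitium simply matches
    plasma (``K_EC = 1``); at ``f_p = 0`` (very high affinity binding) the
    solute tracks albumin and ``K_EC = k_alb``.
    """
    if not 0.0 <= f_p <= 1.0:
        raise ValueError(f"f_p must be in [0,1], got {f_p}")
    if k_alb < 0:
        raise ValueError(f"k_alb must be >= 0, got {k_alb}")
    return f_p + (1.0 - f_p) * k_alb


def organ_distribution_volume(
    organ: OrganSpec,
    partition: float,
    mode: str,
    *,
    hematocrit: float | None = None,
    blood_volume: float = 0.0,
) -> float:
    """Effective distribution volume (liters) of one organ.

    HLS mode: ``V = V_blood + K * V_tissue`` with the organ's whole volume
    as tissue (per-organ capillary blood defaults to 0; the vein and
    artery compartments carry the blood).  ECS mode: plasma sub-volume
    plus ``K_EC`` times the anatomic interstitial volume
    (``ecf_fraction * organ volume``); an organ with no interstitium
    (brain) contributes its plasma sub-volume only.
    """
    if partition < 0:
        raise ValueError("partition must be >= 0")
    if mode in ("hls", "volatile"):
        return blood_volume + partition * organ.volume
    if mode == "ecs":
        if hematocrit is None:
            plasma = blood_volume
        else:
            plasma = blood_volume * (1.0 - hematocrit)
        return plasma + partition * organ.ecf_fraction * organ.volume
    raise ValueError(f"unknown mode '{mode}'")


def adipose_time_constant(weight: float, k_adipose: float, perfusion: float) -> float:
    """Perfusion-limited equilibration time constant of a well-mixed
    adipose depot, minutes.

    ``T = (weight * K) / (weight * perfusion) = K / perfusion``; the
    weight cancels but is kept in the signature to mirror the defining
    ratio of capacity to flow.
    """
    if perfusion <= 0:
        raise ValueError("perfusion must be > 0 (zero flow gives an infinite time constant)")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    return (weight * k_adipose) / (weight * perfusion)


def max_washout_time_constant(f_l_adipose: float, f_l_blood: float, perfusion: float) -> float:
    """Longest possible flow-limited adipose washout time constant, minutes.

    Obtained by substituting the saturated partition
    ``f_l_adipose / f_l_blood`` into ``T = K / perfusion``.  However large
    the lipid/water partition, a flow-limited depot cannot wash out more
    slowly than this; year-scale persistence of extreme lipophiles must
    therefore be metabolism-limited, not distribution-limited.
    """
    if f_l_blood <= 0 or perfusion <= 0:
        raise ValueError("f_l_blood and perfusion must be > 0")
    return f_l_adipose / (f_l_blood * perfusion)


def extraction_fraction(c_arterial: float, c_venous: float, c_tissue: float) -> float:
    """Single-pass capillary extraction fraction
    ``fclr = (c_A - c_v) / (c_A - c_t)`` from free concentrations.

    ``fclr = 1`` when the venous blood leaves equilibrated with tissue
    (infinite permeability); ``fclr = 0`` when it leaves unchanged (zero
    permeability).
    """
    if c_arterial == c_tissue:
        raise ValueError("extraction fraction undefined when c_arterial == c_tissue")
    return (c_arterial - c_venous) / (c_arterial - c_tissue)


def fclr_from_permeability(f_p: float, ps: float, plasma_flow: float) -> float:
    """Crone-Renkin extraction fraction ``1 - exp(-f_p * PS / F_plasma)``.

    ``ps`` is the capillary permeability-surface-area product of the free
    solute and ``plasma_flow`` the tissue plasma flow, in matching units
    (e.g. both ml/min/100 g).  Only the free fraction ``f_p`` exchanges,
    so tight albumin binders can become capillary-limited even when the
    unbound molecule is highly permeant.  ``ps = inf`` returns exactly 1.
    """
    if not 0.0 < f_p <= 1.0:
        raise ValueError(f"f_p must be in (0,1], got {f_p}")
    if ps < 0:
        raise ValueError(f"ps must be >= 0, got {ps}")
    if plasma_flow <= 0:
        raise ValueError(f"plasma_flow must be > 0, got {plasma_flow}")
    if math.isinf(ps):
        return 1.0
    return 1.0 - math.exp(-f_p * ps / plasma_flow)
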