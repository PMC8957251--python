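"""Standard-human physiology: organ parameter table, circulation topology,
and body-composition scaling.

The body is a closed circulation of well-stirred compartments.  Every tissue
sits in parallel between the arterial and venous blood pools except the
portal bed (GI tract, spleen, pancreas), whose effluent perfuses the liver,
and the lung, which sits in series between vein and artery and receives the
whole cardiac output.  Units are minutes, liters, and kilograms throughout;
blood density is taken as 1 kg/l so organ weights double as volumes.

The default parameter set describes a 70 kg human with 20 % body fat.
Adipose tissue is split into two equal-weight compartments with fast
(0.074 l/min/kg) and slow (0.01408 l/min/kg) perfusion: this perfusion
heterogeneity is what produces the multi-day terminal washout phase of
lipophilic solutes and is required to reproduce long-time anesthetic
washout data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

__all__ = [
    "OrganSpec",
    "BodyModel",
    "load_parameter_table",
    "default_body",
    "scale_body",
    "cardiac_output",
    "VEIN",
    "ARTERY",
    "LIVER",
    "PORTAL",
    "KIDNEY",
    "BRAIN",
    "LUNG",
    "BONE",
    "ADIPOSE",
    "ADIPOSE_SLOW",
    "LUNG_PERFUSION_SENTINEL",
    "DEFAULT_HEMATOCRIT",
]

VEIN = "vein"
ARTERY = "artery"
LIVER = "liver"
PORTAL = "portal"
KIDNEY = "kidney"
BRAIN = "brain"
LUNG = "lung"
BONE = "bone"
ADIPOSE = "adipose"
ADIPOSE_SLOW = "adipose 2"

#: Sentinel perfusion value in the parameter table meaning "receives the
#: whole cardiac output" -- the lung is in series with the vein, so a
#: per-kg perfusion is meaningless for it.
LUNG_PERFUSION_SENTINEL = -1.0

#: Default hematocrit used to convert blood flow to plasma flow for
#: extracellular solutes.  Exposed as a BodyModel field.
DEFAULT_HEMATOCRIT = 0.45

_TABLE_COLUMNS = [
    "organ",
    "weight_kg",
    "perfusion_l_min_kg",
    "lipid_fraction",
    "ecf_fraction",
    "k_alb",
]
_N_ROWS = 15


@dataclass(frozen=True)
class OrganSpec:
    """One organ of the circulation.

    Parameters
    ----------
    name
        Organ identifier (e.g. ``"muscle"``).
    weight
        Organ weight in kg (also its volume in liters, density 1 kg/l).
    perfusion
        Blood flow per unit mass, l/min/kg.  ``-1.0`` is the lung
        sentinel (receives total cardiac output); bone carries 0.
    lipid_fraction
        Fraction of the organ that is lipid, in [0, 1].
    ecf_fraction
        Fraction of the (non-lipid) organ weight that is extracellular
        fluid, in [0, 1].
    k_alb
        Ratio of interstitial to plasma albumin concentration; ``None``
        for the pure blood pools (vein, artery).
    """

    name: str
    weight: float
    perfusion: float
    lipid_fraction: float
    ecf_fraction: float
    k_alb: float | None = None

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(f"{self.name}: weight must be >= 0, got {self.weight}")
        if self.perfusion < 0 and self.perfusion != LUNG_PERFUSION_SENTINEL:
            raise ValueError(
                f"{self.name}: perfusion must be >= 0 (or the lung sentinel "
                f"{LUNG_PERFUSION_SENTINEL}), got {self.perfusion}"
            )
        for attr in ("lipid_fraction", "ecf_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr} must be in [0,1], got {v}")
        if self.k_alb is not None and (math.isnan(self.k_alb) or self.k_alb < 0):
            raise ValueError(f"{self.name}: k_alb must be >= 0 or None, got {self.k_alb}")

    @property
    def volume(self) -> float:
        """Organ volume in liters (density 1 kg/l)."""
        return self.weight

    @property
    def blood_flow(self) -> float:
        """Absolute blood flow through the organ, l/min (lung excluded)."""
        if self.perfusion == LUNG_PERFUSION_SENTINEL:
            raise ValueError("lung flow equals cardiac output; use cardiac_output()")
        return self.weight * self.perfusion


@dataclass(frozen=True)
class BodyModel:
    """The organ set plus circulation topology and composition.

    Topology is fixed by organ names: all organs are parallel between
    artery and vein, except ``portal`` (effluent feeds the liver) and
    ``lung`` (in series: vein -> lung -> artery).
    """

    organs: tuple[OrganSpec, ...]
    hematocrit: float = DEFAULT_HEMATOCRIT
    nominal_weight: float = 70.0
    fat_fraction: float = 0.20

    def __post_init__(self) -> None:
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate organ names")
        for required in (VEIN, ARTERY):
            if names.count(required) != 1:
                raise ValueError(f"body must contain exactly one '{required}' compartment")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError(f"hematocrit must be in (0,1), got {self.hematocrit}")

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(f"no organ '{name}'; available: {', '.join(self.organ_names)}")

    @property
    def organ_names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.organs)

    @property
    def total_weight(self) -> float:
        return sum(o.weight for o in self.organs)

    @property
    def adipose_names(self) -> tuple[str, ...]:
        return tuple(n for n in (ADIPOSE, ADIPOSE_SLOW) if n in self.organ_names)

    def with_organ(self, spec: OrganSpec) -> "BodyModel":
        """Return a copy with the organ of the same name replaced."""
        if spec.name not in self.organ_names:
            raise KeyError(f"no organ '{spec.name}' to replace")
        organs = tuple(spec if o.name == spec.name else o for o in self.organs)
        return replace(self, organs=organs)

    def exchanging_organs(self) -> tuple[OrganSpec, ...]:
        """Organs that exchange solute with blood: everything except the
        blood pools and unperfused inert mass (bone)."""
        return tuple(
            o
            for o in self.organs
            if o.name not in (VEIN, ARTERY) and o.perfusion != 0.0
        )

    def parallel_organs(self) -> tuple[OrganSpec, ...]:
        """Exchanging organs on the systemic (parallel) side, i.e. all
        except the in-series lung."""
        return tuple(o for o in self.exchanging_organs() if o.name != LUNG)


def load_parameter_table() -> pd.DataFrame:
    """Load the standard-human organ parameter table from the packaged CSV.

    Validates column names and row count; ``k_alb`` is NaN for the blood
    pools.
    """
    with resources.files("pbpksim.data").joinpath("standard_human.csv").open() as fh:
        table = pd.read_csv(fh, na_values=["NA"])
    if list(table.columns) != _TABLE_COLUMNS:
        raise ValueError(f"parameter table columns must be {_TABLE_COLUMNS}, got {list(table.columns)}")
    if len(table) != _N_ROWS:
        raise ValueError(f"parameter table must have {_N_ROWS} rows, got {len(table)}")
    return table


def default_body(hematocrit: float = DEFAULT_HEMATOCRIT) -> BodyModel:
    """The standard 70 kg, 20 % body-fat human.

    All organ weights, perfusions, lipid fractions, ECF fractions, and
    interstitial/plasma albumin ratios come from the packaged parameter
    table.  The organ weights sum to 70 kg (within 0.1 kg).
    """
    table = load_parameter_table()
    organs = tuple(
        OrganSpec(
            name=row.organ,
            weight=float(row.weight_kg),
            perfusion=float(row.perfusion_l_min_kg),
            lipid_fraction=float(row.lipid_fraction),
            ecf_fraction=float(row.ecf_fraction),
            k_alb=None if pd.isna(row.k_alb) else float(row.k_alb),
        )
        for row in table.itertuples(index=False)
    )
    body = BodyModel(organs=organs, hematocrit=hematocrit, nominal_weight=70.0, fat_fraction=0.20)
    if abs(body.total_weight - body.nominal_weight) > 0.1:
        raise ValueError(
            f"parameter table weights sum to {body.total_weight:.3f} kg, "
            f"expected {body.nominal_weight} within 0.1 kg"
        )
    return body


def scale_body(body: BodyModel, total_weight: float, fat_fraction: float) -> BodyModel:
    """Rescale a body template to a subject's weight and fat fraction.

    The two adipose compartments are kept at equal weight ``w`` chosen so
    that their lipid content matches the whole-body fat mass:
    ``2 w * lipid_fraction(adipose) = fat_fraction * total_weight``.
    All non-adipose organs keep the template values -- the standard-human
    tissue parameters are assumed to extrapolate to the scaled subject,
    which is the main caveat of this scaling.  Vein and artery blood
    volumes are likewise kept fixed.

    Raises
    ------
    ValueError
        If ``fat_fraction`` is outside (0, 0.7), ``total_weight <= 0``, or
        the implied adipose plus blood mass exceeds the total weight.
    """
    if total_weight <= 0:
        raise ValueError(f"total_weight must be > 0, got {total_weight}")
    if not 0.0 < fat_fraction < 0.7:
        raise ValueError(f"fat_fraction must be in (0, 0.7), got {fat_fraction}")
    adipose_names = body.adipose_names
    if len(adipose_names) != 2:
        raise ValueError("body template must carry two adipose compartments")
    f_l = body.organ(adipose_names[0]).lipid_fraction
    if f_l <= 0:
        raise ValueError("adipose lipid_fraction must be > 0 to scale by fat fraction")
    w_each = fat_fraction * total_weight / (2.0 * f_l)
    blood = body.organ(VEIN).weight + body.organ(ARTERY).weight
    if 2.0 * w_each + blood > total_weight:
        raise ValueError(
            f"fat_fraction {fat_fraction} implies {2 * w_each:.1f} kg adipose, "
            f"which with {blood:.1f} kg blood exceeds the {total_weight} kg total"
        )
    out = body
    for name in adipose_names:
        out = out.with_organ(replace(out.organ(name), weight=w_each))
    return replace(out, nominal_weight=total_weight, fat_fraction=fat_fraction)


def cardiac_output(body: BodyModel) -> float:
    """Total cardiac output in l/min.

    Sum of weight x perfusion over the parallel systemic tissues, counting
    the portal -> liver series path once (the liver row's own perfusion is
    its hepatic-artery supply; the portal flow reaches the liver after the
    portal bed and is already counted there).  By flow balance this equals
    the vein and lung throughput.
    """
    return sum(
        o.weight * o.perfusion
        for o in body.organs
        if o.name not in (VEIN, ARTERY, LUNG)
    )
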