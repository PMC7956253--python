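"""Mouse circulatory anatomy consumed by the whole-body PBPK core.

The model body is a set of perfused organ compartments wired in parallel
between an arterial and a venous blood pool, with the lung in series
carrying total cardiac output.  Each organ is described by three
dimensionless fractions — its share of body weight, the capillary share of
its own volume, and its share of cardiac output — from which absolute
volumes (mL) and flows (mL/h) are derived at tissue density 1 g/mL.

The packaged default set (``data/mouse_default.yaml``) is assembled from
standard rodent reference values; every field can be overridden through a
YAML/JSON config document.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

#: canonical organ order used throughout the package
ORGANS = ("lung", "liver", "spleen", "kidney", "tumour", "heart", "rest_of_body")

#: organs whose flow fractions must partition cardiac output (lung is in series)
PARALLEL_ORGANS = tuple(o for o in ORGANS if o != "lung")

FLOW_SUM_TOL = 1e-6
ML_PER_KG = 1000.0  # tissue density 1 g/mL


class PhysiologyError(ValueError):
    """Raised when a physiology config is inconsistent or incomplete."""


@dataclass(frozen=True)
class OrganPhysiology:
    """Fractional description of one perfused organ."""

    name: str
    volume_fraction: float        # fraction of body weight
    blood_volume_fraction: float  # capillary share of organ volume (VBloodC)
    flow_fraction: float          # share of cardiac output

    def __post_init__(self) -> None:
        for f in ("volume_fraction", "blood_volume_fraction", "flow_fraction"):
            v = getattr(self, f)
            if not (0.0 < v < 1.0) and not (self.name == "lung" and f == "flow_fraction" and v == 1.0):
                raise PhysiologyError(
                    f"{self.name}.{f} = {v!r} outside (0, 1)"
                )


@dataclass(frozen=True)
class Physiology:
    """Whole-body anatomy with derived absolute volumes and flows."""

    body_weight_kg: float
    cardiac_output_ml_h: float
    venous_volume_ml: float
    arterial_volume_ml: float
    organs: Mapping[str, OrganPhysiology]
    tumour_volume_ml: float
    allometric_exponent: float = 0.75
    portal_routing: bool = False

    # -- derived quantities ------------------------------------------------
    def organ_volume_ml(self, name: str) -> float:
        """Total organ volume V_organ = volume_fraction x BW (density 1 g/mL)."""
        return self.organs[name].volume_fraction * self.body_weight_kg * ML_PER_KG

    def capillary_volume_ml(self, name: str) -> float:
        """Capillary blood volume V_V of the organ."""
        return self.organs[name].blood_volume_fraction * self.organ_volume_ml(name)

    def tissue_volume_ml(self, name: str) -> float:
        """Interstitial tissue volume V_T = V_organ - V_V."""
        return self.organ_volume_ml(name) - self.capillary_volume_ml(name)

    def flow_ml_h(self, name: str) -> float:
        """Blood flow Q to the organ (lung carries total cardiac output)."""
        return self.organs[name].flow_fraction * self.cardiac_output_ml_h

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        blood_pool = self.venous_volume_ml + self.arterial_volume_ml
        return {
            "body_weight_kg": self.body_weight_kg,
            "cardiac_output_ml_h": self.cardiac_output_ml_h,
            "allometric_exponent": self.allometric_exponent,
            "blood_pool_volume_fraction": blood_pool / (self.body_weight_kg * ML_PER_KG),
            "venous_fraction": self.venous_volume_ml / blood_pool,
            "tumour_volume_ml": self.tumour_volume_ml,
            "portal_routing": self.portal_routing,
            "organs": {
                name: {
                    "volume_fraction": o.volume_fraction,
                    "blood_volume_fraction": o.blood_volume_fraction,
                    "flow_fraction": o.flow_fraction,
                }
                for name, o in self.organs.items()
            },
        }


def _default_config() -> dict:
    text = (
        importlib.resources.files("phagopbpk.data")
        .joinpath("mouse_default.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def load_physiology(source: str | Path | Mapping | None = None) -> Physiology:
    """Build a validated :class:`Physiology` from a config document.

    ``source`` may be a mapping, a path to a YAML/JSON file, or ``None`` for
    the packaged default mouse.  Partial mappings override the default
    field-by-field (organ entries replace whole organs).
    """
    cfg = _default_config()
    if source is not None:
        if isinstance(source, (str, Path)):
            user = yaml.safe_load(Path(source).read_text())
        else:
            user = dict(source)
        organs_override = user.pop("organs", {})
        cfg.update(user)
        for name, entry in organs_override.items():
            merged = dict(cfg["organs"].get(name, {}))
            merged.update(entry)
            cfg["organs"][name] = merged

    bw = float(cfg["body_weight_kg"])
    if bw <= 0:
        raise PhysiologyError(f"body_weight_kg = {bw} must be positive")
    co = float(cfg["cardiac_output_ml_h"])
    if co <= 0:
        raise PhysiologyError(f"cardiac_output_ml_h = {co} must be positive")

    tumour_volume = float(cfg["tumour_volume_ml"])
    if tumour_volume <= 0:
        raise PhysiologyError(f"tumour_volume_ml = {tumour_volume} must be positive")

    organs: dict[str, OrganPhysiology] = {}
    for name in ORGANS:
        if name not in cfg["organs"]:
            raise PhysiologyError(f"missing organ {name!r} in physiology config")
        entry = cfg["organs"][name]
        if name == "tumour" and "volume_fraction" not in entry:
            entry = dict(entry)
            entry["volume_fraction"] = tumour_volume / (bw * ML_PER_KG)
        organs[name] = OrganPhysiology(name=name, **entry)

    flow_sum = sum(organs[o].flow_fraction for o in PARALLEL_ORGANS)
    if abs(flow_sum - 1.0) > FLOW_SUM_TOL:
        raise PhysiologyError(
            f"flow fractions of parallel organs sum to {flow_sum:.8f}, expected 1"
        )
    blood_pool_fraction = float(cfg["blood_pool_volume_fraction"])
    vol_sum = sum(o.volume_fraction for o in organs.values()) + blood_pool_fraction
    if vol_sum > 1.0 + 1e-9:
        raise PhysiologyError(
            f"volume fractions (organs + blood pool) sum to {vol_sum:.6f} > 1"
        )

    blood_pool_ml = blood_pool_fraction * bw * ML_PER_KG
    venous_fraction = float(cfg["venous_fraction"])
    if not (0.0 < venous_fraction < 1.0):
        raise PhysiologyError(f"venous_fraction = {venous_fraction} outside (0, 1)")

    return Physiology(
        body_weight_kg=bw,
        cardiac_output_ml_h=co,
        venous_volume_ml=venous_fraction * blood_pool_ml,
        arterial_volume_ml=(1.0 - venous_fraction) * blood_pool_ml,
        organs=organs,
        tumour_volume_ml=tumour_volume,
        allometric_exponent=float(cfg.get("allometric_exponent", 0.75)),
        portal_routing=bool(cfg.get("portal_routing", False)),
    )


def scale_physiology(phys: Physiology, new_bw_kg: float) -> Physiology:
    """Rescale a physiology to a new body weight.

    Volumes (including the tumour and the blood pools) scale linearly with
    body weight; cardiac output — hence every flow — scales with
    (BW'/BW)**allometric_exponent.  Fractions are invariant.
    """
    if new_bw_kg <= 0:
        raise PhysiologyError(f"new body weight {new_bw_kg} must be positive")
    ratio = new_bw_kg / phys.body_weight_kg
    return replace(
        phys,
        body_weight_kg=new_bw_kg,
        cardiac_output_ml_h=phys.cardiac_output_ml_h * ratio ** phys.allometric_exponent,
        venous_volume_ml=phys.venous_volume_ml * ratio,
        arterial_volume_ml=phys.arterial_volume_ml * ratio,
        tumour_volume_ml=phys.tumour_volume_ml * ratio,
    )
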