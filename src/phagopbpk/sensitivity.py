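"""Two-stage parameter sensitivity analysis and K_max ratio reporting.

Stage one screens every scalar parameter by multiplying and dividing it by 2
and recording the largest relative change of an organ's amount trajectory
over the first 24 h.  Stage two quantifies influence by the relative
sensitivity coefficient

    RSC = (dAUC / AUC) / (dp / p)

computed as a forward difference with a +1% perturbation of the parameter,
where AUC is the trapezoidal area under the compartment's concentration
curve over 0-24 h.  |RSC| > 0.5 classifies a parameter as highly sensitive;
blood is excluded from reports by default.  A central-difference evaluator
is provided as a validation oracle for the step-size choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .pbpk_core import FormulationParams, ModelError, ModelSpec
from .physiology import ORGANS, Physiology, load_physiology, scale_physiology
from .simulate import SimulationResult, compute_auc, simulate

RSC_THRESHOLD = 0.5
DEFAULT_T_END = 24.0
DEFAULT_DELTA = 0.01

#: per-organ kinetic parameters eligible for perturbation
ORGAN_PARAMETERS = ("P", "PAC", "K_max", "K_50", "n", "K_out")
#: formulation- or physiology-level scalar parameters
GLOBAL_PARAMETERS = ("dose", "BW", "K_bile", "K_urine")


class SensitivityError(ValueError):
    pass


@dataclass
class SensitivityReport:
    """RSC matrix with its threshold classification."""

    rsc: pd.DataFrame              # index parameter, columns compartment
    threshold: float
    highly_sensitive: list[tuple[str, str]]   # (parameter, compartment)
    skipped: list[str]             # zero-valued parameters left out

    def classified(self, parameter: str, compartment: str) -> bool:
        return abs(float(self.rsc.loc[parameter, compartment])) > self.threshold

    def to_csv(self, path) -> None:
        self.rsc.to_csv(path)


def _perturb(params: FormulationParams, phys: Physiology, dose_mg: float,
             parameter: str, factor: float):
    """Return (params, phys, dose) with one named parameter scaled by factor.

    Names: 'dose', 'BW', 'K_bile', 'K_urine', '<organ>.<kinetic>', or
    '<organ>.VBloodC' (capillary blood fraction).  A BW change rescales
    volumes linearly and flows allometrically, the documented semantics of
    body-weight perturbation.
    """
    if parameter == "dose":
        return params, phys, dose_mg * factor
    if parameter == "BW":
        return params, scale_physiology(phys, phys.body_weight_kg * factor), dose_mg
    if parameter in ("K_bile", "K_urine"):
        return params.with_value(None, parameter, getattr(params, parameter) * factor), phys, dose_mg
    if "." not in parameter:
        raise SensitivityError(f"unknown parameter {parameter!r}")
    organ, pname = parameter.split(".", 1)
    if organ not in ORGANS:
        raise SensitivityError(f"unknown organ in parameter {parameter!r}")
    if pname == "VBloodC":
        entry = phys.organs[organ]
        new = float(np.clip(entry.blood_volume_fraction * factor, 1e-9, 1 - 1e-9))
        cfg = phys.to_dict()
        cfg["organs"][organ]["blood_volume_fraction"] = new
        return params, load_physiology(cfg), dose_mg
    if pname not in ORGAN_PARAMETERS:
        raise SensitivityError(f"unknown kinetic parameter {pname!r}")
    base = getattr(params.organs[organ], pname)
    return params.with_value(organ, pname, base * factor), phys, dose_mg


def _base_value(params: FormulationParams, phys: Physiology, dose_mg: float,
                parameter: str) -> float:
    if parameter == "dose":
        return dose_mg
    if parameter == "BW":
        return phys.body_weight_kg
    if parameter in ("K_bile", "K_urine"):
        return getattr(params, parameter)
    organ, pname = parameter.split(".", 1)
    if pname == "VBloodC":
        return phys.organs[organ].blood_volume_fraction
    return getattr(params.organs[organ], pname)


def screen_parameters(
    spec: ModelSpec,
    params: FormulationParams,
    phys: Physiology,
    dose_mg: float,
    organ: str,
    parameters: list[str] | None = None,
    t_end: float = DEFAULT_T_END,
) -> pd.DataFrame:
    """x2 / /2 screening of parameters against one organ's amount trajectory.

    Returns a table with, per parameter, the maximum relative deviation of
    the organ's total amount over [0, t_end] under doubling and halving.
    Zero-valued parameters are reported with deviation 0 and a note.
    """
    if parameters is None:
        parameters = all_parameters(params)
    base = simulate(spec, params, phys, dose_mg=dose_mg, t_end=t_end)
    ref = base.organ_amounts(organ)
    scale = np.max(np.abs(ref))
    if scale == 0:
        raise SensitivityError(f"organ {organ!r} trajectory identically zero")
    rows = []
    for name in parameters:
        v0 = _base_value(params, phys, dose_mg, name)
        if v0 == 0:
            rows.append({"parameter": name, "max_dev_x2": 0.0,
                         "max_dev_div2": 0.0, "note": "zero-valued, unchanged"})
            continue
        devs = {}
        for label, factor in (("max_dev_x2", 2.0), ("max_dev_div2", 0.5)):
            p2, ph2, d2 = _perturb(params, phys, dose_mg, name, factor)
            pert = simulate(spec, p2, ph2, d2, t_end=t_end)
            devs[label] = float(np.max(np.abs(pert.organ_amounts(organ) - ref)) / scale)
        rows.append({"parameter": name, **devs, "note": ""})
    return pd.DataFrame(rows).set_index("parameter")


def rsc(
    spec: ModelSpec,
    params: FormulationParams,
    phys: Physiology,
    dose_mg: float,
    parameter: str,
    compartment: str,
    t_end: float = DEFAULT_T_END,
    delta: float = DEFAULT_DELTA,
    central: bool = False,
    _base_result: SimulationResult | None = None,
) -> float:
    """Relative sensitivity coefficient of a compartment's AUC to one parameter.

    Forward difference at +delta (default +1%); ``central=True`` switches to
    the central-difference oracle used for step-size validation.  Undefined
    (raises) for zero-valued base parameters.
    """
    v0 = _base_value(params, phys, dose_mg, parameter)
    if v0 == 0:
        raise SensitivityError(f"RSC undefined for zero-valued parameter {parameter!r}")
    if central:
        up = _perturb(params, phys, dose_mg, parameter, 1.0 + delta)
        dn = _perturb(params, phys, dose_mg, parameter, 1.0 - delta)
        auc_up = compute_auc(simulate(spec, *up, t_end=t_end), compartment, 0.0, t_end)
        auc_dn = compute_auc(simulate(spec, *dn, t_end=t_end), compartment, 0.0, t_end)
        base = _base_result or simulate(spec, params, phys, dose_mg, t_end=t_end)
        auc0 = compute_auc(base, compartment, 0.0, t_end)
        return float((auc_up - auc_dn) / auc0 / (2.0 * delta))
    base = _base_result or simulate(spec, params, phys, dose_mg, t_end=t_end)
    auc0 = compute_auc(base, compartment, 0.0, t_end)
    if auc0 == 0:
        raise SensitivityError(f"base AUC of {compartment!r} is zero")
    pert = _perturb(params, phys, dose_mg, parameter, 1.0 + delta)
    auc1 = compute_auc(simulate(spec, *pert, t_end=t_end), compartment, 0.0, t_end)
    return float((auc1 - auc0) / auc0 / delta)


def all_parameters(params: FormulationParams, include_physiology: bool = True) -> list[str]:
    """Canonical perturbable parameter list for a formulation."""
    names = ["dose", "BW"]
    if params.K_bile > 0:
        names.append("K_bile")
    if params.K_urine > 0:
        names.append("K_urine")
    for organ in ORGANS:
        for pname in ORGAN_PARAMETERS:
            names.append(f"{organ}.{pname}")
        if include_physiology:
            names.append(f"{organ}.VBloodC")
    return names


def sensitivity_report(
    spec: ModelSpec,
    params: FormulationParams,
    phys: Physiology,
    dose_mg: float,
    parameters: list[str] | None = None,
    compartments: list[str] | None = None,
    t_end: float = DEFAULT_T_END,
    delta: float = DEFAULT_DELTA,
    threshold: float = RSC_THRESHOLD,
) -> SensitivityReport:
    """Full RSC matrix with |RSC| > threshold classification.

    Blood is excluded from the default compartment list; zero-valued
    parameters are skipped and listed in the report's ``skipped`` field.
    """
    if parameters is None:
        parameters = all_parameters(params)
    base = simulate(spec, params, phys, dose_mg=dose_mg, t_end=t_end)
    if compartments is None:
        compartments = [c for c in base.compartments if c != "blood"]
    usable, skipped = [], []
    for name in parameters:
        if _base_value(params, phys, dose_mg, name) == 0:
            skipped.append(name)
        else:
            usable.append(name)
    mat = pd.DataFrame(index=usable, columns=compartments, dtype=float)
    for name in usable:
        pert = _perturb(params, phys, dose_mg, name, 1.0 + delta)
        pert_res = simulate(spec, *pert, t_end=t_end)
        for comp in compartments:
            auc0 = compute_auc(base, comp, 0.0, t_end)
            auc1 = compute_auc(pert_res, comp, 0.0, t_end)
            mat.loc[name, comp] = (auc1 - auc0) / auc0 / delta
    if not np.isfinite(mat.to_numpy(dtype=float)).all():
        raise SensitivityError("non-finite RSC encountered")
    hs = [
        (p, c)
        for p in mat.index
        for c in mat.columns
        if abs(float(mat.loc[p, c])) > threshold
    ]
    return SensitivityReport(rsc=mat, threshold=threshold,
                             highly_sensitive=hs, skipped=skipped)


def kmax_ratio(
    params_a: FormulationParams,
    params_b: FormulationParams,
    organ: str,
    decimals: int = 2,
) -> float:
    """Ratio of maximum phagocytic uptake rates K_max(a)/K_max(b) for an organ.

    Rounded half-up to ``decimals`` places to match conventional reporting.
    """
    if organ not in params_a.organs or organ not in params_b.organs:
        raise SensitivityError(f"organ {organ!r} missing from a formulation")
    denom = params_b.organs[organ].K_max
    if denom == 0:
        raise SensitivityError(f"zero K_max denominator for {organ!r}")
    ratio = params_a.organs[organ].K_max / denom
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(ratio)).quantize(q, rounding=ROUND_HALF_UP))


def kmax_ratio_table(formulations: dict[str, FormulationParams]) -> pd.DataFrame:
    """All pairwise per-organ K_max ratios across a set of formulations."""
    rows = []
    names = list(formulations)
    for a in names:
        for b in names:
            if a == b:
                continue
            for organ in ORGANS:
                rows.append({
                    "numerator": a, "denominator": b, "organ": organ,
                    "kmax_ratio": kmax_ratio(formulations[a], formulations[b], organ),
                })
    return pd.DataFrame(rows)
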