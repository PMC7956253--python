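"""Synthetic replicate-level biodistribution datasets from known parameters.

Emulates the study design behind the model: an IV bolus into tumour-bearing
mice, terminal sampling of 7 compartments at 0.083, 1, 4, 8, 24 and 72 h,
a few replicate animals per time point.  Measurement error is multiplicative
lognormal with a chosen coefficient of variation (the assay reports only
error bars, so the noise law is a documented assumption), parameterised
mean-unbiased: c_obs = c exp(eps), eps ~ N(-sigma^2/2, sigma^2) with
sigma^2 = ln(1 + CV^2), so E[c_obs] = c.  Values falling below the limit of
quantification (default 0.0039 mg/mL, the lower end of the assay calibration
ranges) are substituted by LLOQ/2 and flagged, mimicking fluorescence
calibration floors; they may alternatively be dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fit import ObservedDataset
from .pbpk_core import FormulationParams, ModelSpec, load_all_formulations
from .physiology import Physiology, load_physiology
from .simulate import predict_at, simulate

DEFAULT_TIMEPOINTS = (0.083, 1.0, 4.0, 8.0, 24.0, 72.0)
DEFAULT_COMPARTMENTS = ("blood", "heart", "liver", "spleen", "lung", "kidney", "tumour")


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class SynthDesign:
    """Sampling design and noise model of a synthetic study."""

    formulation: str
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    n_replicates: int = 3
    noise_cv: float = 0.2
    lloq: float = 0.0039       # mg/mL
    lloq_action: str = "substitute"   # or "drop"
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints)
        if tp.size == 0 or np.any(tp <= 0) or np.any(np.diff(tp) <= 0):
            raise DesignError("timepoints must be positive and strictly increasing")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise DesignError("noise_cv must be >= 0")
        if self.lloq_action not in ("substitute", "drop"):
            raise DesignError("lloq_action must be 'substitute' or 'drop'")


def generate_observed(
    design: SynthDesign,
    truth: FormulationParams,
    phys: Physiology | None = None,
    dose_mg: float = 2.0,
    spec: ModelSpec | None = None,
) -> ObservedDataset:
    """Simulate ground truth and draw noisy replicate measurements.

    Reproducible for a fixed design seed; with noise_cv = 0 the replicates
    equal the model predictions exactly.
    """
    phys = phys or load_physiology()
    spec = spec or ModelSpec(variant="PCs")
    t_end = max(design.timepoints)
    result = simulate(spec, truth, phys, dose_mg=dose_mg, t_end=t_end,
                      extra_times=design.timepoints)
    rng = np.random.default_rng(design.seed)
    sigma2 = np.log1p(design.noise_cv ** 2)
    sigma = np.sqrt(sigma2)

    rows = []
    for comp in design.compartments:
        clean = predict_at(result, np.asarray(design.timepoints), comp)
        for t, c in zip(design.timepoints, clean):
            if design.noise_cv > 0:
                eps = rng.normal(-sigma2 / 2.0, sigma, size=design.n_replicates)
                values = c * np.exp(eps)
            else:
                values = np.full(design.n_replicates, c)
            for rep, v in enumerate(values):
                censored = v < design.lloq
                if censored and design.lloq_action == "drop":
                    continue
                rows.append({
                    "time_h": t,
                    "compartment": comp,
                    "concentration_mg_ml": design.lloq / 2.0 if censored else v,
                    "replicate": rep,
                    "censored": censored,
                })
    data = pd.DataFrame(rows)
    metadata = {
        "formulation": truth.formulation_name,
        "dose_mg": dose_mg,
        "variant": spec.variant,
        "design": asdict(design),
        "seed": design.seed,
        "physiology": phys.to_dict(),
        "truth": _params_dict(truth),
    }
    return ObservedDataset(data=data, metadata=metadata)


def _params_dict(params: FormulationParams) -> dict:
    return {
        "formulation_name": params.formulation_name,
        "K_bile": params.K_bile,
        "K_urine": params.K_urine,
        "K1": params.K1,
        "K2": params.K2,
        "organs": {o: asdict(k) for o, k in params.organs.items()},
    }


def generate_fixture_suite(
    output_dir: str | Path,
    phys: Physiology | None = None,
    dose_mg: float = 2.0,
    noise_cv: float = 0.2,
    base_seed: int = 20210226,
) -> list[Path]:
    """One noisy and one noise-free dataset per packaged formulation.

    Each CSV carries a JSON manifest (seed, design, generating parameters)
    so recovery experiments can round-trip to their ground truth.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    phys = phys or load_physiology()
    paths = []
    for i, (name, truth) in enumerate(sorted(load_all_formulations().items())):
        slug = (
            name.replace("%", "pct").replace(" ", "").replace("-", "_").replace(".", "p")
        )
        for label, cv in (("noisy", noise_cv), ("noisefree", 0.0)):
            design = SynthDesign(formulation=name, noise_cv=cv,
                                 seed=(base_seed + i) % (2 ** 31))
            ds = generate_observed(design, truth, phys, dose_mg=dose_mg)
            path = output_dir / f"{slug}_{label}.csv"
            ds.to_csv(path)
            paths.append(path)
    return paths


def truth_from_manifest(metadata: dict) -> FormulationParams:
    """Rebuild the generating FormulationParams from a dataset manifest."""
    from .pbpk_core import OrganKinetics

    t = metadata["truth"]
    return FormulationParams(
        formulation_name=t["formulation_name"],
        organs={o: OrganKinetics(**k) for o, k in t["organs"].items()},
        K_bile=t["K_bile"], K_urine=t["K_urine"], K1=t["K1"], K2=t["K2"],
    )
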