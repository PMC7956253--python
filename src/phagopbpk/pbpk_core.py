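"""ODE right-hand sides for the phagocytosis (PCs) and EPR whole-body models.

Every organ carries three sub-compartments — capillary blood, interstitial
tissue, and a phagocytic-cell (PC) pool — exchanging as

    V_V dCV/dt = Q (CA - CV) - PA CV + PA C_T / P - k_up(t) CV V_V + K_out A_PC
    V_T dC_T/dt = PA CV - PA C_T / P
    dA_PC/dt    = k_up(t) CV V_V - K_out A_PC

with PA = PAC x Q and a time-dependent uptake rate constant given by a Hill
function of time, k_up(t) = K_max t^n / (K_50^n + t^n): phagocytes engulf
circulating particles fastest once activated and saturate as they fill.

Under the EPR variant the tumour is reduced to capillary blood plus an EPR
space exchanging by first-order extravasation (K1) and intravasation (K2):

    V_V dCV/dt = Q (CA - CV) - K1 CV V_V + K2 A_EPR
    dA_EPR/dt  = K1 CV V_V - K2 A_EPR

which is the PC organ with PA = 0, a constant uptake rate K1 and release K2;
the implementation exploits that correspondence so both variants share one
state layout and one mass-conserving assembly.

Biliary and urinary clearance (K_bile, K_urine) drain the liver and kidney
into cumulative eliminated-amount states, so the total of all states is the
administered dose at all times.  Amount units mg, volumes mL, time h.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .physiology import ORGANS, Physiology

L_TO_ML = 1000.0

#: kinetic parameter names carried per organ
KINETIC_FIELDS = ("P", "PAC", "K_max", "K_50", "n", "K_out")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class OrganKinetics:
    """Formulation-specific kinetic parameters of one organ.

    P is the tissue/plasma distribution coefficient, PAC the dimensionless
    permeability coefficient (PA = PAC x Q), (K_max, K_50, n) the Hill
    parameters of the time-dependent phagocytic uptake rate constant (1/h, h,
    dimensionless), and K_out the first-order release rate constant (1/h).
    """

    P: float
    PAC: float
    K_max: float
    K_50: float
    n: float
    K_out: float

    def __post_init__(self) -> None:
        for name in KINETIC_FIELDS:
            if getattr(self, name) < 0:
                raise ModelError(f"OrganKinetics.{name} = {getattr(self, name)} < 0")
        if self.PAC > 0 and self.P <= 0:
            raise ModelError("P must be positive where PAC > 0")


@dataclass(frozen=True)
class FormulationParams:
    """All kinetic parameters of one nanoparticle formulation.

    Clearances are in L/h as tabulated (converted internally); K1/K2 (1/h)
    only matter under the EPR tumour variant.
    """

    formulation_name: str
    organs: Mapping[str, OrganKinetics]
    K_bile: float = 0.0   # L/h, liver
    K_urine: float = 0.0  # L/h, kidney
    K1: float = 0.0       # 1/h, tumour extravasation (EPR variant)
    K2: float = 0.0       # 1/h, tumour intravasation (EPR variant)

    def __post_init__(self) -> None:
        missing = [o for o in ORGANS if o not in self.organs]
        if missing:
            raise ModelError(f"formulation {self.formulation_name!r} missing organs {missing}")
        if self.K_bile < 0 or self.K_urine < 0:
            raise ModelError("clearances must be >= 0")

    def with_value(self, organ: str, parameter: str, value: float) -> "FormulationParams":
        """Return a copy with one organ parameter (or clearance/K1/K2) replaced."""
        if organ is None or organ == "":
            return replace(self, **{parameter: value})
        organs = dict(self.organs)
        organs[organ] = replace(organs[organ], **{parameter: value})
        return replace(self, organs=organs)


@dataclass(frozen=True)
class ModelSpec:
    """Structural switches of the whole-body model."""

    variant: Literal["PCs", "EPR"] = "PCs"
    clearance_site: Literal["capillary", "tissue"] = "capillary"
    portal_routing: bool = False

    def __post_init__(self) -> None:
        if self.variant not in ("PCs", "EPR"):
            raise ModelError(f"unknown variant {self.variant!r}")
        if self.clearance_site not in ("capillary", "tissue"):
            raise ModelError(f"unknown clearance_site {self.clearance_site!r}")


# ---------------------------------------------------------------------------
# Hill uptake
# ---------------------------------------------------------------------------

def hill_uptake(k: OrganKinetics, t):
    """Time-dependent phagocytic uptake rate constant k_up(t), 1/h.

    k_up = K_max t^n / (K_50^n + t^n).  At t = 0 with n > 0 the rate is 0;
    with n = 0 the limit convention K_max/2 applies.  Accepts scalars or
    arrays; rejects negative times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ModelError("hill_uptake requires t >= 0")
    if k.n == 0:
        return np.broadcast_to(np.float64(0.5 * k.K_max), t.shape)[()] if t.ndim else np.float64(0.5 * k.K_max)
    tn = np.power(t, k.n)
    return k.K_max * tn / (k.K_50 ** k.n + tn)


# ---------------------------------------------------------------------------
# State layout and compiled model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateLayout:
    """Index map of the flat state vector.

    Order: venous, arterial, capillary amounts per organ, tissue amounts per
    organ, PC (or tumour-EPR) amounts per organ, cumulative bile- and
    urine-cleared amounts.  Under the EPR variant the tumour's tissue slot is
    structurally inert (stays 0) and its PC slot holds A_EPR.
    """

    organs: tuple[str, ...]

    @property
    def n_states(self) -> int:
        return 2 + 3 * len(self.organs) + 2

    @property
    def venous(self) -> int:
        return 0

    @property
    def arterial(self) -> int:
        return 1

    def cap(self, organ: str) -> int:
        return 2 + self.organs.index(organ)

    def tissue(self, organ: str) -> int:
        return 2 + len(self.organs) + self.organs.index(organ)

    def pc(self, organ: str) -> int:
        return 2 + 2 * len(self.organs) + self.organs.index(organ)

    @property
    def cap_slice(self) -> slice:
        return slice(2, 2 + len(self.organs))

    @property
    def tissue_slice(self) -> slice:
        m = len(self.organs)
        return slice(2 + m, 2 + 2 * m)

    @property
    def pc_slice(self) -> slice:
        m = len(self.organs)
        return slice(2 + 2 * m, 2 + 3 * m)

    @property
    def bile(self) -> int:
        return self.n_states - 2

    @property
    def urine(self) -> int:
        return self.n_states - 1


class CompiledModel:
    """Pre-assembled arrays for fast RHS evaluation of one model instance."""

    def __init__(self, spec: ModelSpec, params: FormulationParams, phys: Physiology):
        organs = tuple(o for o in ORGANS if o in phys.organs)
        for o in organs:
            if o not in params.organs:
                raise ModelError(f"unknown organ {o!r} in formulation {params.formulation_name!r}")
        if spec.variant == "EPR" and "tumour" not in organs:
            raise ModelError("EPR variant requires a tumour compartment")
        self.spec = spec
        self.params = params
        self.phys = phys
        self.layout = StateLayout(organs)

        m = len(organs)
        self.Q = np.array([phys.flow_ml_h(o) for o in organs])
        self.V_V = np.array([phys.capillary_volume_ml(o) for o in organs])
        self.V_T = np.array([phys.tissue_volume_ml(o) for o in organs])
        self.P = np.array([params.organs[o].P for o in organs])
        self.PA = np.array([params.organs[o].PAC for o in organs]) * self.Q
        self.K_max = np.array([params.organs[o].K_max for o in organs])
        self.K_50 = np.array([params.organs[o].K_50 for o in organs])
        self.n = np.array([params.organs[o].n for o in organs])
        self.K_out = np.array([params.organs[o].K_out for o in organs])

        self.i_lung = organs.index("lung") if "lung" in organs else -1
        self.i_liver = organs.index("liver") if "liver" in organs else -1
        self.i_kidney = organs.index("kidney") if "kidney" in organs else -1
        self.i_spleen = organs.index("spleen") if "spleen" in organs else -1
        self.i_tumour = organs.index("tumour") if "tumour" in organs else -1

        # EPR tumour: no transcapillary exchange; constant uptake K1, release K2
        self.const_up = np.full(m, np.nan)
        if spec.variant == "EPR":
            it = self.i_tumour
            self.PA[it] = 0.0
            self.const_up[it] = params.K1
            self.K_out[it] = params.K2

        self.k_bile_ml = params.K_bile * L_TO_ML
        self.k_urine_ml = params.K_urine * L_TO_ML
        self.Q_total = phys.cardiac_output_ml_h
        self.V_ven = phys.venous_volume_ml
        self.V_art = phys.arterial_volume_ml

        # P can be 0 only where PA is 0 (validated in OrganKinetics); guard division
        self.PA_over_P = np.where(self.PA > 0, self.PA / np.where(self.P > 0, self.P, 1.0), 0.0)

    def k_up(self, t: float) -> np.ndarray:
        """Per-organ uptake rate constants at time t (1/h)."""
        tn = np.power(t, self.n) if t > 0 else np.where(self.n == 0, 1.0, 0.0)
        k = self.K_max * tn / (np.power(self.K_50, self.n) + tn)
        const = ~np.isnan(self.const_up)
        if const.any():
            k = np.where(const, np.nan_to_num(self.const_up), k)
        return k

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        lay = self.layout
        A_cap = y[lay.cap_slice]
        A_tis = y[lay.tissue_slice]
        A_pc = y[lay.pc_slice]
        CV = A_cap / self.V_V
        CT = A_tis / self.V_T
        CA = y[lay.arterial] / self.V_art
        C_ven = y[lay.venous] / self.V_ven

        k_up = self.k_up(t)

        # inflow concentration seen by each organ's capillary bed
        c_in = np.full_like(CV, CA)
        if self.i_lung >= 0:
            c_in[self.i_lung] = C_ven

        inflow = self.Q * c_in
        outflow = self.Q * CV

        dcap = inflow - outflow - self.PA * CV + self.PA_over_P * CT \
            - k_up * A_cap + self.K_out * A_pc
        dtis = self.PA * CV - self.PA_over_P * CT
        dpc = k_up * A_cap - self.K_out * A_pc

        dy = np.empty_like(y)
        d_bile = d_urine = 0.0
        if self.i_liver >= 0 and self.k_bile_ml > 0:
            c_site = CV[self.i_liver] if self.spec.clearance_site == "capillary" else CT[self.i_liver]
            d_bile = self.k_bile_ml * c_site
            if self.spec.clearance_site == "capillary":
                dcap[self.i_liver] -= d_bile
            else:
                dtis[self.i_liver] -= d_bile
        if self.i_kidney >= 0 and self.k_urine_ml > 0:
            c_site = CV[self.i_kidney] if self.spec.clearance_site == "capillary" else CT[self.i_kidney]
            d_urine = self.k_urine_ml * c_site
            if self.spec.clearance_site == "capillary":
                dcap[self.i_kidney] -= d_urine
            else:
                dtis[self.i_kidney] -= d_urine

        venous_in = outflow.copy()
        if self.i_lung >= 0:
            venous_in[self.i_lung] = 0.0  # lung effluent feeds the arterial pool

        if self.spec.portal_routing and self.i_spleen >= 0 and self.i_liver >= 0:
            # spleen effluent enters the liver capillary bed instead of the
            # venous pool; the liver then discharges both streams
            q_s_out = venous_in[self.i_spleen]
            venous_in[self.i_spleen] = 0.0
            dcap[self.i_liver] += q_s_out
            extra = self.Q[self.i_spleen] * CV[self.i_liver]
            dcap[self.i_liver] -= extra
            venous_in[self.i_liver] += extra

        if self.i_lung >= 0:
            # lung effluent feeds the arterial pool; parallel organs draw
            # Q_t * CA from it (their fractions sum to total cardiac output)
            lung_out = self.Q[self.i_lung] * CV[self.i_lung]
            d_art = lung_out - (inflow.sum() - inflow[self.i_lung])
            d_ven = venous_in.sum() - self.Q_total * C_ven
        else:
            # no lung in a reduced system: venous pool feeds arterial directly
            d_art = self.Q_total * C_ven - inflow.sum()
            d_ven = venous_in.sum() - self.Q_total * C_ven

        dy[lay.venous] = d_ven
        dy[lay.arterial] = d_art
        dy[lay.cap_slice] = dcap
        dy[lay.tissue_slice] = dtis
        dy[lay.pc_slice] = dpc
        dy[lay.bile] = d_bile
        dy[lay.urine] = d_urine
        return dy

    def initial_state(self, dose_mg: float) -> np.ndarray:
        """IV bolus: the whole dose starts in the venous pool."""
        y0 = np.zeros(self.layout.n_states)
        y0[self.layout.venous] = dose_mg
        return y0


def compile_model(spec: ModelSpec, params: FormulationParams, phys: Physiology) -> CompiledModel:
    return CompiledModel(spec, params, phys)


def pcs_rhs(state: np.ndarray, t: float, params: FormulationParams,
            phys: Physiology, spec: ModelSpec | None = None) -> np.ndarray:
    """State derivative of the phagocytosis (PCs) model at (state, t)."""
    spec = spec or ModelSpec(variant="PCs")
    if spec.variant != "PCs":
        raise ModelError("pcs_rhs requires spec.variant == 'PCs'")
    return compile_model(spec, params, phys).rhs(t, np.asarray(state, dtype=float))


def epr_rhs(state: np.ndarray, t: float, params: FormulationParams,
            phys: Physiology, spec: ModelSpec | None = None) -> np.ndarray:
    """State derivative of the EPR-tumour model at (state, t)."""
    spec = spec or ModelSpec(variant="EPR")
    if spec.variant != "EPR":
        raise ModelError("epr_rhs requires spec.variant == 'EPR'")
    return compile_model(spec, params, phys).rhs(t, np.asarray(state, dtype=float))


def mass_balance(state: np.ndarray, dose_mg: float) -> float:
    """Residual of total mass accounting: sum of all states minus the dose."""
    return float(np.sum(state) - dose_mg)


# ---------------------------------------------------------------------------
# Packaged formulation fixtures
# ---------------------------------------------------------------------------

def _formulation_table() -> pd.DataFrame:
    with importlib.resources.files("phagopbpk.data").joinpath("formulations.csv").open() as fh:
        return pd.read_csv(fh)


def formulation_names() -> list[str]:
    """Names of the five packaged nanoparticle formulations."""
    return list(_formulation_table()["formulation"].unique())


def load_formulation(name: str, K1: float = 0.1, K2: float = 0.05) -> FormulationParams:
    """Load one packaged formulation parameter set by name.

    K1/K2 defaults are placeholders for the EPR variant (no tabulated values
    exist); override or estimate them from data before interpreting EPR runs.
    """
    tab = _formulation_table()
    sub = tab[tab["formulation"] == name]
    if sub.empty:
        raise ModelError(f"unknown formulation {name!r}; known: {formulation_names()}")
    organs = {}
    for organ in ORGANS:
        vals = {
            p: float(sub[(sub["parameter"] == p) & (sub["organ"] == organ)]["value"].iloc[0])
            for p in KINETIC_FIELDS
        }
        organs[organ] = OrganKinetics(**vals)
    k_bile = float(sub[sub["parameter"] == "K_bile"]["value"].iloc[0])
    k_urine = float(sub[sub["parameter"] == "K_urine"]["value"].iloc[0])
    return FormulationParams(
        formulation_name=name, organs=organs,
        K_bile=k_bile, K_urine=k_urine, K1=K1, K2=K2,
    )


def load_all_formulations() -> dict[str, FormulationParams]:
    return {name: load_formulation(name) for name in formulation_names()}
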