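"""Goodness of fit, two-fold criterion, open-loop and whole-body estimation."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phagopbpk import (
    FitError,
    ModelSpec,
    ObservedDataset,
    SynthDesign,
    fit_open_loop,
    fit_whole_body,
    generate_observed,
    goodness_of_fit,
    simulate,
    two_fold_fraction,
)
from phagopbpk.fit import open_loop_predict, _paired


@pytest.fixture(scope="module")
def noise_free(reference_formulation, phys):
    design = SynthDesign(formulation=reference_formulation.formulation_name,
                         noise_cv=0.0, seed=1, lloq=0.0)
    return generate_observed(design, reference_formulation, phys, dose_mg=2.0)


@pytest.fixture(scope="module")
def noisy(reference_formulation, phys):
    design = SynthDesign(formulation=reference_formulation.formulation_name,
                         noise_cv=0.2, seed=42)
    return generate_observed(design, reference_formulation, phys, dose_mg=2.0)


@pytest.fixture(scope="module")
def truth_result(pcs_spec, reference_formulation, phys):
    return simulate(pcs_spec, reference_formulation, phys, dose_mg=2.0)


class TestGoodnessOfFit:
    def test_perfect_prediction_gives_unity(self, noise_free, truth_result):
        assert goodness_of_fit(noise_free, truth_result) == pytest.approx(1.0, abs=1e-9)

    def test_constant_factor_offset_keeps_unity(self, noise_free, truth_result, phys,
                                                pcs_spec, reference_formulation):
        # regression R^2 is invariant to a constant log-offset: a 10x dose
        # scales every prediction tenfold and leaves R^2 at 1
        scaled = simulate(pcs_spec, reference_formulation, phys, dose_mg=20.0)
        assert goodness_of_fit(noise_free, scaled) == pytest.approx(1.0, abs=1e-9)

    def test_matches_closed_form_pearson_oracle(self, noisy, truth_result):
        r2 = goodness_of_fit(noisy, truth_result)
        obs, pred = _paired(noisy, truth_result)
        keep = (obs > 0) & (pred > 0)
        x, y = np.log10(pred[keep]), np.log10(obs[keep])
        xc, yc = x - x.mean(), y - y.mean()
        oracle = float((xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc)))
        assert r2 == pytest.approx(oracle, abs=1e-10)

    def test_excluded_zero_pairs_are_counted(self, truth_result, noise_free):
        data = noise_free.data.copy()
        data.loc[data.index[:2], "concentration_mg_ml"] = 0.0
        ds = ObservedDataset(data, metadata=noise_free.metadata)
        r2, details = goodness_of_fit(ds, truth_result, return_details=True)
        assert details["n_excluded"] == 2

    def test_too_few_pairs_rejected(self, truth_result, noise_free):
        ds = ObservedDataset(noise_free.data.iloc[:2].copy(),
                             metadata=noise_free.metadata)
        with pytest.raises(FitError):
            goodness_of_fit(ds, truth_result)


class TestTwoFold:
    def test_identical_data_fraction_one(self, noise_free, truth_result):
        assert two_fold_fraction(noise_free, truth_result) == 1.0

    @pytest.mark.parametrize("factor, expected", [(1.5, 1.0), (2.001, 0.0)])
    def test_uniform_misprediction_boundary(self, factor, expected, noise_free,
                                            pcs_spec, reference_formulation, phys):
        scaled = simulate(pcs_spec, reference_formulation, phys, dose_mg=2.0 * factor)
        assert two_fold_fraction(noise_free, scaled) == expected


@pytest.fixture(scope="module")
def organ_dataset(reference_formulation, phys):
    """Liver data generated by the open-loop model itself."""
    kin = reference_formulation.organs["liver"]

    def forcing(t):
        return 0.5 * np.exp(-3.0 * t) + 0.05 * np.exp(-0.05 * t)

    times = np.array([0.083, 1.0, 4.0, 8.0, 24.0, 72.0])
    clean = open_loop_predict(kin, "liver", phys, forcing, times)
    rows = [
        {"time_h": t, "compartment": "liver", "concentration_mg_ml": v, "replicate": 0}
        for t, v in zip(times, clean)
    ] + [
        {"time_h": t, "compartment": "blood",
         "concentration_mg_ml": forcing(t), "replicate": 0}
        for t in times
    ]
    ds = ObservedDataset(pd.DataFrame(rows),
                         metadata={"physiology": phys.to_dict()})
    return ds, forcing, kin


class TestOpenLoop:
    def test_self_consistent_at_truth(self, organ_dataset):
        ds, forcing, kin = organ_dataset
        est = fit_open_loop("liver", ds, blood_forcing=forcing, init=kin)
        for name in ("K_max", "K_50", "n", "K_out"):
            assert getattr(est, name) == pytest.approx(getattr(kin, name), rel=1e-4)

    def test_recovers_from_threefold_perturbed_start(self, organ_dataset):
        ds, forcing, kin = organ_dataset
        init = replace(kin, K_max=kin.K_max * 3, K_out=kin.K_out * 3)
        est = fit_open_loop("liver", ds, blood_forcing=forcing, init=init)
        assert est.K_max == pytest.approx(kin.K_max, rel=0.10)
        assert est.K_out == pytest.approx(kin.K_out, rel=0.10)

    def test_underdetermined_dataset_rejected(self, organ_dataset):
        ds, forcing, kin = organ_dataset
        tiny = ObservedDataset(
            ds.data[(ds.data["compartment"] == "blood")
                    | (ds.data["time_h"] <= 1.0)].copy(),
            metadata=ds.metadata,
        )
        with pytest.raises(FitError, match="identify"):
            fit_open_loop("liver", tiny, blood_forcing=forcing, init=kin)


class TestWholeBody:
    def test_init_at_truth_on_noise_free_data_is_a_fixed_point(
        self, noise_free, reference_formulation, phys, pcs_spec
    ):
        fr = fit_whole_body(
            noise_free, pcs_spec, reference_formulation,
            free=["liver.K_max", "liver.K_out"], phys=phys,
            n_starts=1, seed=0, nelder_max_nfev=30,
        )
        obs = noise_free.data["concentration_mg_ml"].to_numpy()
        assert fr.loss < 1e-10 * float(np.sum(obs ** 2)) + 1e-12
        assert fr.estimates.organs["liver"].K_max == pytest.approx(132.0, rel=1e-3)

    def test_requires_blood_and_two_organs(self, noise_free, reference_formulation,
                                           phys, pcs_spec):
        ds = ObservedDataset(
            noise_free.data[noise_free.data["compartment"] == "liver"].copy(),
            metadata=noise_free.metadata,
        )
        with pytest.raises(FitError):
            fit_whole_body(ds, pcs_spec, reference_formulation,
                           free=["liver.K_max"], phys=phys)

    def test_recovery_error_grows_with_noise(self, reference_formulation, phys):
        """Median liver K_max error is non-decreasing across noise levels."""
        kin = reference_formulation.organs["liver"]

        def forcing(t):
            return 0.5 * np.exp(-3.0 * t) + 0.05 * np.exp(-0.05 * t)

        times = np.array([0.083, 1.0, 4.0, 8.0, 24.0, 72.0])
        clean = open_loop_predict(kin, "liver", phys, forcing, times)
        medians = []
        for cv in (0.0, 0.10, 0.30):
            errs = []
            for seed in range(5):
                rng = np.random.default_rng(1000 + seed)
                sigma2 = np.log1p(cv ** 2)
                noisy_vals = clean * np.exp(
                    rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=clean.size)
                ) if cv > 0 else clean
                rows = [
                    {"time_h": t, "compartment": "liver",
                     "concentration_mg_ml": v, "replicate": 0}
                    for t, v in zip(times, noisy_vals)
                ] + [
                    {"time_h": t, "compartment": "blood",
                     "concentration_mg_ml": forcing(t), "replicate": 0}
                    for t in times
                ]
                ds = ObservedDataset(pd.DataFrame(rows),
                                     metadata={"physiology": phys.to_dict()})
                est = fit_open_loop("liver", ds, blood_forcing=forcing, init=kin,
                                    free=("K_max", "K_out"), weights="log")
                errs.append(abs(est.K_max - kin.K_max) / kin.K_max)
            medians.append(float(np.median(errs)))
        assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9, medians
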