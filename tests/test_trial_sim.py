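"""Generator, design extraction and carryover chronology."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nof1sim import (
    SCENARIOS,
    SimulationModel,
    TrialDataset,
    apply_carryover,
    extract_design,
    simulate_cohort,
)
from nof1sim.trial_sim import REPRESENTATIVE, SUBPOPULATION

from conftest import build_nof1_dataset, make_single_patient_nof1


class TestSimulationModel:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma_mu": -0.1},
            {"sigma_eps": 0.0},
            {"sigma_eps": -1.0},
            {"n_cycles": 0},
            {"looks_per_cycle": 3},
            {"carryover": -0.05},
            {"p_representative": 1.5},
            {"p_representative": -0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationModel(**kwargs)

    def test_scenario_factory(self):
        assert SCENARIOS == {1: (0.1, 0.5), 2: (0.0, 0.5), 3: (0.5, 0.5), 4: (0.5, 1.0)}
        m = SimulationModel.scenario(3, tau=0.1)
        assert (m.sigma_mu, m.sigma_eps, m.tau) == (0.5, 0.5, 0.1)
        with pytest.raises(ValueError):
            SimulationModel.scenario(5)


class TestSimulateCohort:
    def test_structure_and_balance(self, scenario1_model, rng):
        cohort = simulate_cohort(scenario1_model, 30, rng)
        assert cohort.design == "nof1"
        assert cohort.n_records == 30 * 3 * 2
        assert cohort.n_patients == 30
        # within each (patient, cycle) exactly one treated and one placebo look
        frame = cohort.to_frame()
        per_cycle = frame.groupby(["patient_id", "cycle"])["treatment"].agg(["sum", "count"])
        assert (per_cycle["count"] == 2).all()
        assert (per_cycle["sum"] == 1).all()
        # first chronological period is never flagged as post-treatment
        first = frame.groupby("patient_id").head(1)
        assert (first["prev_treated"] == 0).all()

    def test_rejects_tiny_cohort(self, scenario1_model, rng):
        with pytest.raises(ValueError):
            simulate_cohort(scenario1_model, 1, rng)

    def test_noise_free_limit(self, rng):
        model = SimulationModel(mu=0.0, tau=0.25, sigma_mu=0.0, sigma_eps=1e-12)
        cohort = simulate_cohort(model, 10, rng)
        np.testing.assert_allclose(
            cohort.outcome, 0.25 * cohort.treatment, atol=1e-10
        )

    def test_large_sample_moments(self, scenario1_model, rng):
        """Law-of-large-numbers check on the generative parameters."""
        cohort = simulate_cohort(scenario1_model, 10_000, rng)
        frame = cohort.to_frame()
        # mean within-patient (treatment - placebo) difference estimates tau
        means = frame.groupby(["patient_id", "treatment"])["outcome"].mean().unstack()
        diffs = means[1] - means[0]
        assert abs(diffs.mean() - 0.25) < 0.02
        # patient means have variance sigma_mu^2 + sigma_eps^2 / 6 around mu + tau/2
        pm = frame.groupby("patient_id")["outcome"].mean()
        expected_var = 0.1**2 + 0.5**2 / 6
        assert abs(pm.var() - expected_var) < 0.005
        assert abs(pm.mean() - 0.125) < 0.01

    def test_mixture_marginals(self, rng):
        model = SimulationModel.scenario(1, p_representative=0.5, tau_sub=0.0)
        cohort = simulate_cohort(model, 10_000, rng)
        first = np.concatenate(([True], cohort.patient_id[1:] != cohort.patient_id[:-1]))
        frac = (cohort.population[first] == REPRESENTATIVE).mean()
        assert abs(frac - 0.5) < 0.02

    def test_subpopulation_uses_tau_sub(self, rng):
        model = SimulationModel(
            tau=1.0, tau_sub=-1.0, sigma_mu=0.0, sigma_eps=1e-12, p_representative=0.5
        )
        cohort = simulate_cohort(model, 200, rng)
        treated = cohort.treatment == 1
        sub = cohort.population == SUBPOPULATION
        np.testing.assert_allclose(cohort.outcome[treated & ~sub], 1.0, atol=1e-9)
        np.testing.assert_allclose(cohort.outcome[treated & sub], -1.0, atol=1e-9)

    def test_fixed_order_mode(self, rng):
        model = SimulationModel.scenario(1, reorder_each_cycle=False)
        cohort = simulate_cohort(model, 50, rng)
        frame = cohort.to_frame()
        look1 = frame[frame["look"] == 1].pivot(
            index="patient_id", columns="cycle", values="treatment"
        )
        # every cycle repeats the patient's first-cycle order
        assert (look1.nunique(axis=1) == 1).all()


class TestExtractDesign:
    def test_record_counts(self, scenario1_model, rng):
        cohort = simulate_cohort(scenario1_model, 30, rng)
        assert extract_design(cohort, "crossover").n_records == 60
        assert extract_design(cohort, "rct", rng).n_records == 30
        assert extract_design(cohort, "nof1").n_records == 180

    def test_unknown_design_rejected(self, scenario1_model, rng):
        cohort = simulate_cohort(scenario1_model, 5, rng)
        with pytest.raises(ValueError):
            extract_design(cohort, "factorial", rng)
        with pytest.raises(ValueError):
            extract_design(extract_design(cohort, "crossover"), "rct", rng)

    def test_crossover_is_cycle1_subset(self, scenario1_model, rng):
        """Conservation: crossover records equal the cycle-1 records field-by-field."""
        cohort = simulate_cohort(scenario1_model, 25, rng)
        xo = extract_design(cohort, "crossover")
        keep = cohort.cycle == 1
        for col in ("patient_id", "cycle", "look", "treatment", "outcome", "population"):
            np.testing.assert_array_equal(getattr(xo, col), getattr(cohort, col)[keep])

    def test_rct_deterministic_under_seed(self, scenario1_model):
        datasets = []
        for _ in range(2):
            rng = np.random.default_rng(777)
            cohort = simulate_cohort(scenario1_model, 30, rng)
            datasets.append(extract_design(cohort, "rct", rng))
        np.testing.assert_array_equal(datasets[0].outcome, datasets[1].outcome)
        np.testing.assert_array_equal(datasets[0].treatment, datasets[1].treatment)
        np.testing.assert_array_equal(datasets[0].look, datasets[1].look)

    def test_rct_look_choice_is_uniform(self, scenario1_model, rng):
        cohort = simulate_cohort(scenario1_model, 10_000, rng)
        rct = extract_design(cohort, "rct", rng)
        assert rct.n_records == 10_000
        # half the patients end up contributing their treated period
        assert abs(rct.treatment.mean() - 0.5) < 0.015
        assert (rct.prev_treated == 0).all()


class TestApplyCarryover:
    def test_zero_gamma_is_identity(self, scenario1_model, rng):
        cohort = simulate_cohort(scenario1_model, 20, rng)
        for design in ("nof1", "crossover", "rct"):
            data = extract_design(cohort, design, rng)
            out = apply_carryover(data, 0.0)
            np.testing.assert_array_equal(out.outcome, data.outcome)

    def test_negative_gamma_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            apply_carryover(small_cohort, -0.1)

    def test_hand_traced_chronology(self):
        """Noise-free sequence T,P | P,T | T,P with gamma=0.15, tau=0.25.

        Periods 2, 5 and 6 follow a treated period (within cycle 1, within
        cycle 3, and across the cycle 2 -> 3 boundary respectively), so each
        gains exactly +0.15.
        """
        base = [0.25, 0.0, 0.0, 0.25, 0.25, 0.0]  # mu_i = 0, tau * Z only
        patients = [
            make_single_patient_nof1([1, 0, 0, 1, 1, 0], base, patient_id=0),
            make_single_patient_nof1([1, 0, 0, 1, 1, 0], base, patient_id=1),
        ]
        data = build_nof1_dataset(patients)
        out = apply_carryover(data, 0.15)
        expected = [0.25, 0.15, 0.0, 0.25, 0.40, 0.15]
        np.testing.assert_allclose(out.outcome[:6], expected)
        np.testing.assert_allclose(out.outcome[6:], expected)

    def test_crossover_placebo_first_untouched(self):
        patients = [
            make_single_patient_nof1([0, 1], [0.0, 0.25], patient_id=0),
            make_single_patient_nof1([0, 1], [0.0, 0.25], patient_id=1),
        ]
        data = build_nof1_dataset(patients)
        data.design = "crossover"
        out = apply_carryover(data, 0.3)
        np.testing.assert_array_equal(out.outcome, data.outcome)

    def test_rct_unchanged(self, scenario1_model, rng):
        cohort = simulate_cohort(scenario1_model, 20, rng)
        rct = extract_design(cohort, "rct", rng)
        out = apply_carryover(rct, 0.5)
        np.testing.assert_array_equal(out.outcome, rct.outcome)

    def test_no_compounding(self):
        """Two consecutive treated periods still add a single +gamma each."""
        patients = [
            make_single_patient_nof1([1, 0, 1, 0], [0.25, 0, 0.25, 0], patient_id=0),
            make_single_patient_nof1([0, 1, 1, 0], [0, 0.25, 0.25, 0], patient_id=1),
        ]
        data = build_nof1_dataset(patients)
        out = apply_carryover(data, 0.1)
        # patient 0: periods 2 and 4 follow treatment
        np.testing.assert_allclose(out.outcome[:4], [0.25, 0.1, 0.25, 0.1])
        # patient 1: period 3 follows treatment (gets one +0.1 despite being
        # treated itself), period 4 follows treatment
        np.testing.assert_allclose(out.outcome[4:], [0, 0.25, 0.35, 0.1])

    def test_modified_count_matches_brute_force(self, scenario1_model):
        """Carryover touches exactly the post-treated periods, per design."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cohort = simulate_cohort(scenario1_model, 6, rng)
            design = ("nof1", "crossover")[seed % 2]
            data = extract_design(cohort, design, rng)
            out = apply_carryover(data, 0.1)
            n_modified = int((out.outcome != data.outcome).sum())
            expected = 0
            frame = data.to_frame()
            for _, grp in frame.groupby("patient_id"):
                z = grp["treatment"].to_numpy()
                expected += sum(z[i - 1] == 1 for i in range(1, len(z)))
            assert n_modified == expected


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 12))
def test_invariants_hold_for_random_cohorts(seed, n):
    """Balance, chronology and conservation invariants across random draws."""
    rng = np.random.default_rng(seed)
    model = SimulationModel.scenario(1, p_representative=0.7, tau_sub=0.1)
    cohort = simulate_cohort(model, n, rng)
    # within-cycle balance
    treat = cohort.treatment.reshape(n, model.n_cycles, 2)
    assert (treat.sum(axis=2) == 1).all()
    # prev_treated equals the previous period's treatment within patient
    z = cohort.treatment.reshape(n, -1)
    prev = cohort.prev_treated.reshape(n, -1)
    assert (prev[:, 0] == 0).all()
    assert (prev[:, 1:] == z[:, :-1]).all()
    # crossover view conserves the cycle-1 draws
    xo = extract_design(cohort, "crossover")
    np.testing.assert_array_equal(xo.outcome, cohort.outcome[cohort.cycle == 1])


class TestSerialization:
    def test_csv_round_trip(self, scenario1_model, rng, tmp_path):
        model = SimulationModel.scenario(1, p_representative=0.5, tau_sub=0.1)
        cohort = simulate_cohort(model, 8, rng)
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = TrialDataset.from_csv(path, design="nof1")
        for col in ("patient_id", "cycle", "look", "treatment", "prev_treated", "population"):
            np.testing.assert_array_equal(getattr(back, col), getattr(cohort, col))
        np.testing.assert_allclose(back.outcome, cohort.outcome)
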