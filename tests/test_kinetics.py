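"""Workflow kinetics: closed-form relaxation, staging, and the ODE oracle."""

import numpy as np
import pytest

from hdxsim import (
    ExchangeConditions,
    ProtectionProfile,
    Workflow,
    WorkflowStage,
    fully_deuterated_start,
    intrinsic_rate_profile,
    observed_rates,
    relax_occupancy,
    simulate_workflow,
)
from hdxsim.scenarios import LABELING_CONDITIONS, LC_CONDITIONS

from conftest import random_workflow, rk4_workflow


class TestRelaxOccupancy:
    def test_zero_duration_returns_start(self):
        assert relax_occupancy(0.3, 5.0, 0.0, 1.0) == pytest.approx(0.3)

    def test_fast_rate_reaches_target(self):
        assert relax_occupancy(0.0, 1e9, 1.0, 1.0) == pytest.approx(1.0)
        assert relax_occupancy(1.0, 1e9, 1.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_back_exchange_closed_form(self):
        # start 1, k = 4e-4 /s, 1000 s toward 0: exp(-0.4)
        got = relax_occupancy(1.0, 4e-4, 1000.0, 0.0)
        assert got == pytest.approx(0.6703200460356393, abs=1e-12)

    def test_rejects_negative_rate_or_duration(self):
        with pytest.raises(ValueError):
            relax_occupancy(0.0, -1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            relax_occupancy(0.0, 1.0, -1.0, 1.0)


class TestObservedRates:
    def test_protection_divides_rates(self):
        profile = intrinsic_rate_profile("AAAA", LABELING_CONDITIONS)
        unprotected = observed_rates(profile, ProtectionProfile.uniform(0.0, 4))
        protected = observed_rates(profile, ProtectionProfile.uniform(4.0, 4))
        assert np.allclose(unprotected.rates, profile.rates, equal_nan=True)
        assert np.allclose(
            protected.rates, profile.rates / 1e4, equal_nan=True
        )

    def test_length_mismatch_rejected(self):
        profile = intrinsic_rate_profile("AAAA", LABELING_CONDITIONS)
        with pytest.raises(ValueError, match="length"):
            observed_rates(profile, ProtectionProfile.uniform(0.0, 5))

    def test_strongly_protected_site_two_hour_uptake(self):
        # k_ch = 6.9 /s slowed by log P = 6 leaves ~5% deuteration after 2 h
        k = 6.9 / 10.0**6
        uptake = relax_occupancy(0.0, k, 7200.0, 1.0)
        assert uptake == pytest.approx(0.0485, abs=5e-4)


class TestFullyDeuteratedStart:
    def test_example_peptide(self):
        occ = fully_deuterated_start("ACDEFGHI")
        assert np.isnan(occ[0])
        assert np.all(occ[1:] == 1.0)

    def test_proline_rule(self):
        occ = fully_deuterated_start("APA")
        assert np.isnan(occ[0]) and np.isnan(occ[1]) and occ[2] == 1.0

    @pytest.mark.parametrize("seq", ["ACDEFGHI", "APA", "PPAP", "GGGG"])
    def test_conservation(self, seq):
        occ = fully_deuterated_start(seq)
        n_exchanging = sum(
            1 for i, aa in enumerate(seq) if i > 0 and aa != "P"
        )
        assert np.nansum(occ) == n_exchanging


class TestSimulateWorkflow:
    def test_identity_workflow_leaves_occupancy_unchanged(self):
        start = fully_deuterated_start("ACDEFGHI") * 0.5
        workflow = Workflow(
            stages=(
                WorkflowStage("a", 0.0, LABELING_CONDITIONS, True, 1.0),
                WorkflowStage("b", 0.0, LC_CONDITIONS, False, 0.0),
            ),
            esi_retention=1.0,
        )
        traj = simulate_workflow(
            "ACDEFGHI", ProtectionProfile.uniform(2.0, 8), workflow, start=start
        )
        assert np.allclose(traj.final_occupancy, start, equal_nan=True)

    def test_single_unprotected_labeling_reduces_to_intrinsic_uptake(self, table):
        """With P = 1 and one labeling stage, D_j(t) = 1 - exp(-k_ch t)."""
        seq = "AGSTMK"
        workflow = Workflow(
            stages=(WorkflowStage("label", 300.0, LABELING_CONDITIONS, True, 1.0),),
        )
        traj = simulate_workflow(seq, ProtectionProfile.uniform(0.0, 6), workflow, table)
        k = intrinsic_rate_profile(seq, LABELING_CONDITIONS, table).rates
        for i, t in enumerate(traj.times):
            expected = 1.0 - np.exp(-k * min(t, 300.0))
            assert np.allclose(traj.occupancy[i], expected, equal_nan=True, atol=1e-12)

    def test_occupancies_bounded_and_monotone_per_stage(self, standard_workflow):
        traj = simulate_workflow(
            "ACDEFGHI", ProtectionProfile.uniform(4.0, 8), standard_workflow
        )
        vals = traj.occupancy[:, 1:]  # drop the residue-1 NaN column
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0
        labels = np.array(traj.stage_labels)
        diffs = np.diff(traj.occupancy, axis=0)
        for stage, sign in [("labeling", 1), ("digestion", -1), ("lc", -1)]:
            rows = np.nonzero(labels == stage)[0]
            rows = rows[rows > 0] - 1  # diff rows landing inside the stage
            assert np.all(sign * diffs[rows][:, 1:] >= -1e-12)

    def test_esi_factor_is_single_terminal_discontinuity(self, standard_workflow):
        traj = simulate_workflow(
            "ACDEFGHI", ProtectionProfile.uniform(4.0, 8), standard_workflow
        )
        assert traj.stage_labels[-1] == "esi"
        assert traj.times[-1] == traj.times[-2]
        assert np.allclose(
            traj.occupancy[-1], 0.95 * traj.occupancy[-2], equal_nan=True
        )

    def test_missing_protection_for_protected_stage_is_config_error(self):
        workflow = Workflow(
            stages=(WorkflowStage("label", 10.0, LABELING_CONDITIONS, True, 1.0),)
        )
        with pytest.raises(ValueError, match="protect"):
            simulate_workflow("ACDEFGHI", None, workflow)

    def test_direction_symmetry_labeling_vs_reverse_labeling(self):
        """Under identical conditions, loss from a deuterated chain mirrors
        uptake by a protiated one: D_loss(t) = 1 - D_uptake(t)."""
        seq = "AGSTMK"
        protection = ProtectionProfile.uniform(2.0, 6)
        uptake_wf = Workflow(
            stages=(WorkflowStage("fwd", 500.0, LABELING_CONDITIONS, True, 1.0),)
        )
        loss_wf = Workflow(
            stages=(WorkflowStage("rev", 500.0, LABELING_CONDITIONS, True, 0.0),)
        )
        up = simulate_workflow(seq, protection, uptake_wf)
        down = simulate_workflow(
            seq, protection, loss_wf, start=fully_deuterated_start(seq)
        )
        assert np.allclose(
            down.occupancy[:-1], 1.0 - up.occupancy[:-1], equal_nan=True, atol=1e-12
        )


def test_closed_form_matches_fixed_step_integration(table):
    """Piecewise closed-form propagation agrees with brute-force RK4 time
    stepping (step 5 ms) to 1e-5 occupancy on randomized workflows."""
    rng = np.random.default_rng(42)
    for _ in range(10):
        n = int(rng.integers(5, 12))
        seq = "".join(rng.choice(list("ACDEFGHIKLMNQRSTVWY"), size=n))
        protection, workflow = random_workflow(rng, n)
        start = fully_deuterated_start(seq) * float(rng.random() < 0.5)
        traj = simulate_workflow(
            seq, protection, workflow, table, points_per_stage=2, start=start
        )
        oracle = rk4_workflow(seq, protection, workflow, table, start)
        assert np.allclose(traj.final_occupancy, oracle, equal_nan=True, atol=1e-5)
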