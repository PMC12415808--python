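"""Forward model, read simulation, efficiency estimation and calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from ampbias.calibration import (
    EfficiencyEstimate,
    ReadTable,
    calibrate_sample,
    estimate_efficiencies,
    forward_read_proportions,
    simulate_read_counts,
    summarize_bias,
)
from ampbias.quantification import SpeciesQuant, build_mock_community


def _mock(copies, names=None):
    names = names or [f"s{i}" for i in range(len(copies))]
    members = [SpeciesQuant(n, "fish", 1.0, c) for n, c in zip(names, copies)]
    return build_mock_community(members, np.ones(len(copies)), "template")


def _reads(counts_by_sample, species, marker="M1", taq="NPHF"):
    counts = pd.DataFrame(counts_by_sample, index=species)
    meta = pd.DataFrame(
        {
            "marker": marker,
            "taq": taq,
            "bsa": False,
            "cycling": "normal",
            "replicate": range(1, len(counts.columns) + 1),
        },
        index=counts.columns,
    )
    return ReadTable(counts, meta)


class TestForwardModel:
    def test_zero_alpha_returns_template_composition(self):
        c = np.array([10.0, 30.0, 60.0])
        pi = forward_read_proportions(
            log_template=np.log(c), alpha=np.zeros(3), n_cycles=35
        )
        assert pi == pytest.approx(c / c.sum(), rel=1e-12)

    def test_closed_form_two_species(self):
        # equal templates, alpha = (0.02, 0), 35 cycles: exp(0.7)/(1+exp(0.7))
        pi = forward_read_proportions(
            log_template=np.log([100.0, 100.0]), alpha=np.array([0.02, 0.0]),
            n_cycles=35,
        )
        expected = math.exp(0.7) / (1 + math.exp(0.7))
        assert pi[0] == pytest.approx(expected, rel=1e-9)
        assert pi[0] == pytest.approx(0.66819, abs=5e-6)

    def test_shift_and_scale_invariance(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 30))
            logc = rng.normal(0, 3, n)
            alpha = rng.normal(0, 0.05, n)
            pi = forward_read_proportions(log_template=logc, alpha=alpha)
            delta = float(rng.normal())
            k = float(rng.uniform(0.1, 10))
            pi_shift = forward_read_proportions(log_template=logc + np.log(k), alpha=alpha + delta)
            assert np.max(np.abs(pi - pi_shift)) < 1e-12
            assert pi.sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            forward_read_proportions(log_template=[np.inf, 0.0], alpha=[0.0, 0.0])


class TestSimulateReadCounts:
    def test_degenerate_composition(self):
        counts = simulate_read_counts([1.0, 0.0], 1000, seed=0)
        assert list(counts) == [1000, 0]

    def test_multinomial_mean(self):
        draws = np.array(
            [simulate_read_counts([0.7, 0.3], 10_000, seed=s) for s in range(500)]
        )
        se = np.sqrt(10_000 * 0.7 * 0.3)
        assert abs(draws[:, 0].mean() - 7000) < 3 * se / np.sqrt(500)

    def test_overdispersion_inflates_variance(self):
        tight = np.array(
            [simulate_read_counts([0.5, 0.5], 5000, 0.0, seed=s) for s in range(400)]
        )
        loose = np.array(
            [simulate_read_counts([0.5, 0.5], 5000, 0.1, seed=s) for s in range(400)]
        )
        assert loose[:, 0].var() > 2 * tight[:, 0].var()

    def test_seed_reproducibility(self):
        a = simulate_read_counts([0.2, 0.3, 0.5], 999, 0.05, seed=42)
        b = simulate_read_counts([0.2, 0.3, 0.5], 999, 0.05, seed=42)
        assert np.array_equal(a, b)

    def test_negative_overdispersion_rejected(self):
        with pytest.raises(ValueError):
            simulate_read_counts([0.5, 0.5], 100, -0.1)


class TestEstimateEfficiencies:
    def test_closed_form_single_replicate(self):
        # equal templates, counts 2:1 -> alpha = ln2 / 35
        mock = _mock([1.0, 1.0])
        reads = _reads({"r1": [2000, 1000]}, ["s0", "s1"])
        ests = estimate_efficiencies(
            mock, reads, n_cycles=35, reference_species="s1", kappa=0.0
        )
        by = {e.species: e for e in ests}
        assert by["s0"].alpha_hat == pytest.approx(math.log(2) / 35, rel=1e-9)
        assert by["s0"].alpha_hat == pytest.approx(0.019804, abs=5e-7)
        assert by["s1"].alpha_hat == 0.0
        assert by["s1"].lo == by["s1"].hi == 0.0

    def test_noiseless_pseudocounts_invert_forward_map(self):
        rng = np.random.default_rng(3)
        logc = rng.normal(5, 1, 6)
        alpha = np.append(rng.uniform(-0.04, 0.04, 5), 0.0)
        pi = forward_read_proportions(log_template=logc, alpha=alpha, n_cycles=35)
        counts = np.round(pi * 1e12)  # noiseless expected counts
        mock = _mock(np.exp(logc))
        reads = _reads({"r1": counts}, [f"s{i}" for i in range(6)])
        ests = estimate_efficiencies(
            mock, reads, n_cycles=35, reference_species="s5", kappa=0.0
        )
        got = np.array([e.alpha_hat for e in ests])
        assert got == pytest.approx(alpha - alpha[5], abs=1e-9)

    @pytest.mark.parametrize("method", ["point", "bayes"])
    def test_simulation_recovery_both_methods(self, method):
        rng = np.random.default_rng(8)
        n = 10
        copies = rng.lognormal(5, 0.5, n)
        alpha = np.append(rng.uniform(-0.05, 0.05, n - 1), 0.0)
        pi = forward_read_proportions(log_template=np.log(copies), alpha=alpha)
        reads = _reads(
            {f"r{j}": simulate_read_counts(pi, 50_000, seed=100 + j) for j in range(3)},
            [f"s{i}" for i in range(n)],
        )
        ests = estimate_efficiencies(
            _mock(copies), reads, reference_species=f"s{n - 1}", method=method
        )
        got = np.array([e.alpha_hat for e in ests])
        assert np.max(np.abs(got - alpha)) < 0.003

    def test_mixed_conditions_rejected(self):
        mock = _mock([1.0, 1.0])
        counts = pd.DataFrame({"a": [10, 20], "b": [15, 15]}, index=["s0", "s1"])
        meta = pd.DataFrame(
            {
                "marker": ["M1", "M2"],
                "taq": "NPHF",
                "bsa": False,
                "cycling": "normal",
                "replicate": [1, 1],
            },
            index=["a", "b"],
        )
        with pytest.raises(ValueError, match="marker-Taq"):
            estimate_efficiencies(
                mock, ReadTable(counts, meta), reference_species="s0"
            )

    def test_zero_counts_with_zero_kappa_rejected(self):
        mock = _mock([1.0, 1.0, 1.0])
        reads = _reads({"r1": [100, 0, 50]}, ["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="zero"):
            estimate_efficiencies(
                mock, reads, reference_species="s0", kappa=0.0
            )


class TestCalibrateSample:
    def _est(self, sp, a, width=0.0, marker="M1", taq="NPHF"):
        return EfficiencyEstimate(sp, marker, taq, a, a - width, a + width, "ref")

    def test_identity_when_alpha_zero(self):
        ests = [self._est("a", 0.0), self._est("b", 0.0)]
        res = calibrate_sample([300, 700], ["a", "b"], ests, kappa=0.0)
        assert res.proportions == pytest.approx([0.3, 0.7], rel=1e-9)

    def test_inverts_closed_form_example(self):
        ests = [self._est("a", math.log(2) / 35), self._est("b", 0.0)]
        res = calibrate_sample([2000, 1000], ["a", "b"], ests, n_cycles=35, kappa=0.0)
        assert res.proportions == pytest.approx([0.5, 0.5], abs=1e-9)

    def test_simulate_then_calibrate_round_trip(self):
        rng = np.random.default_rng(17)
        n = 8
        copies = rng.lognormal(4, 0.6, n)
        true_p = copies / copies.sum()
        alpha = np.append(rng.uniform(-0.04, 0.04, n - 1), 0.0)
        pi = forward_read_proportions(log_template=np.log(copies), alpha=alpha)
        counts = simulate_read_counts(pi, 100_000, seed=9)
        ests = [self._est(f"s{i}", a) for i, a in enumerate(alpha)]
        res = calibrate_sample(counts, [f"s{i}" for i in range(n)], ests, seed=1)
        assert np.max(np.abs(res.proportions - true_p)) < 0.01

    def test_missing_species_listed(self):
        ests = [self._est("a", 0.0)]
        with pytest.raises(ValueError, match="b"):
            calibrate_sample([10, 20], ["a", "b"], ests)

    def test_cross_marker_mixing_refused(self):
        ests = [self._est("a", 0.0, marker="M1"), self._est("b", 0.0, marker="M2")]
        with pytest.raises(ValueError, match="marker-Taq"):
            calibrate_sample([10, 20], ["a", "b"], ests)
        res = calibrate_sample([10, 20], ["a", "b"], ests, force=True, kappa=0.0)
        assert res.proportions == pytest.approx([1 / 3, 2 / 3])

    def test_uncertainty_widens_with_interval_width(self):
        tight = [self._est("a", 0.01, width=1e-6), self._est("b", 0.0, width=1e-6)]
        wide = [self._est("a", 0.01, width=0.02), self._est("b", 0.0, width=0.02)]
        r_t = calibrate_sample([500, 500], ["a", "b"], tight, seed=0)
        r_w = calibrate_sample([500, 500], ["a", "b"], wide, seed=0)
        assert (r_w.hi[0] - r_w.lo[0]) > (r_t.hi[0] - r_t.lo[0])


class TestSummarizeBias:
    def _ests(self, alphas, marker="M1", taq="NPHF", ref="ref"):
        out = [EfficiencyEstimate(ref, marker, taq, 0.0, 0.0, 0.0, ref)]
        out += [
            EfficiencyEstimate(f"s{i}", marker, taq, a, a, a, ref)
            for i, a in enumerate(alphas)
        ]
        return out

    def test_all_zero(self):
        table = summarize_bias(self._ests([0.0, 0.0, 0.0]))
        assert table["mean_abs_alpha"].iloc[0] == 0.0
        assert table["sd_abs_alpha"].iloc[0] == 0.0

    def test_hand_arithmetic(self):
        table = summarize_bias(self._ests([0.01, -0.03, 0.02]))
        assert table["mean_abs_alpha"].iloc[0] == pytest.approx(0.02)
        assert table["sd_abs_alpha"].iloc[0] == pytest.approx(
            np.std([0.01, 0.03, 0.02], ddof=1)
        )
        assert table["n_species"].iloc[0] == 3  # reference excluded

    def test_groups_kept_separate(self):
        ests = self._ests([0.01], taq="NPHF") + self._ests([0.05], taq="QMMM")
        table = summarize_bias(ests)
        assert len(table) == 2
        assert set(table["taq"]) == {"NPHF", "QMMM"}


def test_read_table_rejects_bad_input():
    counts = pd.DataFrame({"a": [1, -2]}, index=["x", "y"])
    meta = pd.DataFrame(
        {"marker": "M", "taq": "T", "bsa": False, "cycling": "normal", "replicate": 1},
        index=["a"],
    )
    with pytest.raises(ValueError, match="non-negative"):
        ReadTable(counts, meta)
    with pytest.raises(ValueError, match="zero depth"):
        ReadTable(pd.DataFrame({"a": [0, 0]}, index=["x", "y"]), meta)
    with pytest.raises(ValueError, match="metadata"):
        ReadTable(pd.DataFrame({"b": [1, 2]}, index=["x", "y"]), meta)
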