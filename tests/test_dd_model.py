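import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddmediate.dd_model import (
    ChoiceData,
    ChoiceDataError,
    FitConfig,
    choice_probability,
    fit_subject,
    negative_log_likelihood,
    read_choices,
    subjective_value,
    write_choices,
)


class TestSubjectiveValue:
    def test_zero_delay_leaves_value_undiscounted(self):
        assert subjective_value(10000, 0, 0.017) == 10000.0

    def test_indifference_point_closed_form(self):
        # 45,000 won at 62 days is worth exactly the 10,000 immediate
        # reward when k = (4.5 - 1) / 62
        k = (45000 / 10000 - 1) / 62
        assert subjective_value(45000, 62, k) == pytest.approx(10000.0, abs=1e-9)

    def test_direct_evaluation(self):
        assert subjective_value(48000, 180, 0.017) == pytest.approx(
            48000 / (1 + 0.017 * 180)
        )

    def test_zero_k_undiscounted(self):
        assert subjective_value(23000, 90, 0.0) == 23000.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            subjective_value(-1, 10, 0.01)
        with pytest.raises(ValueError):
            subjective_value(10000, -1, 0.01)
        with pytest.raises(ValueError):
            subjective_value(10000, 10, -0.01)

    @settings(derandomize=True, max_examples=50)
    @given(
        amount=st.floats(11000, 48000),
        d1=st.integers(2, 179),
        gap=st.integers(1, 100),
        k=st.floats(1e-4, 1.0),
    )
    def test_monotone_decreasing_in_delay(self, amount, d1, gap, k):
        d2 = min(d1 + gap, 180)
        assert subjective_value(amount, d1, k) > subjective_value(amount, d2, k)


class TestChoiceProbability:
    def test_equal_values_give_half(self):
        for beta in (0.0, 1e-4, 1.0):
            assert choice_probability(5000.0, 5000.0, beta) == 0.5

    def test_zero_beta_flat_rule(self):
        assert choice_probability(48000.0, 10000.0, 0.0) == 0.5

    def test_unit_logit_value(self):
        assert choice_probability(11000.0, 10000.0, 0.001) == pytest.approx(
            1 / (1 + np.exp(-1))
        )

    def test_complement_sums_to_one_and_monotone(self):
        diffs = np.linspace(-5000, 5000, 11)
        p = choice_probability(10000 + diffs, 10000.0, 3e-4)
        assert np.allclose(p + (1 - p), 1.0)
        assert (np.diff(p) > 0).all()

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            choice_probability(1.0, 0.0, -0.1)


def _loop_nll(k, beta, choices, trials, eps=1e-12):
    """Naive per-trial oracle, deliberately unvectorized."""
    total = 0.0
    for c, t in zip(choices, trials.trials):
        sv_d = t.delayed_amount / (1 + k * t.delay_days)
        p1 = 1 / (1 + np.exp(-beta * (sv_d - t.immediate_amount)))
        p1 = min(max(p1, eps), 1 - eps)
        total -= np.log(p1) if c == 1 else np.log(1 - p1)
    return total


class TestLikelihood:
    def test_zero_beta_gives_n_log_two(self, trial_set, rng):
        data = ChoiceData("s", rng.integers(0, 2, 120))
        nll = negative_log_likelihood(0.01, 0.0, data, trial_set)
        assert nll == pytest.approx(120 * np.log(2), abs=1e-12)

    def test_matches_loop_oracle_on_random_instances(self, trial_set, rng):
        for _ in range(200):
            k = 10 ** rng.uniform(-4, -0.5)
            beta = 10 ** rng.uniform(-5, -1)
            choices = rng.integers(0, 2, 120)
            data = ChoiceData("s", choices)
            fast = negative_log_likelihood(k, beta, data, trial_set)
            slow = _loop_nll(k, beta, choices, trial_set)
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_saturated_model_near_zero(self, trial_set):
        data = ChoiceData("s", np.ones(120, dtype=int))
        nll = negative_log_likelihood(1e-5, 1.0, data, trial_set)
        assert nll < 1e-3

    def test_misaligned_lengths_rejected(self, trial_set):
        with pytest.raises(ChoiceDataError):
            negative_log_likelihood(0.01, 1e-3, ChoiceData("s", np.zeros(10, int)), trial_set)


class TestFitting:
    def test_noiseless_responder_recovers_k(self, trial_set):
        k_true = 0.01
        sv = subjective_value(trial_set.delayed_amounts, trial_set.delays, k_true)
        choices = (sv > trial_set.immediate_amounts).astype(int)
        fit = fit_subject(ChoiceData("det", choices), trial_set)
        assert fit.k == pytest.approx(k_true, rel=0.10)
        assert fit.boundary_flag == "beta_high"

    def test_all_immediate_chooser_flags_k_high(self, trial_set):
        fit = fit_subject(ChoiceData("imm", np.zeros(120, int)), trial_set)
        assert fit.boundary_flag == "k_high"

    def test_all_delayed_chooser_flags_k_low(self, trial_set):
        fit = fit_subject(ChoiceData("del", np.ones(120, int)), trial_set)
        assert fit.boundary_flag == "k_low"

    def test_refit_is_bit_identical(self, trial_set, rng):
        choices = rng.integers(0, 2, 120)
        a = fit_subject(ChoiceData("s", choices), trial_set)
        b = fit_subject(ChoiceData("s", choices), trial_set)
        assert a == b

    def test_log10_k_consistent_with_k(self, trial_set, rng):
        fit = fit_subject(ChoiceData("s", rng.integers(0, 2, 120)), trial_set)
        assert fit.log10_k == pytest.approx(np.log10(fit.k), abs=1e-12)

    def test_recovery_error_decreases_with_beta(self, trial_set, rng):
        """More deterministic choosers are easier to estimate."""
        errors = []
        for log10_beta in (-4.0, -3.2, -2.5):
            errs = []
            for _ in range(20):
                lk = rng.normal(-2.0, 0.456)
                sv = subjective_value(
                    trial_set.delayed_amounts, trial_set.delays, 10**lk
                )
                p1 = choice_probability(
                    sv, trial_set.immediate_amounts, 10**log10_beta
                )
                choices = (rng.random(120) < p1).astype(int)
                fit = fit_subject(ChoiceData("s", choices), trial_set)
                errs.append(abs(fit.log10_k - lk))
            errors.append(np.median(errs))
        assert errors[0] > errors[-1]


class TestChoiceIO:
    def test_round_trip(self, trial_set, rng, tmp_path):
        data = [
            ChoiceData(f"S{i}", rng.integers(0, 2, 120)) for i in range(3)
        ]
        path = tmp_path / "choices.csv"
        write_choices(data, trial_set, path)
        back = read_choices(path, trial_set)
        assert [d.subject_id for d in back] == [d.subject_id for d in data]
        for a, b in zip(data, back):
            assert np.array_equal(a.choices, b.choices)

    def test_incomplete_subject_rejected(self, trial_set, rng, tmp_path):
        import pandas as pd

        path = tmp_path / "choices.csv"
        pd.DataFrame(
            {"subject_id": ["S1"] * 119, "trial_id": range(1, 120), "choice": 0}
        ).to_csv(path, index=False)
        with pytest.raises(ChoiceDataError, match="S1"):
            read_choices(path, trial_set)

    def test_non_binary_choice_rejected(self):
        with pytest.raises(ChoiceDataError):
            ChoiceData("s", np.array([0, 1, 2]))
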