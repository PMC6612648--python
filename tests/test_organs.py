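"""Organ-level decomposition, redistribution rule, and decay constants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmsbmr.metabolic import universal_decline
from rmsbmr.organs import (ORGAN_DECAY, ORGAN_LABELS, CalibrationError,
                           OrganProfile, calibrate_reference,
                           decompose_subject, distribute_delta,
                           load_reference_profile, mean_decay_constant,
                           organ_msbmr_mean, organ_trajectory)
from rmsbmr.renormalize import second_renorm

# Tabulated renormalized organ weights of the worked samples (kg), in the
# canonical organ order; totals 64.38 (s3) and 53.92 (s4).
S3 = {"height": 170.0, "age": 50, "w0": 135.10,
      "w_k": [26.39, 1.71, 1.33, 0.31, 0.29, 12.67, 21.69]}
S4 = {"height": 157.7, "age": 80, "w0": 64.60,
      "w_k": [22.10, 1.43, 1.11, 0.26, 0.24, 10.61, 18.16]}


class TestOrganMsbmrMean:
    def test_single_organ(self):
        assert organ_msbmr_mean([2.0], [200.0]) == 200.0

    def test_equal_weights_give_arithmetic_mean(self):
        rates = [13.0, 200.0, 240.0]
        assert organ_msbmr_mean([1, 1, 1], rates) == pytest.approx(
            np.mean(rates))

    def test_reference_table_weighted_mean(self, reference):
        # weighted mean of the renormalized reference column
        value = organ_msbmr_mean(reference.w_k_r, reference.msbmr_k)
        assert value == pytest.approx(22.159, abs=2e-3)

    def test_zero_total_weight_rejected(self):
        with pytest.raises(ValueError):
            organ_msbmr_mean([0.0, 0.0], [13.0, 200.0])


class TestDistributeDelta:
    def test_q_zero_splits_equally(self, reference):
        deltas = distribute_delta(7.0, reference.msbmr_k, q=0.0)
        assert np.allclose(deltas, 1.0)

    @given(total=st.floats(-20, 20),
           rates=st.lists(st.floats(1.0, 500.0), min_size=2, max_size=8))
    @settings(max_examples=100, derandomize=True)
    def test_mass_conservation(self, total, rates):
        deltas = distribute_delta(total, np.array(rates))
        assert deltas.sum() == pytest.approx(total, abs=1e-12)

    def test_low_rate_tissue_absorbs_most(self, reference):
        # 3.0 kg over the reference rates: adipose ~1.20, residual ~1.35,
        # muscle ~0.40 (closed-form msBMR^-1.15 shares)
        deltas = dict(zip(reference.labels,
                          distribute_delta(3.0, reference.msbmr_k)))
        assert deltas["adipose_tissue"] == pytest.approx(1.20, abs=0.01)
        assert deltas["residual"] == pytest.approx(1.355, abs=0.01)
        assert deltas["skeletal_muscle"] == pytest.approx(0.40, abs=0.01)


class TestCalibrateReference:
    def test_fixture_mode_returns_printed_reference(self, organ_profile):
        ref = calibrate_reference(organ_profile, mode="fixture")
        assert ref.weight_r == 67.0
        assert ref.msbmr_r == 24.59
        assert ref.age_r == 32
        assert ref.w_k_r.sum() == pytest.approx(67.0, abs=0.01)
        # the printed reference msBMR is F at the reference age
        assert universal_decline(32) == pytest.approx(24.59, abs=5e-3)

    def test_reference_weight_solves_second_renorm(self):
        w, _ = second_renorm(175.6, 32)
        assert w == pytest.approx(67.0, abs=0.1)

    def test_search_mode_trivial_fixed_point(self):
        # all organ rates equal c: the weighted mean is c at any weights,
        # so the fixed point is exactly the age where F(T) = c
        c = 22.0
        profile = OrganProfile(labels=ORGAN_LABELS,
                               msbmr_k=np.full(7, c),
                               w0_k=np.full(7, 10.0), height=175.6)
        ref = calibrate_reference(profile, mode="search")
        t_expected = np.log(27.63 / c) / 0.00364
        assert ref.age_r == pytest.approx(t_expected, abs=1e-6)
        assert ref.msbmr_r == pytest.approx(c, abs=1e-9)

    def test_search_mode_finds_fixed_point_on_shipped_table(
            self, organ_profile):
        ref = calibrate_reference(organ_profile, mode="search")
        assert 16 <= ref.age_r <= 106
        assert ref.msbmr_r == pytest.approx(
            universal_decline(ref.age_r), abs=0.01)

    def test_search_mode_no_fixed_point_raises_with_diagnostics(self):
        profile = OrganProfile(labels=ORGAN_LABELS,
                               msbmr_k=np.full(7, 50.0),
                               w0_k=np.full(7, 10.0), height=175.6)
        with pytest.raises(CalibrationError) as err:
            calibrate_reference(profile, mode="search")
        assert {"age", "residual"} <= set(err.value.residuals.columns)


class TestDecomposeSubject:
    @pytest.mark.parametrize("sample, total", [(S3, 64.38), (S4, 53.92)])
    def test_tabulated_renormalized_columns(self, reference, sample, total):
        table = decompose_subject(sample["height"], sample["age"], reference)
        assert table.attrs["weight"] == pytest.approx(total, abs=0.02)
        assert np.allclose(table["w_k"], sample["w_k"], atol=0.01)

    def test_organ_fractions_invariant_across_subjects(self, reference):
        t3 = decompose_subject(S3["height"], S3["age"], reference)
        t4 = decompose_subject(S4["height"], S4["age"], reference)
        f3 = t3["w_k"] / t3["w_k"].sum()
        f4 = t4["w_k"] / t4["w_k"].sum()
        assert np.allclose(f3, f4, atol=1e-12)

    def test_reference_decomposes_to_itself(self, organ_profile):
        # a search-mode reference has weight_r equal to its own second
        # renormalization, so self-decomposition is the identity
        ref = calibrate_reference(organ_profile, mode="search")
        table = decompose_subject(ref.height_r, ref.age_r, ref)
        assert np.allclose(table["w_k"], ref.w_k_r, atol=1e-9)

    def test_recorded_weight_recovers_original_decomposition(self, reference):
        table = decompose_subject(S4["height"], S4["age"], reference,
                                  recorded_weight=S4["w0"])
        # the tabulated organ column sums to 66.99 against the 67.0 total,
        # so recovery carries the table's own 0.01-kg rounding
        assert table["w0_k"].sum() == pytest.approx(S4["w0"], abs=0.01)
        # surplus lands mainly on adipose/residual/muscle
        surplus = table.set_index("organ")
        delta = surplus["w0_k"] - surplus["w_k"]
        assert delta[["adipose_tissue", "residual",
                      "skeletal_muscle"]].sum() > 0.9 * delta.sum()

    def test_negative_organ_weight_names_the_organ(self, reference):
        with pytest.raises(ValueError, match="residual|adipose"):
            decompose_subject(S4["height"], S4["age"], reference,
                              recorded_weight=5.0)


class TestDecayConstants:
    def test_equal_constants_pass_through(self):
        assert mean_decay_constant([10, 20, 30], [0.004] * 3) == \
            pytest.approx(0.004)

    def test_single_organ(self):
        assert mean_decay_constant([50.0], [0.00624]) == 0.00624

    def test_bmr_weighted_mean_matches_global_decay(self, reference):
        bmr_k = reference.w_k_r * reference.msbmr_k
        u_k = [ORGAN_DECAY[o] for o in reference.labels]
        u = mean_decay_constant(bmr_k, u_k)
        assert u == pytest.approx(0.00364, rel=0.01)

    def test_zero_total_bmr_rejected(self):
        with pytest.raises(ValueError):
            mean_decay_constant([0.0, 0.0], [0.001, 0.002])


class TestOrganTrajectory:
    def test_anchor_value(self, reference):
        assert organ_trajectory("liver", 32) == pytest.approx(200.0)

    def test_liver_decade_decay(self):
        ratio = organ_trajectory("liver", 42) / organ_trajectory("liver", 32)
        assert ratio == pytest.approx(np.exp(-0.0624), rel=1e-12)

    def test_unknown_organ(self):
        with pytest.raises(KeyError):
            organ_trajectory("spleen", 40)

    def test_weighted_sum_matches_first_order_expansion(self, reference):
        """Summing per-organ declines reproduces the whole-body exponential
        within the first-order tolerance at five years past the anchor."""
        t = 37.0
        w = reference.w_k_r
        summed = sum(w_i * organ_trajectory(o, t)
                     for o, w_i in zip(reference.labels, w)) / w.sum()
        msbmr0 = organ_msbmr_mean(w, reference.msbmr_k)
        bmr_k = w * reference.msbmr_k
        u_bar = mean_decay_constant(bmr_k,
                                    [ORGAN_DECAY[o] for o in reference.labels])
        linearized = msbmr0 * (1 - u_bar * (t - 32))
        assert summed == pytest.approx(linearized, rel=1e-3)
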