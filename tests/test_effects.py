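"""Effect-size conversion and ingestion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metamediate import (
    EffectEntry,
    StudyRecord,
    beta_to_r,
    build_correlation_sets,
    fisher_z_aggregate,
    path_model_implied_correlations,
)
from metamediate._linalg import InadmissibleMatrixError
from metamediate.effects import EffectConversionError
from metamediate.stage2 import closed_form_saturated

from conftest import make_record


class TestBetaToR:
    @pytest.mark.parametrize(
        "beta, expected",
        [(0.20, 0.246), (0.00, 0.05), (-0.30, -0.294)],
    )
    def test_conversion_arithmetic(self, beta, expected):
        assert beta_to_r(beta) == pytest.approx(expected, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(EffectConversionError, match="S9"):
            beta_to_r(1.0, study_id="S9")

    def test_warns_outside_validity_range(self):
        with pytest.warns(UserWarning, match="validity range"):
            beta_to_r(0.6)

    @given(st.floats(-0.95, 0.95), st.floats(-0.95, 0.95))
    @settings(deadline=None)
    def test_monotone_increasing(self, b1, b2):
        lo, hi = sorted([b1, b2])
        assert beta_to_r(lo) <= beta_to_r(hi)

    def test_jump_of_005_at_zero(self):
        eps = 1e-9
        assert beta_to_r(0.0) - beta_to_r(-eps) == pytest.approx(0.05, abs=1e-6)


class TestPathModelImplied:
    @pytest.mark.parametrize(
        "payload, expected",
        [
            ({"a": 0.21, "b": 0.25, "c_prime": 0.18}, (0.21, 0.2325, 0.2878)),
            ({"a": 0, "b": 0, "c_prime": 0}, (0.0, 0.0, 0.0)),
            ({"a": 0.5, "b": 0, "c_prime": 0}, (0.5, 0.0, 0.0)),
        ],
    )
    def test_path_tracing(self, payload, expected):
        np.testing.assert_allclose(
            path_model_implied_correlations(payload), expected, atol=1e-12
        )

    def test_symmetric_unit_diagonal(self):
        from metamediate._linalg import triple_to_matrix

        r = path_model_implied_correlations({"a": 0.4, "b": -0.3, "c_prime": 0.2})
        R = triple_to_matrix(r)
        np.testing.assert_allclose(R, R.T)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_inadmissible_paths_error(self):
        with pytest.raises(InadmissibleMatrixError):
            path_model_implied_correlations({"a": 0.9, "b": 0.9, "c_prime": 0.9})

    def test_non_recursive_rejected(self):
        B = np.zeros((3, 3))
        B[0, 2] = 0.3  # outcome feeding back into exposure
        with pytest.raises(EffectConversionError, match="recursive"):
            path_model_implied_correlations(B)

    @given(
        st.floats(-0.6, 0.6), st.floats(-0.6, 0.6), st.floats(-0.6, 0.6)
    )
    @settings(deadline=None, max_examples=200)
    def test_round_trip_through_saturated_solver(self, a, b, c):
        payload = {"a": a, "b": b, "c_prime": c}
        try:
            r = path_model_implied_correlations(payload)
        except InadmissibleMatrixError:
            return
        np.testing.assert_allclose(
            closed_form_saturated(r), [a, b, c], atol=1e-10
        )


class TestFisherZAggregate:
    def test_identical_values_identity(self):
        assert fisher_z_aggregate([0.3, 0.3]) == pytest.approx(0.3, abs=1e-12)

    def test_two_value_composite(self):
        # tanh(mean(atanh([0.3, 0.5]))) computed independently
        expected = np.tanh((np.arctanh(0.3) + np.arctanh(0.5)) / 2)
        assert fisher_z_aggregate([0.3, 0.5]) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.4048, abs=5e-5)

    def test_single_zero(self):
        assert fisher_z_aggregate([0.0]) == 0.0

    def test_empty_raises(self):
        with pytest.raises(ValueError, match="aggregate"):
            fisher_z_aggregate([])

    @given(st.lists(st.floats(-0.9, 0.9), min_size=1, max_size=8))
    @settings(deadline=None)
    def test_bounded_by_inputs(self, values):
        agg = fisher_z_aggregate(values)
        assert min(values) - 1e-12 <= agg <= max(values) + 1e-12


class TestBuildCorrelationSets:
    def test_pass_through(self):
        rec = make_record(pairs={"XM": 0.2, "XY": 0.3})
        (cset,) = build_correlation_sets([rec])
        np.testing.assert_allclose(cset.r[:2], [0.2, 0.3])
        assert cset.mask.tolist() == [True, True, False]

    def test_within_study_composite(self):
        rec = StudyRecord(
            "S1", 50,
            entries=[
                EffectEntry("S1", "XM", "correlation", 0.3),
                EffectEntry("S1", "XM", "correlation", 0.5),
            ],
        )
        (cset,) = build_correlation_sets([rec])
        expected = np.tanh((np.arctanh(0.3) + np.arctanh(0.5)) / 2)
        assert cset.r[0] == pytest.approx(expected, abs=1e-12)

    def test_beta_entry_converted(self):
        rec = StudyRecord(
            "S1", 50, entries=[EffectEntry("S1", "XY", "std_beta", 0.20)]
        )
        log = []
        (cset,) = build_correlation_sets([rec], log)
        assert cset.r[1] == pytest.approx(0.246)
        assert any("std_beta" in line for line in log)

    def test_path_model_informs_all_pairs(self):
        rec = StudyRecord(
            "S1", 50,
            entries=[EffectEntry("S1", "XM", "path_model",
                                 path_payload={"a": 0.21, "b": 0.25,
                                               "c_prime": 0.18})],
        )
        (cset,) = build_correlation_sets([rec])
        assert cset.mask.all()
        np.testing.assert_allclose(cset.r, [0.21, 0.2325, 0.2878], atol=1e-12)

    def test_mask_counts_match_pairs_informed(self):
        recs = [
            make_record("S1", pairs={"XM": 0.1}),
            make_record("S2", pairs={"XM": 0.1, "MY": 0.2}),
            make_record("S3", pairs={"XM": 0.1, "XY": 0.2, "MY": 0.3}),
        ]
        sets = build_correlation_sets(recs)
        assert [int(s.mask.sum()) for s in sets] == [1, 2, 3]

    def test_unusable_study_dropped_with_warning(self):
        bad = StudyRecord("S1", 50,
                          entries=[EffectEntry("S1", "XM", "std_beta", 1.0)])
        good = make_record("S2")
        log = []
        with pytest.warns(UserWarning):
            sets = build_correlation_sets([bad, good], log)
        assert [s.study_id for s in sets] == ["S2"]
        assert any("dropped" in line for line in log)

    def test_non_psd_triple_repaired_and_logged(self):
        rec = make_record(pairs={"XM": 0.9, "XY": 0.9, "MY": -0.5})
        log = []
        sets = build_correlation_sets([rec], log)
        if sets:  # repaired within the 0.05/element cap, else dropped
            from metamediate._linalg import is_positive_definite, triple_to_matrix

            assert is_positive_definite(triple_to_matrix(sets[0].r), tol=-1e-9)
            assert any("projected" in line for line in log)
        else:
            assert any("dropped" in line for line in log)
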