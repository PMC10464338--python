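"""The quantification-processing chain: filters, imputation, quantile
normalization (checked against an explicit sort/argsort oracle) and
per-group Z-scoring, plus the stage-order enforcement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hexelute import (
    PeptideEvidence,
    PipelineOrderError,
    ValidationError,
    filter_detected,
    filter_high_confidence,
    impute_min,
    log2_zscore_by_group,
    quantile_normalize,
)
from hexelute.preprocess import STAGE_ORDER, quantile_normalize_matrix

from conftest import make_table


def quantile_normalize_oracle(X):
    """Brute-force quantile normalization with explicit bookkeeping."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(m):
        col = list(X[:, j])
        sorted_rows = sorted(range(n), key=lambda k: (col[k], k))
        rank_of = {row: pos for pos, row in enumerate(sorted_rows)}
        for i in range(n):
            tied_rows = [k for k in range(n) if col[k] == col[i]]
            out[i, j] = np.mean([ref[rank_of[k]] for k in tied_rows])
    return out


class TestHighConfidenceFilter:
    @pytest.mark.parametrize(
        "unique,strict,kept",
        [
            (1, 2, True),   # one unique and two strict
            (0, 3, True),   # more than two strict alone
            (1, 1, False),  # fails both clauses
            (0, 2, False),  # two strict but no unique
            (5, 0, False),  # unique peptides alone are not enough
        ],
    )
    def test_keep_rule(self, unique, strict, kept):
        table = make_table([[1.0, 1.0, 1.0, 1.0]], protein_ids=["P0"])
        evidence = [PeptideEvidence("P0", unique, strict)]
        out = filter_high_confidence(table, evidence)
        assert ("P0" in out.protein_ids) is kept

    def test_missing_evidence_record_errors(self, four_group_table):
        with pytest.raises(ValidationError, match="P2"):
            filter_high_confidence(
                four_group_table,
                [PeptideEvidence("P0", 1, 2), PeptideEvidence("P1", 1, 2)],
            )

    def test_row_order_preserved(self, four_group_table):
        evidence = [PeptideEvidence(p, 1, 2) for p in four_group_table.protein_ids]
        out = filter_high_confidence(four_group_table, evidence)
        assert out.protein_ids == four_group_table.protein_ids


class TestDetectionFilter:
    def test_all_missing_removed_and_single_observation_kept(self):
        table = make_table(
            [[np.nan] * 4, [np.nan, 2.0, np.nan, np.nan]],
            stages=("high_confidence",),
        )
        out = filter_detected(table)
        assert out.protein_ids == ["P1"]

    def test_min_samples_equal_to_width_keeps_complete_rows_only(self):
        table = make_table(
            [[1.0, 2.0, 3.0, 4.0], [1.0, np.nan, 3.0, 4.0]],
            stages=("high_confidence",),
        )
        out = filter_detected(table, min_samples=4)
        assert out.protein_ids == ["P0"]


class TestImputeMin:
    def test_missing_replaced_by_column_minimum(self):
        table = make_table(
            [[np.nan, 10.0], [2.0, 20.0], [4.0, 30.0]],
            stages=("high_confidence", "detected"),
        )
        out, provenance = impute_min(table)
        assert out.abundance.iloc[0, 0] == 2.0
        assert provenance.iloc[0, 0] == "imputed"

    def test_columns_impute_their_own_minima(self):
        table = make_table(
            [[np.nan, np.nan], [2.0, 30.0], [4.0, 20.0]],
            stages=("high_confidence", "detected"),
        )
        out, _ = impute_min(table)
        assert list(out.abundance.iloc[0]) == [2.0, 20.0]

    def test_global_scope_uses_matrix_minimum(self):
        table = make_table(
            [[np.nan, np.nan], [2.0, 30.0], [4.0, 20.0]],
            stages=("high_confidence", "detected"),
        )
        out, _ = impute_min(table, scope="global")
        assert list(out.abundance.iloc[0]) == [2.0, 2.0]

    def test_complete_table_unchanged_and_all_observed(self):
        table = make_table(
            [[1.0, 2.0], [3.0, 4.0]], stages=("high_confidence", "detected")
        )
        out, provenance = impute_min(table)
        assert out.abundance.equals(table.abundance)
        assert (provenance == "observed").all().all()

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(5)
        values = rng.lognormal(1, 1, size=(20, 4))
        mask = rng.random(values.shape) < 0.3
        mask[0] = False  # keep every column imputable
        values[mask] = np.nan
        table = make_table(values, stages=("high_confidence", "detected"))
        out, provenance = impute_min(table)
        observed = ~np.isnan(values)
        assert np.array_equal(
            out.abundance.to_numpy()[observed], values[observed]
        )
        assert ((provenance == "observed").to_numpy() == observed).all()

    def test_all_missing_column_errors(self):
        table = make_table(
            [[1.0, np.nan], [2.0, np.nan]], stages=("high_confidence", "detected")
        )
        with pytest.raises(ValidationError):
            impute_min(table)


class TestQuantileNormalize:
    def test_three_by_two_worked_example(self):
        # order statistics means: (1+4)/2, (2+5)/2, (3+6)/2
        out = quantile_normalize_matrix(pd.DataFrame([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        assert np.allclose(out.to_numpy(), expected)

    def test_identical_columns_unchanged(self):
        values = pd.DataFrame([[3.0, 3.0], [1.0, 1.0], [2.0, 2.0]])
        out = quantile_normalize_matrix(values)
        assert np.allclose(out.to_numpy(), values.to_numpy())

    def test_ties_receive_mean_of_reference_quantiles(self):
        out = quantile_normalize_matrix(pd.DataFrame([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]]))
        ref = np.sort([[1, 10], [1, 20], [5, 30]], axis=0).mean(axis=1).astype(float)
        assert np.allclose(out[0], [ref[:2].mean(), ref[:2].mean(), ref[2]])

    def test_missing_values_rejected(self):
        table = make_table(
            [[1.0, np.nan], [2.0, 3.0]],
            stages=("high_confidence", "detected", "imputed"),
        )
        with pytest.raises(ValidationError):
            quantile_normalize(table)

    @settings(max_examples=50, deadline=None)
    @given(
        arrays(
            float, (10, 4),
            elements=st.floats(0.1, 1e6, allow_nan=False, allow_infinity=False),
        )
    )
    def test_matches_brute_force_oracle(self, X):
        ours = quantile_normalize_matrix(pd.DataFrame(X)).to_numpy()
        assert np.allclose(ours, quantile_normalize_oracle(X))

    @settings(max_examples=25, deadline=None)
    @given(
        arrays(
            float, (8, 3),
            elements=st.floats(0.1, 100, allow_nan=False, allow_infinity=False),
            unique=True,  # the tie rule averages reference quantiles, which
            # deliberately trades these invariants for stable tied outputs
        )
    )
    def test_columns_share_sorted_values_and_idempotent(self, X):
        out = quantile_normalize_matrix(pd.DataFrame(X)).to_numpy()
        for j in range(1, out.shape[1]):
            assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, j]))
        again = quantile_normalize_matrix(pd.DataFrame(out)).to_numpy()
        assert np.allclose(out, again)


class TestLog2ZscoreByGroup:
    def stages(self):
        return STAGE_ORDER

    def test_powers_of_two_give_unit_spaced_zscores(self):
        table = make_table(
            [[2.0] * 4, [4.0] * 4, [8.0] * 4], stages=self.stages()
        )
        z = log2_zscore_by_group(table, "IB")
        assert np.allclose(z.to_numpy(), [-1.0, 0.0, 1.0])

    def test_zero_sd_errors_naming_group(self):
        table = make_table([[4.0] * 4, [4.0] * 4], stages=self.stages())
        with pytest.raises(ValidationError, match="HD5"):
            log2_zscore_by_group(table, "HD5")

    def test_single_protein_group_errors(self):
        table = make_table([[4.0] * 4], stages=self.stages())
        with pytest.raises(ValidationError):
            log2_zscore_by_group(table, "IB")

    def test_output_standardized(self):
        rng = np.random.default_rng(7)
        table = make_table(rng.lognormal(3, 1, (30, 4)), stages=self.stages())
        z = log2_zscore_by_group(table, "HD2")
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12


class TestStageOrderEnforcement:
    def test_high_confidence_must_run_first(self, four_group_table):
        staged = four_group_table.with_stage("detected")
        with pytest.raises(PipelineOrderError):
            filter_high_confidence(staged, [])

    def test_each_stage_requires_predecessor(self, four_group_table):
        with pytest.raises(PipelineOrderError):
            filter_detected(four_group_table)
        with pytest.raises(PipelineOrderError):
            impute_min(four_group_table)
        with pytest.raises(PipelineOrderError):
            quantile_normalize(four_group_table)
        with pytest.raises(PipelineOrderError):
            log2_zscore_by_group(four_group_table, "IB")
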