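import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mirlink import ExpressionMatrix, MirlinkError, ParameterError, ProbeMap
from mirlink.containers import ConsistencyError
from mirlink.preprocess import (
    collapse_probes,
    filter_flags,
    log2_transform,
    preprocess_pipeline,
    quantile_normalize,
)

from conftest import make_sample_meta


def probe_matrix(values, flags=None, n_probes_per_feature=1, scale="log2",
                 stages=("3w",), reps=None):
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    reps = reps or (n_samples + 1) // 2
    meta = make_sample_meta(stages, reps).iloc[:n_samples]
    probe_ids = [f"p{i}" for i in range(values.shape[0])]
    fmap = pd.DataFrame(
        {
            "feature_id": [f"f{i // n_probes_per_feature}" for i in range(values.shape[0])],
            "feature_type": "mrna",
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    kwargs = {}
    if flags is not None:
        kwargs["flags"] = pd.DataFrame(np.asarray(flags, dtype=int), index=fmap.index,
                                       columns=list(meta.index))
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=fmap.index, columns=list(meta.index)),
        sample_meta=meta, level="probe", scale=scale, feature_map=fmap, **kwargs,
    )


class TestFilterFlags:
    def test_all_fine_is_identity(self):
        m = probe_matrix([[1, 2], [3, 4]], flags=[[0, 0], [0, 0]])
        out = filter_flags(m, 0.5)
        assert out.values.equals(m.values)

    def test_fully_flagged_probe_dropped(self):
        m = probe_matrix([[1, 2], [3, 4]], flags=[[1, 2], [0, 0]])
        out = filter_flags(m, 0.5)
        assert list(out.values.index) == ["p1"]

    def test_partially_flagged_probe_kept_with_missing_cells(self):
        # 6 samples, 2 flagged: fine fraction 4/6 >= 0.5 -> retained, 2 NaN
        vals = [[1.0, 2, 3, 4, 5, 6]]
        flags = [[0, 1, 0, 0, 1, 0]]
        m = probe_matrix(vals, flags=flags, stages=("3w",), reps=3)
        out = filter_flags(m, 0.5)
        row = out.values.iloc[0]
        assert row.isna().sum() == 2
        # surviving values unchanged
        assert list(row.dropna()) == [1.0, 3.0, 4.0, 6.0]

    def test_requires_flags(self):
        m = probe_matrix([[1, 2], [3, 4]])
        with pytest.raises(ParameterError):
            filter_flags(m)


class TestLog2:
    def test_closed_forms(self):
        m = probe_matrix([[8.0, 1.0], [2.0, 4.0]], scale="linear")
        out = log2_transform(m)
        assert out.values.iloc[0, 0] == 3.0
        assert out.values.iloc[0, 1] == 0.0
        assert list(out.values.iloc[1]) == [1.0, 2.0]
        assert out.scale == "log2"

    def test_ordering_preserved(self):
        m = probe_matrix([[2.0], [4.0], [8.0]], scale="linear", reps=1)
        # single-sample column just for the elementwise contract
        out = log2_transform(m)
        assert list(out.values.iloc[:, 0]) == [1.0, 2.0, 3.0]

    def test_rejects_nonpositive_and_double_application(self):
        m = probe_matrix([[0.0, 2.0]], scale="linear")
        with pytest.raises(MirlinkError, match="nonpositive"):
            log2_transform(m)
        logged = log2_transform(probe_matrix([[1.0, 2.0]], scale="linear"))
        with pytest.raises(MirlinkError, match="already"):
            log2_transform(logged)


class TestQuantileNormalize:
    def test_hand_computed_2x2(self):
        m = probe_matrix([[1.0, 3.0], [2.0, 4.0]])
        out = quantile_normalize(m)
        # reference distribution (sorted-mean) is (1.5, 3.5)? no: columns
        # (1,2) and (3,4) -> sorted means (2, 3); row A holds each column's
        # smaller value, row B the larger.
        assert list(out.values.loc["p0"]) == [2.0, 2.0]
        assert list(out.values.loc["p1"]) == [3.0, 3.0]

    def test_identical_columns_are_a_fixed_point(self):
        col = np.array([5.0, 1.0, 3.0, 2.0])
        m = probe_matrix(np.column_stack([col, col]))
        out = quantile_normalize(m)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_single_column_unchanged(self):
        m = probe_matrix([[3.0], [1.0], [2.0]], reps=1)
        out = quantile_normalize(m)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_single_row_returned_unchanged_with_warning(self, caplog):
        m = probe_matrix([[3.0, 1.0]])
        with caplog.at_level("WARNING", logger="mirlink"):
            out = quantile_normalize(m)
        assert out.values.equals(m.values)
        assert any("single-row" in r.message for r in caplog.records)

    def test_ties_get_mean_of_spanned_reference_values(self):
        m = probe_matrix([[1.0, 10.0], [1.0, 20.0], [5.0, 30.0]], reps=1, stages=("3w",))
        out = quantile_normalize(m)
        ref = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)  # (5.5, 10.5, 17.5)
        col0 = out.values.iloc[:, 0].to_numpy()
        assert col0[0] == col0[1] == pytest.approx(ref[:2].mean())
        assert col0[2] == pytest.approx(ref[2])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(np.float64, (7, 4), unique=True,
               elements=st.floats(-50, 50, allow_nan=False,
                                  allow_infinity=False, width=32))
    )
    def test_columns_identical_and_ranks_preserved(self, vals):
        # tie-free case: ties intentionally shrink a column's spread
        # (tie groups map to their mean), so distribution equality is a
        # property of tie-free complete data only
        m = probe_matrix(vals)
        out = quantile_normalize(m).values.to_numpy()
        # all column empirical distributions identical (Kolmogorov distance 0)
        sorted_cols = np.sort(out, axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]], atol=1e-12)
        # within-column rank order preserved
        for j in range(vals.shape[1]):
            before = np.argsort(np.argsort(vals[:, j], kind="stable"), kind="stable")
            order = np.argsort(vals[:, j], kind="stable")
            assert np.all(np.diff(out[order, j]) >= -1e-12), (j, before)

    def test_missing_cells_stay_missing(self):
        vals = np.array([[1.0, np.nan], [2.0, 4.0], [3.0, 5.0]])
        out = quantile_normalize(probe_matrix(vals)).values.to_numpy()
        assert np.isnan(out[0, 1])
        assert np.isfinite(out[[1, 2], 1]).all()


class TestCollapseProbes:
    def test_triplicate_identity_median_mean(self):
        m = probe_matrix([[7.0, 7], [7, 7], [7, 7]], n_probes_per_feature=3)
        out = collapse_probes(m)
        assert out.level == "feature"
        assert list(out.values.loc["f0"]) == [7.0, 7.0]

    def test_median_and_mean_definitions(self):
        m = probe_matrix([[1.0, 1], [2, 2], [9, 9]], n_probes_per_feature=3)
        assert collapse_probes(m, method="median").values.iloc[0, 0] == 2.0
        assert collapse_probes(m, method="mean").values.iloc[0, 0] == 4.0

    def test_unmapped_probe_strict_vs_lenient(self):
        m = probe_matrix([[1.0, 2], [3, 4]])
        pmap = ProbeMap(m.feature_map.iloc[[0]])
        with pytest.raises(ConsistencyError):
            collapse_probes(m, pmap, strict=True)
        out = collapse_probes(m, pmap, strict=False)
        assert list(out.values.index) == ["f0"]

    def test_feature_level_input_rejected(self):
        m = probe_matrix([[1.0, 2]])
        feat = collapse_probes(m)
        with pytest.raises(ConsistencyError):
            collapse_probes(feat)


def test_pipeline_enforces_normalize_before_collapse():
    """The fixed chain equals filter -> quantile-normalize -> collapse, and
    differs from collapsing first (the two orders are not interchangeable)."""
    rng = np.random.default_rng(0)
    vals = rng.normal(8, 1, size=(30, 4))
    flags = np.zeros_like(vals, dtype=int)
    m = probe_matrix(vals, flags=flags, n_probes_per_feature=3)
    out, report = preprocess_pipeline(m)
    manual = collapse_probes(quantile_normalize(filter_flags(m)), method="median")
    assert np.allclose(out.values.to_numpy(), manual.values.to_numpy())
    assert report.features_out == 10
    swapped = quantile_normalize(collapse_probes(filter_flags(m), method="median"))
    assert not np.allclose(out.values.to_numpy(), swapped.values.to_numpy())


def test_probe_noise_reduced_by_triplicate_collapsing(small_design):
    """Collapsing replicate probes shrinks measurement scatter around the
    per-feature sample mean."""
    from mirlink import DesignSpec, EffectModel
    from mirlink.synthetic import generate_expression, generate_truth

    design = DesignSpec(n_genes=400, n_mirnas=5, seed=4, flag_fail_rate=0.0,
                        stages=("3w",))
    effects = EffectModel(frac_de_mirnas=0.0, independent_de_frac=0.0,
                          noise_sd_log2=0.0, probe_noise_sd_log2=0.4)
    truth = generate_truth(design, effects)
    mrna, _ = generate_expression(truth, design, effects)
    collapsed = collapse_probes(mrna, method="mean")
    probe_sd = (mrna.values.groupby(mrna.feature_map["feature_id"]).transform("mean")
                - mrna.values).to_numpy().std()
    resid = collapsed.values.to_numpy() - collapsed.values.to_numpy().mean(axis=1,
                                                                           keepdims=True)
    assert resid.std() < probe_sd
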