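import numpy as np
import pandas as pd
import pytest

from mirlink import DesignSpec, EffectModel, ExpressionMatrix, PipelineConfig
from mirlink.synthetic import write_fixture


def make_sample_meta(stages=("3w",), reps=3):
    rows = []
    for st in stages:
        for group in ("control", "irradiated"):
            for r in range(1, reps + 1):
                rows.append(
                    {"sample_id": f"{st}_{group}_r{r}", "group": group,
                     "stage": st, "replicate": str(r)}
                )
    return pd.DataFrame(rows).set_index("sample_id")


def make_feature_matrix(values: np.ndarray, feature_ids, stages=("3w",), reps=None):
    """Feature-level ExpressionMatrix with a standard sample layout."""
    n_samples = values.shape[1]
    if reps is None:
        reps = n_samples // (2 * len(stages))
    meta = make_sample_meta(stages, reps)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(feature_ids, name="feature_id"),
                            columns=list(meta.index)),
        sample_meta=meta,
        level="feature",
        scale="log2",
    )


@pytest.fixture(scope="session")
def small_design():
    return DesignSpec(n_genes=300, n_mirnas=40, seed=11)


@pytest.fixture(scope="session")
def small_effects():
    return EffectModel()


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_design, small_effects):
    """A complete on-disk synthetic fixture at the default study conditions."""
    out = tmp_path_factory.mktemp("fixture")
    return write_fixture(out, small_design, small_effects)


@pytest.fixture()
def pipeline_config(fixture_dir, tmp_path):
    p = fixture_dir
    return PipelineConfig(
        mrna_expression=str(p["mrna_expression"]),
        mrna_flags=str(p["mrna_flags"]),
        mirna_expression=str(p["mirna_expression"]),
        mirna_flags=str(p["mirna_flags"]),
        sample_sheet=str(p["sample_sheet"]),
        target_map=str(p["target_map"]),
        truth_de_labels=str(p["truth_de_labels"]),
        truth_reciprocal_pairs=str(p["truth_reciprocal_pairs"]),
        out_dir=str(tmp_path / "run"),
        seed=7,
    )
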