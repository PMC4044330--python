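"""Relative quantification of qPCR assays with the 2^-ddCt method.

Input is a long-format Ct table: one row per technical replicate with
``sample_id``, ``group``, ``stage``, ``assay_id``, ``assay_role``
(``target``/``reference``) and ``ct`` in cycles. Replicates are averaged on
the Ct scale; for each sample, dCt = mean Ct(target) - mean Ct(reference);
ddCt subtracts the mean dCt of the calibrator-group samples of the same
stage and assay; the relative quantity is rq = 2^-ddCt. No amplification-
efficiency correction is applied (the pure doubling model). The reference
assay is always named explicitly — there is no default housekeeping gene.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MirlinkError, ParameterError

logger = logging.getLogger("mirlink")

__all__ = ["read_ct_table", "delta_delta_ct"]

CT_COLUMNS = ["sample_id", "group", "stage", "assay_id", "assay_role", "ct"]
RQ_COLUMNS = [
    "sample_id",
    "group",
    "stage",
    "assay_id",
    "delta_ct",
    "delta_delta_ct",
    "rq",
    "high_replicate_sd",
]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise MirlinkError(f"Ct table {path} lacks columns {missing}")
    return validate_ct_table(df)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    bad = table[(table["ct"] <= 0) | (table["ct"] >= 45)]
    if len(bad):
        raise MirlinkError(
            f"Ct values must lie in (0, 45) cycles; offending rows: {bad.index.tolist()[:5]}"
        )
    roles = set(table["assay_role"]) - {"target", "reference"}
    if roles:
        raise MirlinkError(f"unknown assay roles: {sorted(roles)}")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    reference_assay: str,
    calibrator_group: str = "control",
    sd_warn_threshold: float = 0.5,
) -> pd.DataFrame:
    """2^-ddCt relative quantities, one row per (sample, target assay).

    The calibrator is a *group* (e.g. the sham-treated controls), averaged
    within each (stage, assay), so the mean rq over calibrator samples of a
    stage equals 1 by construction. Replicate sds above
    ``sd_warn_threshold`` cycles raise the ``high_replicate_sd`` flag on the
    affected rows.
    """
    validate_ct_table(table)
    if reference_assay not in set(table["assay_id"]):
        raise ParameterError(f"reference assay {reference_assay!r} absent from table")
    if calibrator_group not in set(table["group"]):
        raise ParameterError(f"calibrator group {calibrator_group!r} absent from table")

    means = (
        table.groupby(["sample_id", "group", "stage", "assay_id", "assay_role"])["ct"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    means["std"] = means["std"].fillna(0.0)
    ref = means[means["assay_id"] == reference_assay].set_index("sample_id")
    targets = means[(means["assay_role"] == "target") & (means["assay_id"] != reference_assay)]

    rows = []
    for _, row in targets.iterrows():
        sid = row["sample_id"]
        if sid not in ref.index:
            raise MirlinkError(f"sample {sid!r} has no reference assay {reference_assay!r}")
        rrow = ref.loc[sid]
        rows.append(
            {
                "sample_id": sid,
                "group": row["group"],
                "stage": row["stage"],
                "assay_id": row["assay_id"],
                "delta_ct": row["mean"] - rrow["mean"],
                "high_replicate_sd": bool(
                    row["std"] > sd_warn_threshold or rrow["std"] > sd_warn_threshold
                ),
            }
        )
    out = pd.DataFrame(rows, columns=["sample_id", "group", "stage", "assay_id", "delta_ct",
                                      "high_replicate_sd"])
    if out.empty:
        raise MirlinkError("no target assays found in Ct table")

    cal = out[out["group"] == calibrator_group]
    cal_means = cal.groupby(["stage", "assay_id"])["delta_ct"].mean()
    missing = set(zip(out["stage"], out["assay_id"])) - set(cal_means.index)
    if missing:
        raise MirlinkError(f"calibrator group missing for (stage, assay): {sorted(missing)}")
    out["delta_delta_ct"] = out["delta_ct"] - out.apply(
        lambda r: cal_means.loc[(r["stage"], r["assay_id"])], axis=1
    )
    out["rq"] = np.power(2.0, -out["delta_delta_ct"])
    n_flagged = int(out["high_replicate_sd"].sum())
    if n_flagged:
        logger.warning("delta_delta_ct: %d rows with replicate sd > %.2f cycles",
                       n_flagged, sd_warn_threshold)
    return out[RQ_COLUMNS].sort_values(["assay_id", "stage", "sample_id"]).reset_index(drop=True)
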