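"""Core data containers and the plain-TSV dialect shared by all pipeline stages.

The pipeline's main carrier is :class:`ExpressionMatrix`: a (probes or
features) x samples matrix of intensities on a declared scale, with per-sample
metadata (group, post-irradiation stage, replicate) and, at probe level, an
optional per-spot quality-flag matrix (flag 0 = fine signal) and a probe ->
(feature, type) map.

On disk everything is headed, uncompressed TSV:

* expression table: ``probe_id``, ``feature_id``, ``feature_type``
  (``mrna``/``mirna``), then one column of log2 intensity per sample;
* flag table: same shape, integer spot flags;
* sample sheet: ``sample_id``, ``group`` (``control``/``irradiated``),
  ``stage``, ``replicate``.

Feature-level matrices drop the probe columns (``feature_id``,
``feature_type``, then samples) and never carry flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

logger = logging.getLogger("mirlink")

GROUPS = ("control", "irradiated")

#: fixed float format for every TSV the pipeline writes; guarantees that
#: repeated runs produce byte-identical artifacts.
FLOAT_FORMAT = "%.6f"


class MirlinkError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(MirlinkError):
    """Invalid parameter or configuration value."""


class ConsistencyError(MirlinkError):
    """Inputs that are individually valid but mutually inconsistent."""


@dataclass
class ExpressionMatrix:
    """Probe- or feature-level expression with sample metadata.

    Parameters
    ----------
    values
        Rows are probes (``level='probe'``) or features (``level='feature'``);
        columns are sample ids. Missing cells are NaN.
    sample_meta
        Indexed by sample id with columns ``group``, ``stage``, ``replicate``;
        must cover every column of ``values``.
    level
        ``'probe'`` or ``'feature'``.
    scale
        ``'log2'`` or ``'linear'``; guards the log transform against double
        application.
    flags
        Optional integer spot-flag matrix aligned with ``values`` (probe level
        only). Flag 0 is a fine signal.
    feature_map
        Probe level only: DataFrame indexed by probe id with columns
        ``feature_id`` and ``feature_type``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    level: str = "probe"
    scale: str = "log2"
    flags: pd.DataFrame | None = None
    feature_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.level not in ("probe", "feature"):
            raise ParameterError(f"unknown matrix level {self.level!r}")
        if self.scale not in ("log2", "linear"):
            raise ParameterError(f"unknown intensity scale {self.scale!r}")
        missing = [c for c in self.values.columns if c not in self.sample_meta.index]
        if missing:
            raise ConsistencyError(f"samples without metadata: {missing}")
        for col in ("group", "stage", "replicate"):
            if col not in self.sample_meta.columns:
                raise ConsistencyError(f"sample sheet lacks column {col!r}")
        bad_groups = set(self.sample_meta["group"]) - set(GROUPS)
        if bad_groups:
            raise ConsistencyError(f"unknown group labels: {sorted(bad_groups)}")
        if self.values.index.duplicated().any():
            if self.level == "feature":
                dups = self.values.index[self.values.index.duplicated()].unique()
                raise ConsistencyError(
                    f"feature-level matrix with duplicated row ids: {list(dups[:5])}"
                )
        if self.level == "feature" and self.flags is not None:
            raise ConsistencyError("feature-level matrices carry no flags")
        if self.flags is not None:
            if not self.flags.index.equals(self.values.index) or not self.flags.columns.equals(
                self.values.columns
            ):
                raise ConsistencyError("flag matrix not aligned with values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def stages(self) -> list[str]:
        seen: list[str] = []
        for s in self.sample_meta.loc[self.samples, "stage"]:
            if s not in seen:
                seen.append(s)
        return seen

    def samples_for(self, stage: str, group: str) -> list[str]:
        meta = self.sample_meta.loc[self.samples]
        mask = (meta["stage"] == stage) & (meta["group"] == group)
        return list(meta.index[mask])

    def copy_with(self, **kwargs) -> "ExpressionMatrix":
        return replace(self, **kwargs)


@dataclass
class ProbeMap:
    """Probe -> (feature, type) mapping used to collapse replicate spots."""

    table: pd.DataFrame  # index probe_id; columns feature_id, feature_type

    def __post_init__(self) -> None:
        for col in ("feature_id", "feature_type"):
            if col not in self.table.columns:
                raise ConsistencyError(f"probe map lacks column {col!r}")
        if self.table.index.duplicated().any():
            raise ConsistencyError("probe map with duplicated probe ids")

    @classmethod
    def from_matrix(cls, m: ExpressionMatrix) -> "ProbeMap":
        if m.feature_map is None:
            raise ConsistencyError("matrix has no embedded probe map")
        return cls(m.feature_map.copy())

    def feature_of(self, probe_id: str) -> str:
        return self.table.at[probe_id, "feature_id"]


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "group", "stage", "replicate"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ConsistencyError(f"sample sheet {path} lacks columns {missing}")
    return sheet.set_index("sample_id")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep="\t", index=False
    )


def read_expression(
    path: str | Path,
    sample_meta: pd.DataFrame,
    flags_path: str | Path | None = None,
    scale: str = "log2",
) -> ExpressionMatrix:
    """Read a probe- or feature-level expression TSV.

    The level is inferred from the leading columns: ``probe_id`` present means
    probe level, otherwise ``feature_id`` alone means feature level.
    """
    df = pd.read_csv(path, sep="\t")
    if "probe_id" in df.columns:
        level = "probe"
        fmap = df[["probe_id", "feature_id", "feature_type"]].set_index("probe_id")
        values = df.drop(columns=["feature_id", "feature_type"]).set_index("probe_id")
    elif "feature_id" in df.columns:
        level = "feature"
        drop = [c for c in ("feature_type",) if c in df.columns]
        values = df.drop(columns=drop).set_index("feature_id")
        fmap = None
    else:
        raise ConsistencyError(f"{path}: neither probe_id nor feature_id column found")
    values = values.astype(float)
    flags = None
    if flags_path is not None:
        fdf = pd.read_csv(flags_path, sep="\t")
        drop = [c for c in ("feature_id", "feature_type") if c in fdf.columns]
        flags = fdf.drop(columns=drop).set_index(values.index.name)
        flags = flags.astype(int).reindex(index=values.index, columns=values.columns)
    return ExpressionMatrix(
        values=values,
        sample_meta=sample_meta,
        level=level,
        scale=scale,
        flags=flags,
        feature_map=fmap,
    )


def write_expression(m: ExpressionMatrix, path: str | Path, flags_path: str | Path | None = None) -> None:
    if m.level == "probe":
        if m.feature_map is None:
            raise ConsistencyError("probe-level matrix needs a probe map to be written")
        out = m.feature_map.join(m.values)
        out.index.name = "probe_id"
    else:
        out = m.values.copy()
        out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    if flags_path is not None:
        if m.flags is None:
            raise ConsistencyError("no flag matrix to write")
        f = m.flags.copy()
        f.index.name = "probe_id"
        f.to_csv(flags_path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table deterministically (fixed float format, no index)."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
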