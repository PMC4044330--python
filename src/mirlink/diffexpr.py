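"""Stage-wise differential expression between irradiated and control groups.

For each feature at each stage the irradiated and control replicate values
are compared with a Welch (unequal-variance) t-test; the effect size is the
log2 fold change mean(irradiated) - mean(control). Benjamini-Hochberg FDR is
computed within each (platform, stage) family over the features actually
tested. A feature is called ``up`` when log2FC >= fc_threshold and the
significance rule holds (raw p by default, matching a 2-fold / P < 0.05
calling convention; switchable to FDR), ``down`` symmetrically, ``ns``
otherwise.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConsistencyError, ExpressionMatrix, ParameterError

logger = logging.getLogger("mirlink")

__all__ = ["Thresholds", "welch_t", "bh_adjust", "run_de", "stage_overlap"]

DE_COLUMNS = ["feature_id", "stage", "log2_fc", "t_stat", "df", "p_value", "fdr", "call"]


@dataclass(frozen=True)
class Thresholds:
    """Calling rule: fold-change gate (log2 units) + significance gate."""

    fc_threshold: float = 1.0
    alpha: float = 0.05
    significance_on: str = "p"  # or "fdr"

    def __post_init__(self) -> None:
        if self.fc_threshold < 0:
            raise ParameterError("fc_threshold must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.significance_on not in ("p", "fdr"):
            raise ParameterError("significance_on must be 'p' or 'fdr'")


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t: statistic, Satterthwaite df, two-sided p.

    t = (mean x - mean y) / sqrt(sx^2/nx + sy^2/ny). Degenerate inputs
    follow a fixed contract: both groups constant with equal means gives
    (0, pooled df, 1); both constant with unequal means gives p = 0 with a
    warning; fewer than two finite values per group is an error (callers
    skip such features).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise ParameterError("welch_t needs at least 2 finite values per group")
    t, df, p = _welch_arrays(x[None, :], y[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def _welch_arrays(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t over rows, NaN-aware, with degenerate handling."""
    nx = np.sum(~np.isnan(X), axis=1)
    ny = np.sum(~np.isnan(Y), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mx = np.nanmean(X, axis=1)
        my = np.nanmean(Y, axis=1)
        vx = np.nanvar(X, axis=1, ddof=1)
        vy = np.nanvar(Y, axis=1, ddof=1)
        se2 = vx / nx + vy / ny
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    degenerate = se2 == 0
    if degenerate.any():
        df = np.where(degenerate, nx + ny - 2.0, df)
        equal = degenerate & (mx == my)
        unequal = degenerate & (mx != my)
        with np.errstate(invalid="ignore"):
            t = np.where(equal, 0.0, t)
            t = np.where(unequal, np.sign(mx - my) * np.inf, t)
        if unequal.any():
            logger.warning(
                "welch_t: %d features with zero variance in both groups and "
                "unequal means; p set to 0", int(unequal.sum())
            )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((t == 0) & (df > 0), 1.0, np.minimum(p, 1.0))
    return t, df, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(
    m: ExpressionMatrix, stage: str, thresholds: Thresholds | None = None
) -> pd.DataFrame:
    """Differential calls for one stage; one row per tested feature.

    Columns: feature_id, stage, log2_fc, t_stat, df, p_value, fdr, call.
    Features with fewer than two finite values in either group are skipped
    (and logged); the BH family is the tested features only.
    """
    thresholds = thresholds or Thresholds()
    if m.level != "feature":
        raise ConsistencyError("run_de expects a feature-level matrix")
    irr = m.samples_for(stage, "irradiated")
    ctl = m.samples_for(stage, "control")
    if not irr or not ctl:
        raise ConsistencyError(f"stage {stage!r} lacks a group (design error)")
    X = m.values[irr].to_numpy(dtype=float)
    Y = m.values[ctl].to_numpy(dtype=float)
    testable = (np.sum(~np.isnan(X), axis=1) >= 2) & (np.sum(~np.isnan(Y), axis=1) >= 2)
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.info("run_de[%s]: skipped %d features with <2 values per group",
                    stage, n_skipped)
    X, Y = X[testable], Y[testable]
    ids = m.values.index[testable]
    t, df, p = _welch_arrays(X, Y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fc = np.nanmean(X, axis=1) - np.nanmean(Y, axis=1)
    fdr = bh_adjust(p)
    sig = (p if thresholds.significance_on == "p" else fdr) < thresholds.alpha
    call = np.where(
        sig & (fc >= thresholds.fc_threshold),
        "up",
        np.where(sig & (fc <= -thresholds.fc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "feature_id": ids,
            "stage": stage,
            "log2_fc": fc,
            "t_stat": t,
            "df": df,
            "p_value": p,
            "fdr": fdr,
            "call": call,
        }
    ).reset_index(drop=True)


def run_de_all_stages(
    m: ExpressionMatrix, thresholds: Thresholds | None = None
) -> dict[str, pd.DataFrame]:
    """Convenience wrapper: one DE table per stage present in the metadata."""
    return {st: run_de(m, st, thresholds) for st in m.stages}


def stage_overlap(results: dict[str, pd.DataFrame], direction: str) -> dict[frozenset, int]:
    """Venn cell counts of features called ``direction`` across stages.

    Returns a map from each nonempty stage subset to the number of features
    called in exactly those stages; cells are mutually exclusive and sum to
    the size of the union.
    """
    if direction not in ("up", "down"):
        raise ParameterError(f"unknown direction {direction!r}")
    if len(results) < 2:
        raise ParameterError("stage_overlap needs at least 2 stages")
    sets = {
        st: set(df.loc[df["call"] == direction, "feature_id"]) for st, df in results.items()
    }
    stages = sorted(sets)
    cells: dict[frozenset, int] = {}
    for r in range(1, len(stages) + 1):
        for subset in itertools.combinations(stages, r):
            inside = set.intersection(*(sets[s] for s in subset))
            outside = set.union(*(sets[s] for s in stages if s not in subset), set())
            cells[frozenset(subset)] = len(inside - outside)
    return cells


def overlap_frame(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Venn summary for both directions as a tidy frame (for TSV export)."""
    rows = []
    for direction in ("up", "down"):
        for subset, n in sorted(
            stage_overlap(results, direction).items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        ):
            rows.append(
                {"direction": direction, "stages": "+".join(sorted(subset)), "n_features": n}
            )
    return pd.DataFrame(rows, columns=["direction", "stages", "n_features"])
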