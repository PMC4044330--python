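"""End-to-end orchestration: config, run-all, truth-based evaluation.

``run_all`` executes preprocess -> stage-wise DE (both platforms) ->
per-miRNA Fisher screens -> reciprocal pairs -> optional enrichment ->
network export -> summary, writing every intermediate as headed TSV plus a
manifest of SHA-256 file hashes and the resolved config. With identical
inputs and seed, two runs produce byte-identical manifests. When the inputs
are a synthetic fixture, ``evaluate`` scores the calls against the planted
truth (per-stage DE sensitivity and false-discovery proportion, pair-level
precision/recall, and the screen's ability to rank truly regulating miRNAs
first).
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ConsistencyError,
    MirlinkError,
    ParameterError,
    read_expression,
    read_sample_sheet,
    write_expression,
    write_table,
)
from .diffexpr import Thresholds, overlap_frame, run_de
from .enrichment import hypergeom_enrich, load_gmt
from .integration import TargetMap, load_target_map, pair_summary, reciprocal_pairs, screen_mirnas
from .network import build_network, export
from .preprocess import preprocess_pipeline

logger = logging.getLogger("mirlink")

__all__ = ["PipelineConfig", "run_all", "evaluate", "precision_recall"]


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; round-trips through YAML identically."""

    mrna_expression: str = ""
    mrna_flags: str | None = None
    mirna_expression: str = ""
    mirna_flags: str | None = None
    sample_sheet: str = ""
    target_map: str = ""
    gmt: str | None = None
    truth_de_labels: str | None = None
    truth_reciprocal_pairs: str | None = None
    out_dir: str = "mirlink_out"
    fc_threshold: float = 1.0
    alpha: float = 0.05
    significance_on: str = "p"
    min_fine_fraction: float = 0.5
    collapse_method: str = "median"
    quantile_normalize: bool = True
    screen_alpha: float = 0.05
    bh_across_screens: bool = False
    seed: int = 0
    mode: str = "default"  # or "paper-faithful"

    def thresholds(self) -> Thresholds:
        return Thresholds(self.fc_threshold, self.alpha, self.significance_on)

    def validate_inputs(self) -> None:
        for name in ("mrna_expression", "mirna_expression", "sample_sheet", "target_map"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise ParameterError(f"config input {name!r} missing or nonexistent: {p!r}")
        for name in ("mrna_flags", "mirna_flags", "gmt", "truth_de_labels",
                     "truth_reciprocal_pairs"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ParameterError(f"config input {name!r} does not exist: {p!r}")
        if self.mode not in ("default", "paper-faithful"):
            raise ParameterError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> Path:
    """Run every stage and write the artifact directory; returns its path."""
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out / name
        write_table(df, path)
        written.append(path)

    def stage_step(name: str):
        logger.info("stage %s: starting", name)
        return time.monotonic()

    try:
        t0 = stage_step("load")
        sheet = read_sample_sheet(config.sample_sheet)
        matrices = {
            "mrna": read_expression(config.mrna_expression, sheet, config.mrna_flags),
            "mirna": read_expression(config.mirna_expression, sheet, config.mirna_flags),
        }
        tmap = load_target_map(config.target_map)
        logger.info("stage load: done in %.2fs", time.monotonic() - t0)
    except MirlinkError as exc:
        raise MirlinkError(f"stage load failed: {exc}") from exc

    # --- preprocess -------------------------------------------------------
    features = {}
    for platform, m in matrices.items():
        t0 = stage_step(f"preprocess/{platform}")
        try:
            feat, report = preprocess_pipeline(
                m, config.min_fine_fraction, config.collapse_method,
                quantile=config.quantile_normalize,
            )
        except MirlinkError as exc:
            raise MirlinkError(f"stage preprocess/{platform} failed: {exc}") from exc
        features[platform] = feat
        emit(report.to_frame(), f"preprocess_report_{platform}.tsv")
        path = out / f"features_{platform}.tsv"
        write_expression(feat, path)
        written.append(path)
        logger.info("stage preprocess/%s: done in %.2fs", platform, time.monotonic() - t0)

    # --- differential expression -----------------------------------------
    thresholds = config.thresholds()
    de: dict[str, dict[str, pd.DataFrame]] = {}
    for platform, feat in features.items():
        de[platform] = {}
        for stage in feat.stages:
            t0 = stage_step(f"de/{platform}/{stage}")
            try:
                de[platform][stage] = run_de(feat, stage, thresholds)
            except MirlinkError as exc:
                raise MirlinkError(f"stage de/{platform}/{stage} failed: {exc}") from exc
            emit(de[platform][stage], f"de_{platform}_{stage}.tsv")
        if len(de[platform]) >= 2:
            emit(overlap_frame(de[platform]), f"venn_{platform}.tsv")

    # --- integration ------------------------------------------------------
    screens_all, pairs_all = [], []
    for stage in features["mrna"].stages:
        t0 = stage_step(f"integrate/{stage}")
        try:
            screens_all.append(
                screen_mirnas(
                    de["mirna"][stage], de["mrna"][stage], tmap, stage,
                    alpha=config.screen_alpha, bh_across_screens=config.bh_across_screens,
                )
            )
            pairs_all.append(reciprocal_pairs(de["mirna"][stage], de["mrna"][stage], tmap, stage))
        except MirlinkError as exc:
            raise MirlinkError(f"stage integrate/{stage} failed: {exc}") from exc
        logger.info("stage integrate/%s: done in %.2fs", stage, time.monotonic() - t0)
    screens = pd.concat(screens_all, ignore_index=True) if screens_all else pd.DataFrame()
    pairs = pd.concat(pairs_all, ignore_index=True) if pairs_all else pd.DataFrame()
    emit(screens, "fisher_results.tsv")
    emit(pairs, "pairs.tsv")
    emit(pair_summary(pairs), "pair_summary.tsv")

    # --- enrichment (optional) -------------------------------------------
    if config.gmt:
        t0 = stage_step("enrich")
        collection = load_gmt(config.gmt)
        universe = set(features["mrna"].values.index)
        for stage in features["mrna"].stages:
            dtab = de["mrna"][stage]
            query = set(dtab.loc[dtab["call"] != "ns", "feature_id"])
            emit(
                hypergeom_enrich(query, collection, universe, alpha=config.alpha),
                f"enrichment_{stage}.tsv",
            )
        logger.info("stage enrich: done in %.2fs", time.monotonic() - t0)

    # --- network ----------------------------------------------------------
    t0 = stage_step("network")
    net = build_network(pairs, screens)
    for fmt, name in (("sif", "network.sif"), ("graphml", "network.graphml"),
                      ("edge-tsv", "network_edges.tsv")):
        written.append(export(net, out / name, fmt))
    logger.info("stage network: done in %.2fs", time.monotonic() - t0)

    # --- evaluation against planted truth (optional) ----------------------
    if config.truth_de_labels and config.truth_reciprocal_pairs:
        truth_labels = pd.read_csv(config.truth_de_labels, sep="\t")
        truth_pairs = pd.read_csv(config.truth_reciprocal_pairs, sep="\t")
        report = evaluate(de, pairs, truth_labels, truth_pairs, screens=screens)
        emit(report, "recovery_report.tsv")

    # --- manifest ---------------------------------------------------------
    config.to_yaml(out / "resolved_config.yaml")
    written.append(out / "resolved_config.yaml")
    manifest = pd.DataFrame(
        [{"file": p.name, "sha256": _sha256(p)} for p in sorted(set(written))]
    ).sort_values("file").reset_index(drop=True)
    write_table(manifest, out / "manifest.tsv")
    return out


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """Precision and recall from confusion counts; empty denominators give 0."""
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def _screen_auc(screens: pd.DataFrame, true_mirnas: set[str], stage: str) -> float:
    """Rank-based AUC: do truly regulating miRNAs screen with smaller p?"""
    sub = screens[screens["stage"] == stage]
    if not len(sub):
        return float("nan")
    best = sub.groupby("mirna_id")["p_two_tailed"].min()
    pos = best[best.index.isin(true_mirnas)]
    neg = best[~best.index.isin(true_mirnas)]
    if not len(pos) or not len(neg):
        return float("nan")
    wins = sum((pos_p < neg.to_numpy()).sum() + 0.5 * (pos_p == neg.to_numpy()).sum()
               for pos_p in pos)
    return float(wins / (len(pos) * len(neg)))


def evaluate(
    de: dict[str, dict[str, pd.DataFrame]],
    pairs: pd.DataFrame,
    truth_labels: pd.DataFrame,
    truth_pairs: pd.DataFrame,
    screens: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score pipeline calls against planted truth; one row per stage.

    DE sensitivity counts a truth feature as recovered when it is called in
    the planted direction at that stage; the observed false-discovery
    proportion is the fraction of called features whose planted label is
    null or opposite. Pair precision/recall compare the extracted reciprocal
    pairs with the true (functional-edge) pairs. ``screen_auc`` is the
    probability that a truly regulating miRNA screens with a smaller best p
    than a non-regulating one.
    """
    stages = sorted({st for platform in de.values() for st in platform})
    tested_by_stage = {
        st: {fid for platform in de.values() if st in platform
             for fid in platform[st]["feature_id"]}
        for st in stages
    }
    truth_known = {
        (r.feature_id, r.stage): r.label for r in truth_labels.itertuples()
    }
    bad = set(truth_labels["feature_id"]) - set.union(*tested_by_stage.values())
    if len(bad) == len(set(truth_labels["feature_id"])) and len(bad):
        raise ConsistencyError("no truth feature id matches any tested feature")

    rows = []
    for st in stages:
        calls: dict[str, str] = {}
        for platform in de.values():
            if st in platform:
                dtab = platform[st]
                for fid, call in zip(dtab["feature_id"], dtab["call"]):
                    if call != "ns":
                        calls[fid] = call
        truth_st = {
            fid: lab for (fid, stage), lab in truth_known.items()
            if stage == st and fid in tested_by_stage[st]
        }
        tp = sum(1 for fid, lab in truth_st.items() if calls.get(fid) == lab)
        fn = len(truth_st) - tp
        fp = sum(1 for fid, call in calls.items() if truth_st.get(fid) != call)
        sens = tp / (tp + fn) if truth_st else float("nan")
        fdp = fp / (tp + fp) if calls else 0.0

        called_pairs = {
            (r.mirna_id, r.gene_id)
            for r in pairs.itertuples()
            if r.stage == st
        } if len(pairs) else set()
        true_p = {
            (r.mirna_id, r.gene_id) for r in truth_pairs.itertuples() if r.stage == st
        }
        ptp = len(called_pairs & true_p)
        p_prec, p_rec = precision_recall(ptp, len(called_pairs) - ptp, len(true_p) - ptp)

        auc = float("nan")
        if screens is not None and len(screens):
            auc = _screen_auc(screens, {m for m, _ in true_p}, st)
        rows.append(
            {
                "stage": st,
                "de_sensitivity": sens,
                "de_fdp": fdp,
                "n_true_de": len(truth_st),
                "n_called_de": len(calls),
                "pair_precision": p_prec,
                "pair_recall": p_rec,
                "n_true_pairs": len(true_p),
                "n_called_pairs": len(called_pairs),
                "screen_auc": auc,
            }
        )
    return pd.DataFrame(rows)
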