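"""Synthetic probe-level time-course data with a planted miRNA->target network.

The generator emulates the shape of a pooled-design rat irradiation study:
three post-irradiation stages (3, 12 and 26 weeks), each with its own
sham-treated control condition, replicate hybridizations per condition,
every feature printed as replicate probes (triplicate by default), per-spot
quality flags, and log2-scale intensities.

The regulatory structure is planted as a bipartite prediction graph: every
miRNA receives a set of *predicted* target genes; each predicted edge is
*functional* (the miRNA really represses that gene) with probability
``repression_penetrance``. A differentially expressed (DE) miRNA pushes an
opposite-sign expression shift onto the genes it functionally represses, so
the data contain exactly the reciprocal (anti-correlated) miRNA->mRNA
signal the downstream screen is designed to recover. The full truth —
functional edges, signed per-stage DE labels, and the implied true
reciprocal pairs — is returned alongside the data, so every pipeline stage
can be scored against ground truth without any external download.

Determinism: every draw comes from a child generator derived from
``(seed, stable stage label)`` via :func:`stream`, so identical inputs give
byte-identical fixtures and adding a new draw site never reshuffles earlier
streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ConsistencyError,
    ExpressionMatrix,
    ParameterError,
    write_expression,
    write_sample_sheet,
    write_table,
)

__all__ = [
    "DesignSpec",
    "EffectModel",
    "SyntheticTruth",
    "stream",
    "generate_truth",
    "generate_expression",
    "generate_target_map_frame",
    "write_fixture",
]


def stream(seed: int, label: str) -> np.random.Generator:
    """Child RNG for a named draw site, stable under code growth."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class DesignSpec:
    """Shape of the study: stages, replication, probe layout, spot failures.

    The source design pooled RNA from eight animals per condition and
    hybridized each pool twice; a two-vs-two comparison is statistically
    fragile, so the default is four replicate hybridizations per condition
    with :meth:`paper_faithful` switching to two.
    """

    stages: tuple[str, ...] = ("3w", "12w", "26w")
    replicates_per_condition: int = 4
    n_genes: int = 1000
    n_mirnas: int = 100
    probes_per_feature: int = 3
    flag_fail_rate: float = 0.02
    seed: int = 0
    stage_matched_controls: bool = True

    def __post_init__(self) -> None:
        if self.replicates_per_condition < 2:
            raise ParameterError("replicates_per_condition must be >= 2 (Welch t undefined)")
        if self.probes_per_feature < 1:
            raise ParameterError("probes_per_feature must be >= 1")
        if not (0.0 <= self.flag_fail_rate < 0.5):
            raise ParameterError("flag_fail_rate must lie in [0, 0.5)")
        if self.n_genes < 1 or self.n_mirnas < 1:
            raise ParameterError("n_genes and n_mirnas must be positive")
        if len(self.stages) < 1 or len(set(self.stages)) != len(self.stages):
            raise ParameterError("stages must be non-empty and unique")

    def paper_faithful(self) -> "DesignSpec":
        """Two hybridizations per pooled condition, as in the source design."""
        from dataclasses import replace

        return replace(self, replicates_per_condition=2)

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"gene{str(i + 1).zfill(width)}" for i in range(self.n_genes)]

    @property
    def mirna_ids(self) -> list[str]:
        width = len(str(self.n_mirnas))
        return [f"mir{str(i + 1).zfill(width)}" for i in range(self.n_mirnas)]

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for stage in self.stages:
            for group in ("control", "irradiated"):
                for r in range(1, self.replicates_per_condition + 1):
                    rows.append(
                        {
                            "sample_id": f"{stage}_{group}_r{r}",
                            "group": group,
                            "stage": stage,
                            "replicate": str(r),
                        }
                    )
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass(frozen=True)
class EffectModel:
    """Sizes and rates of the planted effects, all on the log2 scale.

    ``mirna_effect_log2`` draws |effect| from a normal clipped below at
    ``min_effect_log2`` (1 log2 unit by default), so planted truth is
    detectable under the 2-fold calling rule. ``repression_penetrance`` is
    the probability that a *predicted* edge is functional. Stage activity of
    a DE feature follows a Gaussian copula with pairwise correlation
    ``stage_correlation`` (large cross-stage overlaps at 0.5 by default).

    The default rates mirror a bulk irradiation time course: roughly 6% of
    miRNAs responding (cf. 23 of 387 assayed) and, through their targets
    plus a 5% miRNA-independent background, on the order of 10-20% of genes
    DE per stage (cf. ~5100 of >41000 transcripts). Keeping the DE fraction
    at realistic levels also keeps quantile normalization honest: rank
    normalization assumes most features are unchanged, and a generator that
    planted effects into most of the transcriptome would violate that
    assumption by construction.
    """

    frac_de_mirnas: float = 0.06
    mirna_effect_log2: tuple[float, float] = (2.0, 0.25)  # (mean, sd) of |effect|
    repression_penetrance: float = 0.8
    independent_de_frac: float = 0.05
    noise_sd_log2: float = 0.25
    baseline_log2: tuple[float, float] = (8.0, 1.5)  # (mean, sd)
    stage_correlation: float = 0.5
    stage_activity: float = 0.8  # P(DE-capable feature active at a given stage)
    targets_per_mirna: int = 30
    min_effect_log2: float = 1.0
    probe_noise_sd_log2: float | None = None  # default: half of noise_sd_log2

    def __post_init__(self) -> None:
        for name in (
            "frac_de_mirnas",
            "repression_penetrance",
            "independent_de_frac",
            "stage_activity",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if not (-1.0 < self.stage_correlation < 1.0):
            raise ParameterError("stage_correlation must lie in (-1, 1)")
        if self.mirna_effect_log2[1] <= 0 or self.baseline_log2[1] <= 0:
            raise ParameterError("effect and baseline sds must be > 0")
        if self.noise_sd_log2 < 0:
            raise ParameterError("noise_sd_log2 must be >= 0")
        if self.targets_per_mirna < 0:
            raise ParameterError("targets_per_mirna must be >= 0")

    @property
    def probe_sd(self) -> float:
        if self.probe_noise_sd_log2 is not None:
            return self.probe_noise_sd_log2
        return 0.5 * self.noise_sd_log2


@dataclass
class SyntheticTruth:
    """The planted ground truth against which recovery is scored.

    ``predicted_edges`` is the full prediction map handed to the screen;
    ``regulation_edges`` is its functional subset (edges that actually push
    expression). ``de_labels`` maps (feature_id, stage) to a signed log2
    effect (absent key = null). ``reciprocal_pairs_true`` contains every
    (miRNA, gene, stage) with a functional edge and opposite-sign labels.
    """

    predicted_edges: set[tuple[str, str]]
    regulation_edges: set[tuple[str, str]]
    de_labels: dict[tuple[str, str], float]  # (feature_id, stage) -> signed effect
    reciprocal_pairs_true: set[tuple[str, str, str]]
    design: DesignSpec = field(repr=False, default=None)  # type: ignore[assignment]
    effects: EffectModel = field(repr=False, default=None)  # type: ignore[assignment]

    def label(self, feature_id: str, stage: str) -> str:
        eff = self.de_labels.get((feature_id, stage), 0.0)
        if eff > 0:
            return "up"
        if eff < 0:
            return "down"
        return "null"

    def de_features(self, stage: str, feature_ids: list[str] | None = None) -> dict[str, str]:
        out = {}
        for (fid, st), eff in self.de_labels.items():
            if st == stage and eff != 0.0:
                if feature_ids is None or fid in feature_ids:
                    out[fid] = "up" if eff > 0 else "down"
        return out


def _stage_active(
    rng: np.random.Generator, n: int, stages: tuple[str, ...], rho: float, marginal: float
) -> np.ndarray:
    """Correlated per-stage activity indicators via a one-factor Gaussian copula."""
    n_stages = len(stages)
    z_common = rng.standard_normal((n, 1))
    z = np.sqrt(abs(rho)) * np.sign(rho) * z_common + np.sqrt(1 - abs(rho)) * rng.standard_normal(
        (n, n_stages)
    )
    return z < stats.norm.ppf(marginal)


def generate_truth(design: DesignSpec, effects: EffectModel) -> SyntheticTruth:
    """Draw the planted regulatory structure and per-stage DE labels.

    Deterministic in ``design.seed``. The number of DE miRNAs is a single
    binomial draw at rate ``frac_de_mirnas``; each DE miRNA gets a fixed
    direction and per-stage activity; functional targets receive the
    opposite-sign effect at every stage their miRNA is active. A gene
    regulated by several conflicting miRNAs takes the sign of its
    largest-magnitude active regulator (deterministic tie-break by miRNA id).
    """
    rng = stream(design.seed, "truth")
    genes = design.gene_ids
    mirnas = design.mirna_ids

    # --- prediction graph -------------------------------------------------
    predicted: set[tuple[str, str]] = set()
    k = min(effects.targets_per_mirna, design.n_genes)
    for m in mirnas:
        targets = rng.choice(design.n_genes, size=k, replace=False)
        predicted.update((m, genes[t]) for t in targets)
    # iterate in sorted order: pairing RNG draws with set-iteration order
    # would silently break cross-process determinism
    functional = {e for e in sorted(predicted) if rng.random() < effects.repression_penetrance}

    # --- miRNA DE status --------------------------------------------------
    de_capable = rng.random(design.n_mirnas) < effects.frac_de_mirnas
    directions = np.where(rng.random(design.n_mirnas) < 0.5, 1.0, -1.0)
    active = _stage_active(
        rng, design.n_mirnas, design.stages, effects.stage_correlation, effects.stage_activity
    )
    mean_eff, sd_eff = effects.mirna_effect_log2
    de_labels: dict[tuple[str, str], float] = {}
    mirna_effect: dict[tuple[str, str], float] = {}
    for i, m in enumerate(mirnas):
        if not de_capable[i]:
            continue
        for j, st in enumerate(design.stages):
            if not active[i, j]:
                continue
            mag = max(effects.min_effect_log2, rng.normal(mean_eff, sd_eff))
            eff = directions[i] * mag
            de_labels[(m, st)] = eff
            mirna_effect[(m, st)] = eff

    # --- gene effects from functional repression --------------------------
    regulators: dict[str, list[str]] = {}
    for m, g in functional:
        regulators.setdefault(g, []).append(m)
    regulated_genes = set(regulators)
    for g in sorted(regulated_genes):
        for st in design.stages:
            best = None
            for m in sorted(regulators[g]):
                eff = mirna_effect.get((m, st))
                if eff is not None and (best is None or abs(eff) > abs(best)):
                    best = eff
            if best is not None:
                mag = max(effects.min_effect_log2, rng.normal(mean_eff, sd_eff))
                de_labels[(g, st)] = -np.sign(best) * mag

    # --- independent (miRNA-free) gene DE ---------------------------------
    free = [g for g in genes if g not in regulated_genes]
    cap = rng.random(len(free)) < effects.independent_de_frac
    dirs = np.where(rng.random(len(free)) < 0.5, 1.0, -1.0)
    act = _stage_active(
        rng, len(free), design.stages, effects.stage_correlation, effects.stage_activity
    )
    for i, g in enumerate(free):
        if not cap[i]:
            continue
        for j, st in enumerate(design.stages):
            if act[i, j]:
                mag = max(effects.min_effect_log2, rng.normal(mean_eff, sd_eff))
                de_labels[(g, st)] = dirs[i] * mag

    # --- true reciprocal pairs, derived from labels + functional edges ----
    pairs: set[tuple[str, str, str]] = set()
    for m, g in functional:
        for st in design.stages:
            em = de_labels.get((m, st), 0.0)
            eg = de_labels.get((g, st), 0.0)
            if em != 0.0 and eg != 0.0 and np.sign(em) != np.sign(eg):
                pairs.add((m, g, st))

    return SyntheticTruth(
        predicted_edges=predicted,
        regulation_edges=functional,
        de_labels=de_labels,
        reciprocal_pairs_true=pairs,
        design=design,
        effects=effects,
    )


def _expression_for(
    feature_ids: list[str],
    feature_type: str,
    truth: SyntheticTruth,
    design: DesignSpec,
    effects: EffectModel,
    rng: np.random.Generator,
) -> ExpressionMatrix:
    sheet = design.sample_sheet()
    samples = list(sheet.index)
    n_feat = len(feature_ids)
    n_probe = design.probes_per_feature
    baseline = rng.normal(effects.baseline_log2[0], effects.baseline_log2[1], size=n_feat)

    # condition means: baseline + planted effect for irradiated samples
    mean = np.tile(baseline[:, None], (1, len(samples)))
    for j, s in enumerate(samples):
        if sheet.at[s, "group"] != "irradiated":
            continue
        st = sheet.at[s, "stage"]
        for i, fid in enumerate(feature_ids):
            eff = truth.de_labels.get((fid, st))
            if eff:
                mean[i, j] += eff

    feat_noise = effects.noise_sd_log2 * rng.standard_normal((n_feat, len(samples)))
    per_sample = mean + feat_noise

    probe_rows = np.repeat(per_sample, n_probe, axis=0)
    probe_noise = effects.probe_sd * rng.standard_normal(probe_rows.shape)
    values = probe_rows + probe_noise

    probe_ids = [f"{fid}_p{p + 1}" for fid in feature_ids for p in range(n_probe)]
    fmap = pd.DataFrame(
        {
            "feature_id": np.repeat(feature_ids, n_probe),
            "feature_type": feature_type,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    flags = (rng.random(values.shape) < design.flag_fail_rate).astype(int)
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=samples),
        sample_meta=sheet,
        level="probe",
        scale="log2",
        flags=pd.DataFrame(flags, index=pd.Index(probe_ids, name="probe_id"), columns=samples),
        feature_map=fmap,
    )


def generate_expression(
    truth: SyntheticTruth, design: DesignSpec, effects: EffectModel
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Materialize probe-level mRNA and miRNA matrices from planted truth.

    Probe intensity = baseline + condition effect + per-sample feature noise
    + per-spot probe noise, all on the log2 scale. In the zero-noise limit
    the irradiated-minus-control group mean equals the planted effect
    exactly.
    """
    if truth.design is not None and truth.design != design:
        raise ConsistencyError("truth was generated from a different design")
    mrna = _expression_for(
        design.gene_ids, "mrna", truth, design, effects, stream(design.seed, "expr/mrna")
    )
    mirna = _expression_for(
        design.mirna_ids, "mirna", truth, design, effects, stream(design.seed, "expr/mirna")
    )
    return mrna, mirna


def generate_target_map_frame(truth: SyntheticTruth) -> pd.DataFrame:
    """Predicted miRNA->gene edges as a two-column frame, sorted for determinism."""
    edges = sorted(truth.predicted_edges)
    return pd.DataFrame(edges, columns=["mirna_id", "gene_id"])


def write_fixture(
    dir_path: str | Path,
    design: DesignSpec | None = None,
    effects: EffectModel | None = None,
) -> dict[str, Path]:
    """Generate and write a complete fixture directory; returns the file map.

    Emits the expression/flag TSVs for both platforms, the shared sample
    sheet, the predicted target map, and three truth tables
    (``truth_de_labels.tsv``, ``truth_regulation_edges.tsv``,
    ``truth_reciprocal_pairs.tsv``). Everything round-trips through the
    readers in :mod:`mirlink.containers`.
    """
    design = design or DesignSpec()
    effects = effects or EffectModel()
    out = Path(dir_path)
    out.mkdir(parents=True, exist_ok=True)

    truth = generate_truth(design, effects)
    mrna, mirna = generate_expression(truth, design, effects)

    paths = {
        "mrna_expression": out / "mrna_expression.tsv",
        "mrna_flags": out / "mrna_flags.tsv",
        "mirna_expression": out / "mirna_expression.tsv",
        "mirna_flags": out / "mirna_flags.tsv",
        "sample_sheet": out / "samples.tsv",
        "target_map": out / "target_map.tsv",
        "truth_de_labels": out / "truth_de_labels.tsv",
        "truth_regulation_edges": out / "truth_regulation_edges.tsv",
        "truth_reciprocal_pairs": out / "truth_reciprocal_pairs.tsv",
    }
    write_expression(mrna, paths["mrna_expression"], paths["mrna_flags"])
    write_expression(mirna, paths["mirna_expression"], paths["mirna_flags"])
    write_sample_sheet(design.sample_sheet(), paths["sample_sheet"])
    write_table(generate_target_map_frame(truth), paths["target_map"])

    labels = pd.DataFrame(
        [
            {
                "feature_id": fid,
                "stage": st,
                "effect_log2": eff,
                "label": "up" if eff > 0 else "down",
            }
            for (fid, st), eff in sorted(truth.de_labels.items())
        ],
        columns=["feature_id", "stage", "effect_log2", "label"],
    )
    write_table(labels, paths["truth_de_labels"])
    write_table(
        pd.DataFrame(sorted(truth.regulation_edges), columns=["mirna_id", "gene_id"]),
        paths["truth_regulation_edges"],
    )
    write_table(
        pd.DataFrame(
            sorted(truth.reciprocal_pairs_true), columns=["mirna_id", "gene_id", "stage"]
        ),
        paths["truth_reciprocal_pairs"],
    )
    return paths
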