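"""miRNA-mRNA integration: per-miRNA Fisher-exact target-enrichment screens
and reciprocal (anti-correlated) pair extraction.

For every differentially expressed miRNA at a stage, a 2x2 contingency table
is built over the *universe* of mRNA features tested at that stage:

====================  ==============  ==================
\                      predicted target  not a target
DE (given direction)   a                 b
not DE                 c                 d
====================  ==============  ==================

and a two-tailed Fisher exact test asks whether predicted targets are over-
(or under-) represented among the directional DE list. Each miRNA is
screened twice, against the up- and the down-regulated mRNA lists. The
two-tailed p follows the minimum-likelihood convention: the sum of
hypergeometric probabilities of all tables with the same margins that are
at most as probable as the observed one.

A reciprocal pair is a predicted miRNA->gene edge whose endpoints are DE in
opposite directions at the same stage — the operational definition of a
candidate repressive interaction when samples are pooled and per-sample
correlation is unavailable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MirlinkError, ParameterError, write_table
from .diffexpr import bh_adjust

logger = logging.getLogger("mirlink")

__all__ = [
    "TargetMap",
    "ContingencyTable",
    "load_target_map",
    "fisher_two_tailed",
    "screen_mirnas",
    "reciprocal_pairs",
    "pair_summary",
]

FISHER_COLUMNS = [
    "mirna_id",
    "stage",
    "mirna_direction",
    "mrna_list_direction",
    "a",
    "b",
    "c",
    "d",
    "odds_ratio",
    "p_two_tailed",
    "fdr",
    "significant",
    "zero_targets",
]

PAIR_COLUMNS = ["mirna_id", "gene_id", "stage", "mirna_call", "gene_call"]


class TargetMap:
    """Deduplicated bipartite miRNA->gene prediction edges, indexed both ways."""

    def __init__(self, edges) -> None:
        self.edges: set[tuple[str, str]] = set(map(tuple, edges))
        self._targets: dict[str, set[str]] = {}
        self._mirnas: dict[str, set[str]] = {}
        for m, g in self.edges:
            self._targets.setdefault(m, set()).add(g)
            self._mirnas.setdefault(g, set()).add(m)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, edge: tuple[str, str]) -> bool:
        return tuple(edge) in self.edges

    def targets(self, mirna_id: str) -> set[str]:
        return self._targets.get(mirna_id, set())

    def mirnas(self, gene_id: str) -> set[str]:
        return self._mirnas.get(gene_id, set())

    @property
    def mirna_ids(self) -> set[str]:
        return set(self._targets)

    @property
    def gene_ids(self) -> set[str]:
        return set(self._mirnas)


def load_target_map(path: str | Path) -> TargetMap:
    """Read a TargetScan-style two-column (miRNA, gene) TSV; extra columns
    (e.g. a score) are ignored; duplicate lines collapse to one edge."""
    path = Path(path)
    edges = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() and "mirna" not in header.lower():
            # headerless file: first line is data
            fields = header.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise MirlinkError(f"{path}:1: malformed target-map line {header!r}")
            edges.append((fields[0], fields[1]))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise MirlinkError(f"{path}:{lineno}: malformed target-map line {line!r}")
            edges.append((fields[0], fields[1]))
    tmap = TargetMap(edges)
    if not tmap.edges:
        logger.warning("load_target_map: %s contains no edges", path)
    return tmap


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a = DE-and-target, b = DE-not-target, c = target-not-DE,
    d = neither; margins are the DE list and the target set within the
    universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ParameterError("contingency counts must be >= 0")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def fisher_two_tailed(table: ContingencyTable) -> tuple[float, float]:
    """(odds ratio, two-tailed p) for a 2x2 table.

    The odds ratio is the sample estimate a*d / (b*c), infinite when
    b*c = 0 with a*d > 0 and NaN (undefined) when a margin is zero; a zero
    margin also fixes p = 1 (only one table is possible given the margins).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        return float("nan"), 1.0
    if b * c == 0:
        odds = float("inf") if a * d > 0 else (0.0 if a * d == 0 and (b or c) else float("nan"))
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return odds, float(min(p, 1.0))


def screen_mirnas(
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    target_map: TargetMap,
    stage: str | None = None,
    alpha: float = 0.05,
    bh_across_screens: bool = False,
) -> pd.DataFrame:
    """Fisher-exact target-enrichment screen for every DE miRNA at a stage.

    The universe is the set of mRNA features in ``mrna_de`` (i.e. the
    features that survived preprocessing and were tested), so the DE family
    and the Fisher family coincide. Each DE miRNA contributes two rows, one
    against the up- and one against the down-regulated mRNA list, sorted by
    p. A miRNA with no targets inside the universe gets p = 1 and the
    ``zero_targets`` marker instead of an exception. No correction across
    screens is applied unless ``bh_across_screens`` is set (then an ``fdr``
    column drives nothing but is reported).
    """
    if stage is None:
        stages = set(mirna_de["stage"]) | set(mrna_de["stage"])
        if len(stages) != 1:
            raise ParameterError("ambiguous stage; pass it explicitly")
        stage = stages.pop()
    if not (set(mirna_de["stage"]) <= {stage} and set(mrna_de["stage"]) <= {stage}):
        raise ParameterError("DE tables mix stages; screen one stage at a time")

    universe = set(mrna_de["feature_id"])
    n_universe = len(universe)
    de_lists = {
        "up": set(mrna_de.loc[mrna_de["call"] == "up", "feature_id"]),
        "down": set(mrna_de.loc[mrna_de["call"] == "down", "feature_id"]),
    }
    rows = []
    de_mirnas = mirna_de[mirna_de["call"].isin(("up", "down"))]
    for _, mrow in de_mirnas.iterrows():
        targets = target_map.targets(mrow["feature_id"]) & universe
        for list_dir in ("down", "up"):
            de_list = de_lists[list_dir]
            a = len(de_list & targets)
            b = len(de_list) - a
            c = len(targets) - a
            d = n_universe - a - b - c
            table = ContingencyTable(a, b, c, d)
            odds, p = fisher_two_tailed(table)
            rows.append(
                {
                    "mirna_id": mrow["feature_id"],
                    "stage": stage,
                    "mirna_direction": mrow["call"],
                    "mrna_list_direction": list_dir,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds,
                    "p_two_tailed": p,
                    "significant": p < alpha,
                    "zero_targets": len(targets) == 0,
                }
            )
    out = pd.DataFrame(rows, columns=[c for c in FISHER_COLUMNS if c != "fdr"])
    if len(out):
        out["fdr"] = bh_adjust(out["p_two_tailed"].to_numpy())
        if bh_across_screens:
            out["significant"] = out["fdr"] < alpha
            logger.info("screen_mirnas[%s]: significance from BH across %d screens",
                        stage, len(out))
        out = out.sort_values(
            ["p_two_tailed", "mirna_id", "mrna_list_direction"], kind="stable"
        ).reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out[FISHER_COLUMNS]


def reciprocal_pairs(
    mirna_de: pd.DataFrame,
    mrna_de: pd.DataFrame,
    target_map: TargetMap,
    stage: str | None = None,
) -> pd.DataFrame:
    """All predicted edges whose miRNA and gene are DE in opposite directions."""
    if stage is None:
        stages = set(mirna_de["stage"]) | set(mrna_de["stage"])
        if len(stages) != 1:
            raise ParameterError("ambiguous stage; pass it explicitly")
        stage = stages.pop()
    gene_calls = dict(
        zip(mrna_de["feature_id"], mrna_de["call"])
    )
    rows = []
    de_mirnas = mirna_de[mirna_de["call"].isin(("up", "down"))]
    for _, mrow in de_mirnas.iterrows():
        opposite = "down" if mrow["call"] == "up" else "up"
        for gene in sorted(target_map.targets(mrow["feature_id"])):
            if gene_calls.get(gene) == opposite:
                rows.append(
                    {
                        "mirna_id": mrow["feature_id"],
                        "gene_id": gene,
                        "stage": stage,
                        "mirna_call": mrow["call"],
                        "gene_call": opposite,
                    }
                )
    return (
        pd.DataFrame(rows, columns=PAIR_COLUMNS)
        .drop_duplicates()
        .sort_values(["mirna_id", "gene_id"], kind="stable")
        .reset_index(drop=True)
    )


def pair_summary(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-stage counts of distinct miRNAs and genes in each direction class.

    Columns: stage, n_up_mirnas (up miRNAs with >=1 down target),
    n_down_target_genes, n_down_mirnas, n_up_target_genes — the shape of the
    "N up-regulated miRNAs had M down-regulated targets" summary.
    """
    rows = []
    stages = sorted(set(pairs["stage"])) if len(pairs) else []
    for st in stages:
        sub = pairs[pairs["stage"] == st]
        up = sub[sub["mirna_call"] == "up"]
        down = sub[sub["mirna_call"] == "down"]
        rows.append(
            {
                "stage": st,
                "n_up_mirnas": up["mirna_id"].nunique(),
                "n_down_target_genes": up["gene_id"].nunique(),
                "n_down_mirnas": down["mirna_id"].nunique(),
                "n_up_target_genes": down["gene_id"].nunique(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stage",
            "n_up_mirnas",
            "n_down_target_genes",
            "n_down_mirnas",
            "n_up_target_genes",
        ],
    )
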