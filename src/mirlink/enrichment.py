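"""Gene-set enrichment of DE gene lists via the exact hypergeometric test.

A transparent replacement for web-service functional annotation: the user
supplies GMT collections (GO-style molecular function / biological process /
cellular component, KEGG-style pathways, or anything else), and each set is
scored with the upper-tail hypergeometric probability of the observed
overlap given the universe, with Benjamini-Hochberg correction across the
sets of each category. The default statistic is the plain hypergeometric
tail P(X >= k); an EASE-style conservative variant (one overlap gene
discounted) is available as a switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .containers import MirlinkError, ParameterError
from .diffexpr import bh_adjust

logger = logging.getLogger("mirlink")

__all__ = ["GeneSetCollection", "load_gmt", "hypergeom_enrich"]

ENRICHMENT_COLUMNS = ["set_name", "category", "k", "K", "n", "N", "p_value", "fdr"]


@dataclass
class GeneSetCollection:
    """Named gene sets with a category label per set."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, genes, category: str = "default") -> None:
        genes = set(genes)
        if name in self.sets:
            raise MirlinkError(f"duplicate gene-set name {name!r}")
        if not genes:
            raise MirlinkError(f"gene set {name!r} is empty")
        self.sets[name] = genes
        self.categories[name] = category

    def __len__(self) -> int:
        return len(self.sets)


def load_gmt(path: str | Path, category: str | None = None) -> GeneSetCollection:
    """Parse a GMT file: ``set_name <TAB> description <TAB> gene ...``.

    Genes repeated within a set are counted once. The category defaults to
    the file stem so several GMT files can be merged without clashes.
    """
    path = Path(path)
    cat = category or path.stem
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise MirlinkError(
                    f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}"
                )
            name, _description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise MirlinkError(f"{path}:{lineno}: gene set {name!r} is empty")
            coll.add(name, genes, category=cat)
    if not len(coll):
        logger.warning("load_gmt: %s contains no gene sets", path)
    return coll


def hypergeom_enrich(
    query,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
    ease: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` against every set.

    Sets are intersected with the universe before testing; query genes
    outside the universe are dropped with a logged count. p = P(X >= k) for
    X ~ Hypergeom(N, K, n) with N the universe size, K the in-universe set
    size, n the query size and k the overlap (EASE mode tests P(X >= k-1)
    restricted to k >= 1). BH runs across sets within each category; output
    is sorted by (category, p, set_name).
    """
    universe = set(universe)
    if not universe:
        raise ParameterError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning("hypergeom_enrich: dropped %d query genes outside universe",
                       len(outside))
        query &= universe
    N = len(universe)
    n = len(query)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = genes & universe
        K = len(in_universe)
        k = len(in_universe & query)
        k_eff = max(k - 1, 0) if ease else k
        p = float(stats.hypergeom.sf(k_eff - 1, N, K, n)) if k_eff > 0 else 1.0
        rows.append(
            {
                "set_name": name,
                "category": collection.categories[name],
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "fdr"])
    if len(out):
        out["fdr"] = 1.0
        for cat, idx in out.groupby("category").groups.items():
            out.loc[idx, "fdr"] = bh_adjust(out.loc[idx, "p_value"].to_numpy())
        out = out.sort_values(["category", "p_value", "set_name"], kind="stable").reset_index(
            drop=True
        )
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out[ENRICHMENT_COLUMNS]
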