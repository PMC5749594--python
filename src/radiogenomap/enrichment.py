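"""Functional annotation of metagenes by hypergeometric overlap testing.

For each (metagene, gene set) pair, the upper-tail hypergeometric probability
asks whether the observed overlap is larger than expected by chance when
drawing the metagene's genes from the universe. P values are corrected by
Benjamini–Hochberg FDR jointly across all tested pairs; a pair is called
significant when P < .001 and Q < 0.05 (both thresholds configurable).

The universe is the set of analyzed genes (typically the expression matrix
after low-count filtering), not the database's gene union: the genes actually
tested define the sampling frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import read_gmt
from .metagenes import Metagene

__all__ = [
    "GeneSetDatabase",
    "hypergeom_upper_tail",
    "bh_fdr",
    "MetageneEnrichment",
    "EnrichmentResults",
]


@dataclass
class GeneSetDatabase:
    """Named gene-id collections from a functional-category database."""

    sets: dict[str, frozenset]
    source: str = ""

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    @classmethod
    def from_gmt(cls, path, source: str | None = None) -> "GeneSetDatabase":
        raw = read_gmt(path)
        names = [name for name, _, _ in raw]
        if len(set(names)) != len(names):
            raise ValueError(f"{path}: duplicate gene-set names")
        return cls(
            sets={name: frozenset(genes) for name, _, genes in raw},
            source=source or str(path),
        )


def hypergeom_upper_tail(k: int, K: int, M: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, M, K): the chance that drawing K
    genes (the metagene) from a universe of N containing M set members yields
    an overlap of at least k. Exact (scipy survival function), one-sided
    enrichment only."""
    if not (0 <= k <= min(K, M) and K <= N and M <= N):
        raise ValueError(f"inconsistent sizes: k={k}, K={K}, M={M}, N={N}")
    return float(hypergeom.sf(k - 1, N, M, K))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class MetageneEnrichment:
    """Hypergeometric enrichment of metagenes against a gene-set database.

    Parameters
    ----------
    metagenes : list of Metagene
    database : GeneSetDatabase
    universe : iterable of gene ids
        Sampling frame; metagene and set memberships are intersected with it
        before counting.
    """

    def __init__(self, metagenes: list[Metagene], database: GeneSetDatabase, universe):
        universe = frozenset(map(str, universe))
        if not universe:
            raise ValueError("universe is empty")
        self.metagenes = metagenes
        self.database = database
        self.universe = universe

    def fit(
        self,
        p_thresh: float = 0.001,
        q_thresh: float = 0.05,
        include_zero_overlap: bool = False,
    ) -> "EnrichmentResults":
        N = len(self.universe)
        rows = []
        for mg in self.metagenes:
            mg_genes = mg.member_set & self.universe
            if not mg_genes:
                continue
            for set_name, set_genes in self.database.sets.items():
                sg = set_genes & self.universe
                overlap = len(mg_genes & sg)
                if overlap == 0 and not include_zero_overlap:
                    continue
                if not sg:
                    continue
                rows.append(
                    {
                        "metagene_id": mg.id,
                        "set_name": set_name,
                        "overlap": overlap,
                        "metagene_size_in_universe": len(mg_genes),
                        "set_size_in_universe": len(sg),
                        "universe_size": N,
                        "p": hypergeom_upper_tail(overlap, len(mg_genes), len(sg), N),
                    }
                )
        table = pd.DataFrame(
            rows,
            columns=[
                "metagene_id",
                "set_name",
                "overlap",
                "metagene_size_in_universe",
                "set_size_in_universe",
                "universe_size",
                "p",
            ],
        )
        if len(table):
            table["q"] = bh_fdr(table["p"].to_numpy())
            table["significant"] = (table["p"] < p_thresh) & (table["q"] < q_thresh)
        else:
            table["q"] = pd.Series(dtype=float)
            table["significant"] = pd.Series(dtype=bool)
        return EnrichmentResults(table, p_thresh, q_thresh, include_zero_overlap)


class EnrichmentResults:
    """Enrichment table with the dual significance rule applied.

    Attributes
    ----------
    table : DataFrame
        One row per tested (metagene, set) pair; BH correction was applied
        jointly across all rows.
    """

    def __init__(self, table: pd.DataFrame, p_thresh, q_thresh, include_zero_overlap):
        self.table = table
        self.p_thresh = p_thresh
        self.q_thresh = q_thresh
        self.include_zero_overlap = include_zero_overlap

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]].reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Metagene functional enrichment (hypergeometric upper tail, BH FDR)",
            f"  pairs tested: {len(self.table)}   "
            f"significant (P<{self.p_thresh}, Q<{self.q_thresh}): {self.n_significant}",
        ]
        top = self.significant().sort_values("p").head(10)
        for _, r in top.iterrows():
            lines.append(
                f"  {r.metagene_id:>14s}  {r.set_name:<24s} overlap={r.overlap:<3d} "
                f"p={r.p:.3g} q={r.q:.3g}"
            )
        return "\n".join(lines)
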