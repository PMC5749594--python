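"""Metagenes: construction, loading, homogeneity scoring, selection, per-sample scores.

A metagene is a named cluster of coexpressed genes summarized into one
per-sample activity score (the mean of its standardized member genes). The
homogeneity score of a metagene within a cohort is the average of all pairwise
Pearson correlations between member-gene expression rows; metagenes are
validated by their average homogeneity across external cohorts and the top 10
with average >= 0.45 are carried forward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import read_gmt
from .preprocess import standardize_genes

__all__ = [
    "Metagene",
    "HomogeneityRecord",
    "cluster_metagenes",
    "load_metagenes",
    "homogeneity",
    "cross_cohort_homogeneity",
    "select_top_metagenes",
    "metagene_scores",
]


@dataclass(frozen=True)
class Metagene:
    """A named set of >=2 coexpressed genes."""

    id: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.members)) < 2:
            raise ValueError(f"metagene {self.id!r} needs >=2 distinct members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"metagene {self.id!r} has duplicate members")

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)


@dataclass(frozen=True)
class HomogeneityRecord:
    metagene_id: str
    cohort_id: str
    score: float
    n_genes_present: int


def cluster_metagenes(expr: pd.DataFrame, n_clusters: int, seed: int, restarts: int = 20) -> list[Metagene]:
    """Partition genes into metagenes by k-means on standardized gene rows.

    For rows standardized to mean 0 / unit variance, squared Euclidean distance
    is monotonically related to 1 - Pearson correlation, so k-means here is a
    correlation-distance clustering. Best of ``restarts`` initializations kept;
    deterministic given ``seed``. Cluster ids are assigned in order of first
    appearance along the gene index.
    """
    n_genes = expr.shape[0]
    if not (2 <= n_clusters < n_genes):
        raise ValueError(f"n_clusters must be in [2, n_genes); got {n_clusters}")
    km = KMeans(n_clusters=n_clusters, n_init=restarts, random_state=seed)
    labels = km.fit_predict(expr.to_numpy(dtype=float))
    # stable relabeling: clusters numbered by first gene occurrence
    relabel: dict[int, int] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    out: list[Metagene] = []
    for new_id in range(1, n_clusters + 1):
        orig = next(k for k, v in relabel.items() if v == new_id)
        members = tuple(expr.index[labels == orig])
        if len(members) < 2:  # k-means can produce singletons on tiny data
            warnings.warn(f"cluster {new_id} is a singleton; skipped")
            continue
        out.append(Metagene(id=f"metagene_{new_id}", members=members))
    return out


def load_metagenes(path) -> list[Metagene]:
    """Load metagene memberships from a GMT file (or two-column TSV).

    GMT lines are ``name<TAB>description<TAB>gene...``; a two-column TSV has
    ``metagene_id<TAB>gene`` rows. Duplicated genes within a set are
    deduplicated with a warning; singleton sets are rejected.
    """
    path = str(path)
    if path.endswith(".gmt"):
        raw = read_gmt(path)
    else:
        table = pd.read_csv(path, sep="\t", header=None, names=["metagene_id", "gene"])
        raw = [
            (str(mid), "", list(sub["gene"].astype(str)))
            for mid, sub in table.groupby("metagene_id", sort=False)
        ]
    if not raw:
        warnings.warn(f"{path}: no gene sets found")
        return []
    out = []
    for name, _desc, genes in raw:
        unique = list(dict.fromkeys(genes))
        if len(unique) != len(genes):
            warnings.warn(f"metagene {name!r}: duplicated gene(s) removed")
        if len(unique) < 2:
            raise ValueError(f"metagene {name!r} has fewer than 2 genes")
        out.append(Metagene(id=name, members=tuple(unique)))
    return out


def homogeneity(expr: pd.DataFrame, metagene: Metagene, cohort_id: str = "") -> HomogeneityRecord:
    """Average pairwise Pearson correlation between member-gene rows.

    Pairs involving a constant row are excluded (with a warning). Raises if
    fewer than two member genes are present in the matrix.
    """
    present = [g for g in metagene.members if g in expr.index]
    if len(present) < 2:
        raise ValueError(
            f"metagene {metagene.id!r} has <2 members in cohort {cohort_id!r}; homogeneity undefined"
        )
    X = expr.loc[present].to_numpy(dtype=float)
    sd = X.std(axis=1)
    if (sd == 0).any():
        warnings.warn(
            f"metagene {metagene.id!r}: constant member row(s) excluded from pairwise correlations"
        )
        X = X[sd > 0]
        if X.shape[0] < 2:
            raise ValueError(
                f"metagene {metagene.id!r} has <2 non-constant members in cohort {cohort_id!r}"
            )
    R = np.corrcoef(X)
    iu = np.triu_indices_from(R, k=1)
    return HomogeneityRecord(
        metagene_id=metagene.id,
        cohort_id=cohort_id,
        score=float(R[iu].mean()),
        n_genes_present=len(present),
    )


def cross_cohort_homogeneity(
    metagenes: list[Metagene],
    cohorts: dict[str, pd.DataFrame],
    primary_id: str | None = None,
) -> pd.DataFrame:
    """Homogeneity of every metagene in every cohort, ranked by validation average.

    The average is taken over validation cohorts only: every cohort except
    ``primary_id`` (whose score is still reported). Metagenes undefined in all
    cohorts are excluded with a warning; ties in the ranking break
    lexicographically by metagene id.
    """
    if not cohorts:
        raise ValueError("need at least one cohort")
    validation = [c for c in cohorts if c != primary_id]
    rows = {}
    for mg in metagenes:
        scores = {}
        for cid, expr in cohorts.items():
            try:
                scores[cid] = homogeneity(expr, mg, cid).score
            except ValueError:
                scores[cid] = np.nan
        if all(np.isnan(v) for v in scores.values()):
            warnings.warn(f"metagene {mg.id!r} undefined in every cohort; excluded")
            continue
        val = [scores[c] for c in validation if not np.isnan(scores[c])]
        scores["validation_average"] = float(np.mean(val)) if val else np.nan
        rows[mg.id] = scores
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "metagene_id"
    table = table.sort_values(
        ["validation_average", "metagene_id"],
        ascending=[False, True],
        key=lambda s: s if s.name == "validation_average" else s.str.lower(),
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def select_top_metagenes(
    ranked_table: pd.DataFrame,
    metagenes: list[Metagene],
    top_n: int = 10,
    min_avg: float = 0.45,
) -> list[Metagene]:
    """First ``min(top_n, #{average >= min_avg})`` metagenes of the ranked table."""
    if ranked_table.empty:
        warnings.warn("empty homogeneity table: selecting no metagenes")
        return []
    eligible = ranked_table[ranked_table["validation_average"] >= min_avg]
    chosen_ids = list(eligible.index[:top_n])
    by_id = {m.id: m for m in metagenes}
    return [by_id[i] for i in chosen_ids]


def metagene_scores(expr: pd.DataFrame, metagenes: list[Metagene]) -> pd.DataFrame:
    """Per-sample metagene activity: mean of standardized member-gene rows.

    Members absent from the matrix are skipped (logged); a metagene with no
    members present yields a row of NaN with a warning. Expression must be
    complete (no missing values).
    """
    Z = standardize_genes(expr)
    rows = {}
    for mg in metagenes:
        present = [g for g in mg.members if g in Z.index]
        if not present:
            warnings.warn(f"metagene {mg.id!r}: no members present; scores are NaN")
            rows[mg.id] = np.full(Z.shape[1], np.nan)
            continue
        if len(present) < len(mg.members):
            missing = set(mg.members) - set(present)
            warnings.warn(f"metagene {mg.id!r}: {len(missing)} member(s) absent from matrix")
        rows[mg.id] = Z.loc[present].to_numpy().mean(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=Z.columns)
    out.index.name = "metagene_id"
    return out
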