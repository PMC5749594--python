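"""Prognosis meta-analysis across survival cohorts.

For each metagene and cohort, member genes are standardized within that cohort,
averaged into a per-sample activity score, and the score is fit by univariate
Cox proportional-hazards regression. The per-cohort Wald z statistics
(positive = higher score, higher hazard = poor prognosis) are combined across
cohorts of the same histology group by the Stouffer method,
``meta_z = sum(z) / sqrt(k)``, and a metagene is called prognostic when
|meta_z| > 2: poor prognosis above +2, good prognosis below -2.

The Cox partial likelihood uses Breslow tie handling and is maximized by
Newton-Raphson to gradient tolerance 1e-9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .enrichment import bh_fdr
from .metagenes import Metagene
from .preprocess import standardize_genes

__all__ = [
    "SurvivalCohort",
    "ConvergenceError",
    "cox_z",
    "stouffer",
    "prognosis_call",
    "MetagenePrognosis",
    "PrognosisResults",
]

CALL_POOR = "poor-prognosis"
CALL_GOOD = "good-prognosis"
CALL_NS = "not-significant"


class ConvergenceError(RuntimeError):
    pass


@dataclass
class SurvivalCohort:
    """One cohort: follow-up times, event indicators and matched expression."""

    cohort_id: str
    histology_group: str
    times: np.ndarray
    events: np.ndarray
    expr: pd.DataFrame  # genes x samples, same sample order as times/events

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if (self.times <= 0).any():
            raise ValueError(f"cohort {self.cohort_id!r}: times must be positive")
        if not np.isin(self.events, [0, 1]).all():
            raise ValueError(f"cohort {self.cohort_id!r}: events must be 0/1")
        if len(self.times) != len(self.events) or len(self.times) != self.expr.shape[1]:
            raise ValueError(f"cohort {self.cohort_id!r}: sample counts disagree")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expr.columns)

    @property
    def n(self) -> int:
        return len(self.times)


def cox_z(score, times, events, tol: float = 1e-9, max_iter: int = 100) -> float:
    """Wald z of a univariate Cox proportional-hazards fit (Breslow ties).

    z = beta_hat / SE(beta_hat); positive z means higher score carries higher
    hazard. Raises on a constant score, <2 observed events, or failure to
    reach gradient tolerance within ``max_iter`` Newton steps.
    """
    x = np.asarray(score, dtype=float)
    t = np.asarray(times, dtype=float)
    d = np.asarray(events, dtype=int)
    if x.std() == 0:
        raise ValueError("constant score: Cox z undefined")
    if d.sum() < 2:
        raise ValueError("fewer than 2 observed events: Cox z undefined")
    x = x - x.mean()  # numerical stability; Cox is shift-invariant

    order = np.argsort(-t, kind="stable")  # descending time
    xs, ts, ds = x[order], t[order], d[order]
    n = len(ts)
    # risk set of subject i = everyone with time >= t_i; with the descending
    # sort that is positions 0..last index sharing t_i (Breslow: tied events
    # all see the full risk set)
    last_tied = np.arange(n)
    for i in range(n - 2, -1, -1):
        if ts[i] == ts[i + 1]:
            last_tied[i] = last_tied[i + 1]
    ev = ds == 1

    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * xs)
        S0 = np.cumsum(w)[last_tied]
        S1 = np.cumsum(w * xs)[last_tied]
        S2 = np.cumsum(w * xs * xs)[last_tied]
        mu = S1 / S0
        U = float(np.sum(xs[ev] - mu[ev]))
        I = float(np.sum((S2 / S0 - mu * mu)[ev]))
        if abs(U) < tol:
            if I <= 0:
                raise ConvergenceError(f"non-positive information {I} at beta={beta}")
            return beta * np.sqrt(I)
        step = U / I
        beta += np.clip(step, -5.0, 5.0)
    raise ConvergenceError(
        f"Cox Newton-Raphson did not converge in {max_iter} iterations "
        f"(beta={beta:.4g}, gradient={U:.3g})"
    )


def prognosis_call(meta_z: float, cut: float = 2.0) -> str:
    """Significance call for a meta-z: poor above +cut, good below -cut."""
    if meta_z > cut:
        return CALL_POOR
    if meta_z < -cut:
        return CALL_GOOD
    return CALL_NS


def stouffer(zs) -> float:
    """Unweighted Stouffer combination: sum(z) / sqrt(len(z))."""
    z = np.asarray(list(zs), dtype=float)
    if z.size == 0:
        raise ValueError("Stouffer combination needs at least one z")
    if not np.isfinite(z).all():
        raise ValueError("Stouffer combination requires finite z values")
    return float(z.sum() / np.sqrt(z.size))


class MetagenePrognosis:
    """Meta-analysis of metagene activity against overall survival.

    Parameters
    ----------
    metagenes : list of Metagene
    cohorts : list of SurvivalCohort
        Each labeled with a histology group (e.g. adenocarcinoma / squamous).
    """

    def __init__(self, metagenes: list[Metagene], cohorts: list[SurvivalCohort]):
        if not cohorts:
            raise ValueError("need at least one survival cohort")
        self.metagenes = metagenes
        self.cohorts = cohorts

    def _cohort_z(self, mg: Metagene, cohort: SurvivalCohort) -> float:
        present = [g for g in mg.members if g in cohort.expr.index]
        if len(present) == 0:
            raise ValueError(f"no members of {mg.id!r} in cohort {cohort.cohort_id!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Z = standardize_genes(cohort.expr.loc[present])
        if Z.empty:
            raise ValueError(f"all members of {mg.id!r} constant in {cohort.cohort_id!r}")
        score = Z.to_numpy().mean(axis=0)
        return cox_z(score, cohort.times, cohort.events)

    def fit(self, group_by_histology: bool = True, meta_z_cut: float = 2.0) -> "PrognosisResults":
        groups: dict[str, list[SurvivalCohort]] = {}
        for c in self.cohorts:
            key = c.histology_group if group_by_histology else "all"
            groups.setdefault(key, []).append(c)

        records = []
        for group, cohorts in groups.items():
            for mg in self.metagenes:
                per_cohort = {}
                for c in cohorts:
                    try:
                        per_cohort[c.cohort_id] = self._cohort_z(mg, c)
                    except (ValueError, ConvergenceError) as exc:
                        warnings.warn(
                            f"{mg.id}/{c.cohort_id}: Cox z undefined ({exc}); excluded"
                        )
                        per_cohort[c.cohort_id] = np.nan
                finite = [z for z in per_cohort.values() if np.isfinite(z)]
                if not finite:
                    warnings.warn(f"{mg.id}: no defined cohort z in group {group!r}")
                    continue
                mz = stouffer(finite)
                records.append(
                    {
                        "metagene_id": mg.id,
                        "histology_group": group,
                        "per_cohort_z": per_cohort,
                        "n_cohorts": len(finite),
                        "meta_z": mz,
                        "meta_p": float(2 * norm.sf(abs(mz))),
                    }
                )

        # BH FDR within each histology group (the reported family)
        df = pd.DataFrame(records)
        if len(df):
            df["fdr"] = np.nan
            for group in df["histology_group"].unique():
                mask = df["histology_group"] == group
                df.loc[mask, "fdr"] = bh_fdr(
                    np.clip(df.loc[mask, "meta_p"].to_numpy(), 1e-300, 1.0)
                )
            df["call"] = [prognosis_call(z, meta_z_cut) for z in df["meta_z"]]
        else:
            df = pd.DataFrame(
                columns=[
                    "metagene_id", "histology_group", "per_cohort_z",
                    "n_cohorts", "meta_z", "meta_p", "fdr", "call",
                ]
            )
        return PrognosisResults(df, meta_z_cut)


class PrognosisResults:
    """Per-group meta-z table with prognosis calls.

    ``table`` holds one row per (metagene, histology group) with the
    per-cohort z map, the Stouffer meta-z, its two-sided normal p, the
    within-group BH FDR and the |z|>cut call.
    """

    def __init__(self, table: pd.DataFrame, meta_z_cut: float):
        self.table = table
        self.meta_z_cut = meta_z_cut

    def wide_table(self) -> pd.DataFrame:
        """Table with one column per cohort z, mirroring a per-cohort layout."""
        if self.table.empty:
            return self.table.copy()
        z_cols = pd.json_normalize(self.table["per_cohort_z"]).set_index(self.table.index)
        z_cols.columns = [f"z_{c}" for c in z_cols.columns]
        base = self.table.drop(columns=["per_cohort_z"])
        return pd.concat([base, z_cols], axis=1)

    def calls(self, group: str | None = None) -> pd.Series:
        t = self.table if group is None else self.table[self.table["histology_group"] == group]
        return t.set_index("metagene_id")["call"]

    def summary(self) -> str:
        lines = [f"Metagene prognosis meta-analysis (Stouffer meta-z, |z|>{self.meta_z_cut:g})"]
        for group, sub in self.table.groupby("histology_group"):
            lines.append(f"  [{group}]")
            for _, r in sub.sort_values("meta_z").iterrows():
                lines.append(
                    f"    {r.metagene_id:>14s}  meta_z={r.meta_z:+7.2f}  "
                    f"p={r.meta_p:.3g}  fdr={r.fdr:.3g}  {r.call}"
                )
        return "\n".join(lines)
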