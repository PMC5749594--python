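"""The radiogenomic association map.

Every retained semantic image feature is tested against every metagene
activity score: binary features by a pooled-variance two-sample t statistic
(positive t = higher metagene activity when the feature is present), ordinal
features by Spearman rank correlation over the codebook's declared level
order. P values are corrected by Benjamini-Hochberg FDR jointly across all
tested pairs, and a pair is significant when P < .05 and FDR < 0.01. Rows and
columns of the resulting map are ordered by average-linkage hierarchical
clustering of the -log10(p) profiles.

Features are first screened by occurrence rate: a binary feature must have
minor-class frequency strictly above the cutoff (a feature present in 95% of
patients is as uninformative as one present in 5%); an ordinal feature must
have more than the cutoff fraction of patients outside its modal level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu, spearmanr, ttest_ind

from .enrichment import bh_fdr

__all__ = [
    "SemanticFeatureTable",
    "filter_features",
    "binary_association",
    "ordinal_association",
    "group_difference_test",
    "AssociationMap",
    "AssociationMapResults",
]


@dataclass
class SemanticFeatureTable:
    """Patients x semantic-feature table with a codebook.

    ``data`` holds integer codes (binary: 0/1; ordinal: 0..L-1 indexing the
    codebook's ordered level labels) with NaN for missing. ``codebook`` maps
    feature id -> {"type": "binary"|"ordinal", "levels": [labels] | None}.
    """

    data: pd.DataFrame
    codebook: dict

    def __post_init__(self):
        undeclared = [c for c in self.data.columns if c not in self.codebook]
        if undeclared:
            raise ValueError(f"feature column(s) missing from codebook: {undeclared}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate patient ids")
        for col in self.data.columns:
            spec = self.codebook[col]
            vals = self.data[col].dropna()
            if spec["type"] == "binary":
                if not vals.isin([0, 1]).all():
                    raise ValueError(f"binary feature {col!r} has values outside {{0,1}}")
            elif spec["type"] == "ordinal":
                n_levels = len(spec["levels"])
                if not vals.isin(range(n_levels)).all():
                    raise ValueError(
                        f"ordinal feature {col!r} has codes outside 0..{n_levels - 1}"
                    )
            else:
                raise ValueError(f"feature {col!r}: unknown type {spec['type']!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)


def filter_features(
    table: SemanticFeatureTable, min_occurrence: float = 0.10
) -> tuple[SemanticFeatureTable, dict[str, str]]:
    """Occurrence-rate screen; returns the retained table and a removal log.

    Binary: minor-class frequency must exceed ``min_occurrence`` (strict).
    Ordinal: the fraction of patients outside the modal level must exceed it.
    Missing values are excluded from the denominators.
    """
    removed: dict[str, str] = {}
    keep = []
    for col in table.data.columns:
        vals = table.data[col].dropna()
        if vals.empty:
            removed[col] = "all values missing"
            warnings.warn(f"feature {col!r}: all values missing; removed")
            continue
        freqs = vals.value_counts(normalize=True)
        if table.codebook[col]["type"] == "binary":
            minor = min(freqs.get(0, 0.0), freqs.get(1, 0.0))
            if minor > min_occurrence:
                keep.append(col)
            else:
                removed[col] = f"minor-class frequency {minor:.3f} <= {min_occurrence}"
        else:
            non_modal = 1.0 - freqs.max()
            if non_modal > min_occurrence:
                keep.append(col)
            else:
                removed[col] = f"non-modal fraction {non_modal:.3f} <= {min_occurrence}"
    out = SemanticFeatureTable(
        data=table.data[keep].copy(),
        codebook={f: table.codebook[f] for f in keep},
    )
    return out, removed


def binary_association(scores, feature) -> tuple[float, float]:
    """Pooled-variance two-sample t of metagene scores by binary feature.

    Positive t means higher scores when the feature is present (1 vs 0);
    two-sided p on n1+n0-2 degrees of freedom. Missing values dropped
    pairwise. Both groups must have >=2 patients.
    """
    s = np.asarray(scores, dtype=float)
    f = np.asarray(feature, dtype=float)
    ok = ~(np.isnan(s) | np.isnan(f))
    s, f = s[ok], f[ok]
    g1, g0 = s[f == 1], s[f == 0]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError(f"a group has <2 patients (n1={len(g1)}, n0={len(g0)})")
    t, p = ttest_ind(g1, g0, equal_var=True)
    return float(t), float(p)


def ordinal_association(scores, feature) -> tuple[float, float]:
    """Spearman rank correlation of metagene scores with ordinal level codes.

    Ties receive average ranks; two-sided p from the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` (p = 0 at rho = +/-1). Needs >=3
    complete pairs and >=2 distinct levels.
    """
    s = np.asarray(scores, dtype=float)
    f = np.asarray(feature, dtype=float)
    ok = ~(np.isnan(s) | np.isnan(f))
    s, f = s[ok], f[ok]
    if len(s) < 3:
        raise ValueError(f"need >=3 complete pairs, got {len(s)}")
    if len(np.unique(f)) < 2:
        raise ValueError("feature constant after dropping missing values")
    rho, p = spearmanr(s, f)
    if abs(rho) >= 1.0 - 1e-12:  # perfectly monotone up to float error
        rho, p = float(np.sign(rho)), 0.0
    return float(rho), float(p)


def group_difference_test(values, label) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of ``values`` between two groups.

    Returns the rank sum of the label-1 group and the two-sided p: exact by
    enumeration of rank splits when n1+n2 <= 12 and there are no ties, else
    the tie-corrected normal approximation (with continuity correction).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(label)
    x, y = v[g == 1], v[g != 1]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    small = len(x) + len(y) <= 12
    no_ties = len(np.unique(v)) == len(v)
    method = "exact" if (small and no_ties) else "asymptotic"
    u1, p = mannwhitneyu(x, y, alternative="two-sided", method=method)
    rank_sum = float(u1) + len(x) * (len(x) + 1) / 2.0
    return rank_sum, float(p)


class AssociationMap:
    """Model linking metagene activity scores to semantic image features.

    Parameters
    ----------
    scores : DataFrame
        Metagenes x patients activity matrix (see metagene_scores).
    features : SemanticFeatureTable
        Patients x features with codebook. Patients are matched to the score
        matrix by id; the intersection must reach ``min_patients``.
    """

    def __init__(self, scores: pd.DataFrame, features: SemanticFeatureTable, min_patients: int = 10):
        patients = [p for p in scores.columns if p in set(features.patient_ids)]
        if not patients:
            raise ValueError("no patients shared between scores and features")
        if len(patients) < min_patients:
            raise ValueError(
                f"only {len(patients)} shared patients; need >= {min_patients}"
            )
        self.scores = scores[patients]
        self.features = SemanticFeatureTable(
            data=features.data.loc[patients], codebook=features.codebook
        )
        self.patients = patients

    def fit(
        self,
        p_thresh: float = 0.05,
        fdr_thresh: float = 0.01,
        min_occurrence: float = 0.10,
    ) -> "AssociationMapResults":
        retained, removed = filter_features(self.features, min_occurrence)
        records = []
        for fid in retained.feature_ids:
            spec = retained.codebook[fid]
            fvals = retained.data[fid].to_numpy(dtype=float)
            for mid in self.scores.index:
                svals = self.scores.loc[mid].to_numpy(dtype=float)
                rec = {"feature_id": fid, "metagene_id": mid,
                       "stat_type": "t" if spec["type"] == "binary" else "spearman"}
                try:
                    if spec["type"] == "binary":
                        stat, p = binary_association(svals, fvals)
                    else:
                        stat, p = ordinal_association(svals, fvals)
                    rec.update(statistic=stat, p=p, tested=True)
                except ValueError as exc:
                    warnings.warn(f"{fid} x {mid}: untested ({exc})")
                    rec.update(statistic=np.nan, p=np.nan, tested=False)
                records.append(rec)
        table = pd.DataFrame(
            records,
            columns=["feature_id", "metagene_id", "stat_type", "statistic", "p", "tested"],
        )
        table["fdr"] = np.nan
        tested = table["tested"].to_numpy(dtype=bool)
        if tested.any():
            # BH family: all defined tests jointly; p=0 (perfect monotone
            # Spearman) clipped for the corrector, q stays 0-adjacent
            pvals = np.clip(table.loc[tested, "p"].to_numpy(), 1e-300, 1.0)
            table.loc[tested, "fdr"] = bh_fdr(pvals)
        table["significant"] = (
            tested & (table["p"] < p_thresh) & (table["fdr"] < fdr_thresh)
        )
        table["direction"] = np.sign(table["statistic"])
        return AssociationMapResults(
            table,
            feature_ids=retained.feature_ids,
            metagene_ids=list(self.scores.index),
            removed_features=removed,
            p_thresh=p_thresh,
            fdr_thresh=fdr_thresh,
            n_patients=len(self.patients),
        )


class AssociationMapResults:
    """Fitted feature-metagene association map.

    ``records`` has one row per feature x metagene pair (tested or not);
    ``row_order`` / ``col_order`` (set by :meth:`order_map`) arrange features
    and metagenes by hierarchical clustering of their -log10(p) profiles.
    """

    def __init__(self, records, feature_ids, metagene_ids, removed_features,
                 p_thresh, fdr_thresh, n_patients):
        self.records = records
        self.feature_ids = list(feature_ids)
        self.metagene_ids = list(metagene_ids)
        self.removed_features = removed_features
        self.p_thresh = p_thresh
        self.fdr_thresh = fdr_thresh
        self.n_patients = n_patients
        self.row_order: list[str] = list(feature_ids)
        self.col_order: list[str] = list(metagene_ids)

    @property
    def n_significant(self) -> int:
        return int(self.records["significant"].sum())

    @property
    def n_tested(self) -> int:
        return int(self.records["tested"].sum())

    def significant(self) -> pd.DataFrame:
        sig = self.records[self.records["significant"]]
        return sig.sort_values(["metagene_id", "p"]).reset_index(drop=True)

    def p_matrix(self) -> pd.DataFrame:
        """Features x metagenes matrix of p values (NaN where untested)."""
        return self.records.pivot(index="feature_id", columns="metagene_id", values="p").loc[
            self.feature_ids, self.metagene_ids
        ]

    def order_map(self, method: str = "average") -> "AssociationMapResults":
        """Set row/col orders by agglomerative clustering of -log10(p) vectors.

        Euclidean distances, average linkage by default; untested cells are
        imputed with 0 before clustering. Single-row or single-column maps
        keep the identity order. Returns self.
        """
        logp = -np.log10(np.clip(self.p_matrix().to_numpy(dtype=float), 1e-300, 1.0))
        logp[~np.isfinite(logp)] = 0.0
        logp = np.nan_to_num(logp, nan=0.0)

        def _leaf_order(X):
            if X.shape[0] < 2:
                return list(range(X.shape[0]))
            return list(leaves_list(linkage(pdist(X), method=method)))

        self.row_order = [self.feature_ids[i] for i in _leaf_order(logp)]
        self.col_order = [self.metagene_ids[i] for i in _leaf_order(logp.T)]
        return self

    def plot_heatmap(self, ax=None):
        """Signed -log10(p) heatmap in clustered order (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 10))
        pm = self.p_matrix().loc[self.row_order, self.col_order]
        sm = self.records.pivot(
            index="feature_id", columns="metagene_id", values="statistic"
        ).loc[self.row_order, self.col_order]
        signed = -np.log10(np.clip(pm.to_numpy(), 1e-300, 1.0)) * np.sign(
            np.nan_to_num(sm.to_numpy())
        )
        im = ax.imshow(np.nan_to_num(signed), cmap="RdBu_r", aspect="auto")
        ax.set_xticks(range(len(self.col_order)), self.col_order, rotation=90, fontsize=7)
        ax.set_yticks(range(len(self.row_order)), self.row_order, fontsize=6)
        ax.figure.colorbar(im, ax=ax, label="signed -log10 P")
        return ax

    def summary(self) -> str:
        lines = [
            "Radiogenomic association map",
            f"  patients: {self.n_patients}   features retained: {len(self.feature_ids)} "
            f"(removed {len(self.removed_features)})   metagenes: {len(self.metagene_ids)}",
            f"  pairs tested: {self.n_tested}   "
            f"significant (P<{self.p_thresh}, FDR<{self.fdr_thresh}): {self.n_significant}",
        ]
        for _, r in self.significant().iterrows():
            lines.append(
                f"  {r.metagene_id:>14s} ~ {r.feature_id:<24s} {r.stat_type:>8s}="
                f"{r.statistic:+7.3f}  p={r.p:.3g}  fdr={r.fdr:.3g}"
            )
        return "\n".join(lines)
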