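"""Synthetic data with planted ground truth for every pipeline input.

The generators emulate the statistical structure the analysis assumes:

* blocks of coexpressed genes with tunable within-block correlation (a single
  shared Gaussian factor per block: gene g in block b is
  ``sqrt(rho) * f_b + sqrt(1-rho) * eps_g`` so every within-block pair has
  expected Pearson correlation rho),
* binary/ordinal semantic features whose distribution shifts with metagene
  scores at a tunable effect size (logistic link for binary, quantile-binned
  noisy latent for ordinal),
* right-censored survival times with a log-linear hazard in metagene score
  (exponential baseline, independent uniform censoring calibrated to the
  requested censor rate),
* gene-set databases with planted overlaps, and uniform missing-value masks.

Every generator is deterministic given its seed, and the planted structure is
returned in a GroundTruth record that can be serialized next to the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .assoc import SemanticFeatureTable
from .enrichment import GeneSetDatabase
from .metagenes import Metagene
from .survival import SurvivalCohort

__all__ = [
    "GroundTruth",
    "simulate_expression",
    "simulate_counts",
    "simulate_features",
    "simulate_survival_cohorts",
    "simulate_gene_sets",
    "inject_missing",
]


@dataclass
class GroundTruth:
    """Planted structure recorded alongside generated data.

    block_memberships maps gene id -> block id (or None for noise genes);
    planted_pairs lists (feature_id, metagene_id, effect_size) triples;
    hazard_betas maps (cohort_id, metagene_id) -> log hazard per unit score.
    """

    seed: int
    block_memberships: dict = field(default_factory=dict)
    planted_pairs: list = field(default_factory=list)
    hazard_betas: dict = field(default_factory=dict)
    within_block_correlation: float | None = None

    def __post_init__(self):
        if self.within_block_correlation is not None and not (
            0 <= self.within_block_correlation < 1
        ):
            raise ValueError("within_block_correlation must lie in [0, 1)")

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "within_block_correlation": self.within_block_correlation,
            "block_memberships": self.block_memberships,
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "hazard_betas": [
                {"cohort_id": c, "metagene_id": m, "beta": b}
                for (c, m), b in self.hazard_betas.items()
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            seed=d["seed"],
            within_block_correlation=d.get("within_block_correlation"),
            block_memberships=d.get("block_memberships", {}),
            planted_pairs=[tuple(p) for p in d.get("planted_pairs", [])],
            hazard_betas={
                (r["cohort_id"], r["metagene_id"]): r["beta"]
                for r in d.get("hazard_betas", [])
            },
        )


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def simulate_expression(
    n_genes: int,
    n_samples: int,
    n_blocks: int,
    block_size: int,
    rho: float,
    seed: int,
    sample_prefix: str = "s",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gaussian expression with ``n_blocks`` coexpression blocks.

    The first ``n_blocks * block_size`` genes form blocks b1..bK with expected
    pairwise within-block correlation ``rho``; remaining genes are independent
    standard normal noise.
    """
    if not (0 <= rho < 1):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if n_blocks * block_size > n_genes:
        raise ValueError("n_blocks * block_size exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    samples = [f"{sample_prefix}{j:04d}" for j in range(n_samples)]
    X = np.empty((n_genes, n_samples))
    membership: dict[str, str | None] = {g: None for g in genes}
    for b in range(n_blocks):
        factor = rng.standard_normal(n_samples)
        lo = b * block_size
        eps = rng.standard_normal((block_size, n_samples))
        X[lo : lo + block_size] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * eps
        for g in genes[lo : lo + block_size]:
            membership[g] = f"b{b + 1}"
    n_planted = n_blocks * block_size
    X[n_planted:] = rng.standard_normal((n_genes - n_planted, n_samples))
    truth = GroundTruth(
        seed=seed, block_memberships=membership, within_block_correlation=rho
    )
    return pd.DataFrame(X, index=genes, columns=samples), truth


def simulate_counts(
    n_genes: int,
    n_samples: int,
    expressed_fraction: float,
    seed: int,
    expressed_mean: float = 50.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Count matrix where a known subset of rows passes the low-count filter.

    Expressed rows have >=5 reads in every sample (5 + Poisson); unexpressed
    rows never reach 5 reads anywhere, so the >=5-in->=70%-of-samples rule
    keeps exactly the labeled rows. Returns (counts, pass-labels).
    """
    if not (0 <= expressed_fraction <= 1):
        raise ValueError("expressed_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    n_expr = int(round(expressed_fraction * n_genes))
    counts = np.empty((n_genes, n_samples), dtype=int)
    counts[:n_expr] = 5 + rng.poisson(expressed_mean, size=(n_expr, n_samples))
    counts[n_expr:] = np.minimum(
        rng.poisson(1.0, size=(n_genes - n_expr, n_samples)), 4
    )
    labels = pd.Series([i < n_expr for i in range(n_genes)], index=genes, name="expressed")
    samples = [f"s{j:04d}" for j in range(n_samples)]
    return pd.DataFrame(counts, index=genes, columns=samples), labels


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_features(
    metagene_scores: pd.DataFrame,
    planted_pairs: list[tuple[str, str, float]],
    n_null_features: int,
    feature_specs: dict | None = None,
    seed: int = 0,
    null_frequencies: list[float] | None = None,
    ordinal_noise_sd: float = 1.0,
) -> tuple[SemanticFeatureTable, GroundTruth]:
    """Semantic feature table with planted feature-metagene associations.

    For a planted binary pair with effect d the feature is Bernoulli with
    P(1) = logistic(d * score); for a planted ordinal pair the feature is a
    quantile-binned copy of ``d * score + noise`` on the codebook's levels.
    Null features are independent of all scores, Bernoulli with marginal
    frequencies cycling through ``null_frequencies`` (default 0.3) so the
    occurrence filter can be exercised in both directions.

    ``feature_specs`` declares planted features' types/levels; undeclared
    planted features default to binary.
    """
    rng = np.random.default_rng(seed)
    patients = list(metagene_scores.columns)
    feature_specs = dict(feature_specs or {})
    for fid, mid, _d in planted_pairs:
        if mid not in metagene_scores.index:
            raise ValueError(f"planted pair references unknown metagene {mid!r}")
        spec = feature_specs.setdefault(fid, {"type": "binary", "levels": None})
        if spec["type"] not in ("binary", "ordinal"):
            raise ValueError(f"feature {fid!r}: unknown type {spec['type']!r} in codebook")

    data = {}
    codebook = {}
    for fid, mid, d in planted_pairs:
        spec = feature_specs[fid]
        score = metagene_scores.loc[mid].to_numpy(dtype=float)
        if spec["type"] == "binary":
            data[fid] = (rng.random(len(patients)) < _logistic(d * score)).astype(float)
            codebook[fid] = {"type": "binary", "levels": None}
        else:
            latent = d * score + ordinal_noise_sd * rng.standard_normal(len(patients))
            levels = spec["levels"]
            n_lv = len(levels)
            edges = np.quantile(latent, np.linspace(0, 1, n_lv + 1)[1:-1])
            data[fid] = np.searchsorted(edges, latent, side="right").astype(float)
            codebook[fid] = {"type": "ordinal", "levels": list(levels)}

    null_frequencies = null_frequencies or [0.3]
    for i in range(n_null_features):
        fid = f"null_{i:03d}"
        freq = null_frequencies[i % len(null_frequencies)]
        data[fid] = (rng.random(len(patients)) < freq).astype(float)
        codebook[fid] = {"type": "binary", "levels": None}

    table = SemanticFeatureTable(
        data=pd.DataFrame(data, index=patients), codebook=codebook
    )
    truth = GroundTruth(seed=seed, planted_pairs=[tuple(p) for p in planted_pairs])
    return table, truth


def _calibrate_censor_tau(event_times: np.ndarray, censor_rate: float) -> float:
    """Upper bound tau of Uniform(0, tau) censoring such that the expected
    censored fraction of the drawn event times equals censor_rate."""
    # P(censored_i) = P(C < T_i) = min(T_i, tau)/tau; average over i, solve in tau
    lo, hi = 1e-9, float(event_times.max()) * 1e4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        rate = np.minimum(event_times, mid).mean() / mid
        if rate > censor_rate:
            lo = mid  # too much censoring -> lengthen tau
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_survival_cohorts(
    n_cohorts: int,
    n_per_cohort: int,
    betas: dict[str, float],
    censor_rate: float,
    seed: int,
    metagenes: list[Metagene] | None = None,
    rho: float = 0.6,
    block_size: int = 20,
    baseline_hazard: float = 0.1,
    histology_group: str = "adenocarcinoma",
    cohort_prefix: str = "cohort",
) -> tuple[list[SurvivalCohort], GroundTruth]:
    """Survival cohorts whose hazard is log-linear in metagene activity.

    Each cohort carries expression with one coexpression block per metagene
    (within-block correlation ``rho``); the hazard of patient j is
    ``h0 * exp(sum_m beta_m * f_m(j))`` where f_m is block m's latent factor
    (the noiseless metagene score). Event times are exponential, censoring is
    independent Uniform(0, tau) with tau calibrated to the requested censor
    rate; observed time = min(event, censor).
    """
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    if metagenes is None:
        metagenes = [
            Metagene(
                id=mid, members=tuple(f"{mid}_g{j:03d}" for j in range(block_size))
            )
            for mid in betas
        ]
    by_id = {m.id: m for m in metagenes}
    for mid in betas:
        if mid not in by_id:
            raise ValueError(f"beta references unknown metagene {mid!r}")

    cohorts = []
    hazard_betas = {}
    for c in range(n_cohorts):
        cid = f"{cohort_prefix}_{c + 1}"
        factors = {}
        rows, index = [], []
        for mg in metagenes:
            f = rng.standard_normal(n_per_cohort)
            factors[mg.id] = f
            eps = rng.standard_normal((len(mg.members), n_per_cohort))
            rows.append(np.sqrt(rho) * f + np.sqrt(1 - rho) * eps)
            index.extend(mg.members)
        X = np.vstack(rows)
        samples = [f"{cid}_p{j:04d}" for j in range(n_per_cohort)]
        expr = pd.DataFrame(X, index=index, columns=samples)

        log_hazard = np.zeros(n_per_cohort)
        for mid, beta in betas.items():
            log_hazard += beta * factors[mid]
            hazard_betas[(cid, mid)] = beta
        lam = baseline_hazard * np.exp(log_hazard)
        event_times = rng.exponential(1.0 / lam)
        if censor_rate > 0:
            tau = _calibrate_censor_tau(event_times, censor_rate)
            censor_times = rng.uniform(0, tau, size=n_per_cohort)
            times = np.minimum(event_times, censor_times)
            events = (event_times <= censor_times).astype(int)
        else:
            times, events = event_times, np.ones(n_per_cohort, dtype=int)
        times = np.maximum(times, 1e-9)  # strictly positive
        cohorts.append(
            SurvivalCohort(
                cohort_id=cid,
                histology_group=histology_group,
                times=times,
                events=events,
                expr=expr,
            )
        )
    truth = GroundTruth(
        seed=seed, hazard_betas=hazard_betas, within_block_correlation=rho
    )
    return cohorts, truth


def simulate_gene_sets(
    universe: list[str],
    metagenes: list[Metagene],
    planted_overlaps: list[tuple[str, int, int]],
    n_random_sets: int,
    seed: int,
    random_set_size: tuple[int, int] = (10, 50),
) -> tuple[GeneSetDatabase, GroundTruth]:
    """Gene-set database with planted overlaps against target metagenes.

    ``planted_overlaps`` entries are (metagene_id, overlap, set_size): the
    planted set shares exactly ``overlap`` genes with the metagene (within the
    universe) and pads to ``set_size`` with genes outside it. Random sets are
    uniform draws from the universe.
    """
    rng = np.random.default_rng(seed)
    universe = list(map(str, universe))
    uni_set = set(universe)
    by_id = {m.id: m for m in metagenes}
    sets: dict[str, frozenset] = {}
    for i, (mid, overlap, set_size) in enumerate(planted_overlaps):
        if mid not in by_id:
            raise ValueError(f"planted overlap references unknown metagene {mid!r}")
        mg_in_uni = sorted(by_id[mid].member_set & uni_set)
        if overlap > len(mg_in_uni):
            raise ValueError(
                f"requested overlap {overlap} exceeds metagene {mid!r} size {len(mg_in_uni)}"
            )
        inside = list(rng.choice(mg_in_uni, size=overlap, replace=False)) if overlap else []
        outside_pool = sorted(uni_set - by_id[mid].member_set)
        n_out = set_size - overlap
        if n_out > len(outside_pool):
            raise ValueError(f"set_size {set_size} too large for the universe")
        outside = list(rng.choice(outside_pool, size=n_out, replace=False))
        sets[f"planted_{i:02d}_{mid}"] = frozenset(inside + outside)
    for i in range(n_random_sets):
        size = int(rng.integers(random_set_size[0], random_set_size[1] + 1))
        sets[f"random_{i:03d}"] = frozenset(rng.choice(universe, size=size, replace=False))
    truth = GroundTruth(
        seed=seed,
        planted_pairs=[
            (f"planted_{i:02d}_{mid}", mid, float(overlap))
            for i, (mid, overlap, _sz) in enumerate(planted_overlaps)
        ],
    )
    return GeneSetDatabase(sets=sets, source="synthetic"), truth


def inject_missing(
    matrix: pd.DataFrame, rate: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set entries missing uniformly at random; returns (masked, mask).

    The boolean mask marks the removed entries so recovery error can be
    computed against the caller's original matrix.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(matrix.shape) < rate
    out = matrix.copy().astype(float)
    out.values[mask] = np.nan
    return out, pd.DataFrame(mask, index=matrix.index, columns=matrix.columns)
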