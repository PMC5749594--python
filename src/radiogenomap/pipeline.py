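"""End-to-end orchestration: preprocess -> metagenes -> enrichment -> prognosis -> map.

`make_demo` writes a complete synthetic input bundle shaped like a
radiogenomics study (113 patients, 87 semantic features of which ~35 survive
the occurrence filter, 10 high-coherence metagenes among 14 candidates, 5
validation expression cohorts, survival cohorts in two histology groups) with
its planted ground truth; `run_pipeline` executes every stage from files,
writes each stage's tables, and returns a RunReport whose counts reconcile
with the written outputs. Re-running with the same config and inputs
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .assoc import AssociationMap, SemanticFeatureTable
from .enrichment import GeneSetDatabase, MetageneEnrichment
from .metagenes import (
    Metagene,
    cross_cohort_homogeneity,
    load_metagenes,
    metagene_scores,
    select_top_metagenes,
)
from .preprocess import filter_low_count_transcripts, knn_impute, log_transform, standardize_genes
from .simulate import (
    GroundTruth,
    inject_missing,
    simulate_counts,
    simulate_expression,
    simulate_features,
    simulate_gene_sets,
    simulate_survival_cohorts,
)
from .survival import MetagenePrognosis, SurvivalCohort

logger = logging.getLogger("radiogenomap")

__all__ = ["PipelineConfig", "RunReport", "make_demo", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run.

    All thresholds default to the analysis' standard cutoffs: >=5 reads in
    >=70% of samples, k=15 imputation neighbors, top 10 metagenes at average
    homogeneity >=0.45, enrichment at P<.001 & Q<0.05, prognosis at |meta-z|>2,
    the map at P<.05 & FDR<0.01, and a 10% feature occurrence cutoff.
    """

    counts: str
    fpkm: str
    metagenes_gmt: str
    validation_cohorts: dict
    gene_sets_gmt: str
    features: str
    codebook: str
    survival: str
    survival_expr: dict
    ground_truth: str | None = None
    min_count: int = 5
    min_fraction: float = 0.7
    knn_k: int = 15
    pseudocount: float | None = None
    top_n: int = 10
    min_homogeneity: float = 0.45
    enrich_p: float = 0.001
    enrich_q: float = 0.05
    meta_z_cut: float = 2.0
    map_p: float = 0.05
    map_fdr: float = 0.01
    min_occurrence: float = 0.10
    seed: int = 0
    base_dir: str = "."

    def validate(self) -> None:
        checks = [
            ("min_fraction", 0.0, 1.0), ("min_homogeneity", -1.0, 1.0),
            ("enrich_p", 0.0, 1.0), ("enrich_q", 0.0, 1.0),
            ("map_p", 0.0, 1.0), ("map_fdr", 0.0, 1.0),
            ("min_occurrence", 0.0, 1.0),
        ]
        for name, lo, hi in checks:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"config: {name}={v} outside [{lo}, {hi}]")
        for name in ("min_count", "knn_k", "top_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"config: {name} must be >= 1")
        if self.meta_z_cut <= 0:
            raise ValueError("config: meta_z_cut must be positive")

    def path(self, p: str) -> Path:
        p = Path(p)
        return p if p.is_absolute() else Path(self.base_dir) / p

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d.pop("base_dir")
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        cfg = cls(**d, base_dir=str(Path(path).parent))
        cfg.validate()
        return cfg

    def content_hash(self) -> str:
        d = asdict(self)
        d.pop("base_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage record counts plus the warnings raised during the run."""

    config_hash: str
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# demo bundle

_MARGIN_LEVELS = ["smooth", "lobulated", "irregular", "spiculated", "poorly-defined"]
_GGO_LEVELS = ["0%", "1-20%", "21-40%", "41-60%", "61-80%", "81-100%"]


def _blocked_expression(n_samples, seed, sample_prefix):
    """Primary/validation expression: 10 tight blocks (rho=0.7), 4 loose
    blocks (rho=0.2), 60 noise genes; gene names shared across cohorts."""
    hi, truth_hi = simulate_expression(
        n_genes=260, n_samples=n_samples, n_blocks=10, block_size=20,
        rho=0.7, seed=seed, sample_prefix=sample_prefix,
    )
    lo, truth_lo = simulate_expression(
        n_genes=80, n_samples=n_samples, n_blocks=4, block_size=20,
        rho=0.2, seed=seed + 1, sample_prefix=sample_prefix,
    )
    lo = lo.rename(index=lambda g: f"lo_{g}")
    expr = pd.concat([hi, lo])
    membership = dict(truth_hi.block_memberships)
    for g, b in truth_lo.block_memberships.items():
        membership[f"lo_{g}"] = f"lo_{b}" if b else None
    return expr, membership


def _demo_metagenes(membership) -> list[Metagene]:
    blocks: dict[str, list[str]] = {}
    for g, b in membership.items():
        if b is not None:
            blocks.setdefault(b, []).append(g)
    # stable naming: metagene_1..10 are the tight blocks, 11..14 the loose ones
    names = [b for b in blocks if not b.startswith("lo_")]
    names.sort(key=lambda b: int(b[1:]))
    lo_names = sorted((b for b in blocks if b.startswith("lo_")), key=lambda b: int(b[4:]))
    out = []
    for i, b in enumerate(names + lo_names, start=1):
        out.append(Metagene(id=f"metagene_{i}", members=tuple(sorted(blocks[b]))))
    return out


def make_demo(outdir, seed: int = 0) -> PipelineConfig:
    """Write a complete synthetic study bundle plus its ground truth and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_patients = 113

    expr, membership = _blocked_expression(n_patients, seed * 1000 + 11, "pt")
    genes = list(expr.index)
    metagenes = _demo_metagenes(membership)
    hi_metagenes = metagenes[:10]

    # counts: every expression gene passes the low-count filter, 100 extras fail
    counts, labels = simulate_counts(
        n_genes=len(genes) + 100, n_samples=n_patients,
        expressed_fraction=len(genes) / (len(genes) + 100), seed=seed * 1000 + 12,
    )
    counts.index = genes + [f"unexpr_{i:03d}" for i in range(100)]
    counts.columns = expr.columns

    # FPKM on the natural scale; ~2% of entries zeroed -> missing after log
    fpkm = pd.DataFrame(
        np.exp2(expr.to_numpy()), index=expr.index, columns=expr.columns
    )
    masked, _ = inject_missing(fpkm, rate=0.02, seed=seed * 1000 + 13)
    fpkm = masked.fillna(0.0)

    validation = {}
    for v in range(5):
        vexpr, _ = _blocked_expression(200, seed * 1000 + 20 + v, f"v{v + 1}_")
        validation[f"val_{v + 1}"] = vexpr

    universe = genes
    gene_sets, gs_truth = simulate_gene_sets(
        universe=universe,
        metagenes=hi_metagenes,
        planted_overlaps=[(m.id, 15, 25) for m in hi_metagenes],
        n_random_sets=30,
        seed=seed * 1000 + 31,
    )

    adeno, truth_a = simulate_survival_cohorts(
        n_cohorts=6, n_per_cohort=150,
        betas={"metagene_1": 0.8, "metagene_2": -0.8},
        censor_rate=0.3, seed=seed * 1000 + 41,
        metagenes=hi_metagenes, histology_group="adenocarcinoma",
        cohort_prefix="adeno",
    )
    squam, truth_s = simulate_survival_cohorts(
        n_cohorts=5, n_per_cohort=150,
        betas={"metagene_3": -0.8},
        censor_rate=0.3, seed=seed * 1000 + 42,
        metagenes=hi_metagenes, histology_group="squamous",
        cohort_prefix="squam",
    )

    scores = metagene_scores(expr, hi_metagenes)
    planted_pairs = [
        ("solid_attenuation", "metagene_1", 2.0),
        ("poorly_defined_margin", "metagene_2", -2.0),
        ("ggo_proportion", "metagene_3", 2.0),
        ("margin_type", "metagene_4", 2.0),
        ("emphysema_present", "metagene_5", 2.0),
        ("reticulation", "metagene_6", -2.0),
    ]
    feature_specs = {
        "ggo_proportion": {"type": "ordinal", "levels": _GGO_LEVELS},
        "margin_type": {"type": "ordinal", "levels": _MARGIN_LEVELS},
    }
    # 29 informative null features + 52 rare ones that the 10% filter removes
    null_freqs = [0.3] * 29 + [0.04] * 52
    features, feat_truth = simulate_features(
        metagene_scores=scores,
        planted_pairs=planted_pairs,
        n_null_features=81,
        feature_specs=feature_specs,
        seed=seed * 1000 + 51,
        null_frequencies=null_freqs,
    )

    # --- write everything -------------------------------------------------
    rio.write_expression_tsv(counts, outdir / "counts.tsv")
    rio.write_expression_tsv(fpkm, outdir / "fpkm.tsv")
    rio.write_gmt([(m.id, "demo", list(m.members)) for m in metagenes], outdir / "metagenes.gmt")
    for cid, vexpr in validation.items():
        rio.write_expression_tsv(vexpr, outdir / f"{cid}.tsv")
    rio.write_gmt(
        [(name, gene_sets.source, sorted(s)) for name, s in gene_sets.sets.items()],
        outdir / "gene_sets.gmt",
    )
    surv_rows = []
    surv_expr_paths = {}
    for cohort in adeno + squam:
        for s, t, e in zip(cohort.sample_ids, cohort.times, cohort.events):
            surv_rows.append(
                {"sample": s, "time": t, "event": int(e),
                 "cohort": cohort.cohort_id, "histology_group": cohort.histology_group}
            )
        path = outdir / f"survexpr_{cohort.cohort_id}.tsv"
        rio.write_expression_tsv(cohort.expr, path)
        surv_expr_paths[cohort.cohort_id] = path.name
    rio.write_survival_csv(pd.DataFrame(surv_rows), outdir / "survival.csv")
    rio.write_features_csv(features.data, outdir / "features.csv")
    rio.write_codebook_csv(features.codebook, outdir / "codebook.csv")

    truth = GroundTruth(
        seed=seed,
        block_memberships=membership,
        planted_pairs=planted_pairs,
        hazard_betas={**truth_a.hazard_betas, **truth_s.hazard_betas},
        within_block_correlation=0.7,
    )
    truth.to_json(outdir / "ground_truth.json")

    cfg = PipelineConfig(
        counts="counts.tsv",
        fpkm="fpkm.tsv",
        metagenes_gmt="metagenes.gmt",
        validation_cohorts={cid: f"{cid}.tsv" for cid in validation},
        gene_sets_gmt="gene_sets.gmt",
        features="features.csv",
        codebook="codebook.csv",
        survival="survival.csv",
        survival_expr=surv_expr_paths,
        ground_truth="ground_truth.json",
        seed=seed,
        base_dir=str(outdir),
    )
    cfg.validate()
    cfg.to_yaml(outdir / "config.yaml")
    return cfg


# ---------------------------------------------------------------------------
# pipeline


def run_pipeline(config: PipelineConfig, outdir) -> RunReport:
    """Execute every stage from the configured input files.

    Writes per-stage tables under ``outdir`` and returns a RunReport whose
    counts reconcile with the written files. Deterministic: identical config
    and inputs give byte-identical outputs.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.content_hash())

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # -- preprocess ----------------------------------------------------
        logger.info("stage 1/5: preprocess")
        counts = rio.read_expression_tsv(config.path(config.counts))
        filtered, kept = filter_low_count_transcripts(
            counts, config.min_count, config.min_fraction
        )
        report.counts["genes_input"] = int(counts.shape[0])
        report.counts["genes_kept"] = len(kept)

        fpkm = rio.read_expression_tsv(config.path(config.fpkm))
        fpkm = fpkm.loc[[g for g in kept if g in fpkm.index]]
        logged = log_transform(fpkm, pseudocount=config.pseudocount)
        imputed = knn_impute(logged, k=config.knn_k) if logged.isna().any().any() else logged
        rio.write_expression_tsv(imputed, outdir / "expression_log_imputed.tsv")
        standardized = standardize_genes(imputed)
        rio.write_expression_tsv(standardized, outdir / "expression_standardized.tsv")

        # -- metagenes -----------------------------------------------------
        logger.info("stage 2/5: metagene homogeneity and selection")
        metagenes = load_metagenes(config.path(config.metagenes_gmt))
        cohorts = {"primary": imputed}
        for cid, path in config.validation_cohorts.items():
            cohorts[cid] = rio.read_expression_tsv(config.path(path))
        homog = cross_cohort_homogeneity(metagenes, cohorts, primary_id="primary")
        homog.to_csv(outdir / "homogeneity.csv")
        selected = select_top_metagenes(
            homog, metagenes, top_n=config.top_n, min_avg=config.min_homogeneity
        )
        rio.write_gmt(
            [(m.id, "selected", list(m.members)) for m in selected],
            outdir / "metagenes_selected.gmt",
        )
        report.counts["metagenes_input"] = len(metagenes)
        report.counts["metagenes_selected"] = len(selected)

        # -- enrichment ----------------------------------------------------
        logger.info("stage 3/5: functional enrichment")
        db = GeneSetDatabase.from_gmt(config.path(config.gene_sets_gmt))
        enr = MetageneEnrichment(selected, db, universe=list(imputed.index)).fit(
            p_thresh=config.enrich_p, q_thresh=config.enrich_q
        )
        enr.table.to_csv(outdir / "enrichment.csv", index=False)
        report.counts["enrichment_pairs_tested"] = int(len(enr.table))
        report.counts["enrichment_significant"] = enr.n_significant

        # -- prognosis -----------------------------------------------------
        logger.info("stage 4/5: survival meta-analysis")
        surv = rio.read_survival_csv(config.path(config.survival))
        cohort_objs = []
        for cid, sub in surv.groupby("cohort", sort=False):
            expr_c = rio.read_expression_tsv(config.path(config.survival_expr[cid]))
            sub = sub.set_index("sample").loc[list(expr_c.columns)]
            cohort_objs.append(
                SurvivalCohort(
                    cohort_id=str(cid),
                    histology_group=str(sub["histology_group"].iloc[0]),
                    times=sub["time"].to_numpy(),
                    events=sub["event"].to_numpy(),
                    expr=expr_c,
                )
            )
        prog = MetagenePrognosis(selected, cohort_objs).fit(meta_z_cut=config.meta_z_cut)
        prog.wide_table().to_csv(outdir / "prognosis.csv", index=False)
        report.counts["survival_cohorts"] = len(cohort_objs)
        report.counts["prognosis_significant"] = int(
            (prog.table["call"] != "not-significant").sum()
        )

        # -- association map -------------------------------------------------
        logger.info("stage 5/5: radiogenomic association map")
        codebook = rio.read_codebook_csv(config.path(config.codebook))
        feat_df = rio.read_features_csv(config.path(config.features), codebook)
        table = SemanticFeatureTable(data=feat_df, codebook=codebook)
        scores = metagene_scores(imputed, selected)
        amap = AssociationMap(scores, table).fit(
            p_thresh=config.map_p,
            fdr_thresh=config.map_fdr,
            min_occurrence=config.min_occurrence,
        ).order_map()
        amap.records.to_csv(outdir / "associations.csv", index=False)
        amap.p_matrix().loc[amap.row_order, amap.col_order].to_csv(outdir / "map_matrix.csv")
        report.counts["features_input"] = int(feat_df.shape[1])
        report.counts["features_retained"] = len(amap.feature_ids)
        report.counts["associations_tested"] = amap.n_tested
        report.counts["associations_significant"] = amap.n_significant

        # -- planted-truth reconciliation (when ground truth travels along)
        if config.ground_truth:
            truth = GroundTruth.from_json(config.path(config.ground_truth))
            sig = set(
                zip(amap.significant()["feature_id"], amap.significant()["metagene_id"])
            )
            planted = {(f, m) for f, m, _d in truth.planted_pairs}
            report.counts["planted_pairs"] = len(planted)
            report.counts["planted_pairs_recovered"] = len(planted & sig)
            report.counts["false_positive_associations"] = len(sig - planted)

    report.warnings = sorted({str(w.message) for w in caught})
    config.to_yaml(outdir / "config_used.yaml")
    report.to_json(outdir / "run_report.json")
    return report
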