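"""End-to-end orchestration of the four-way stratification comparison.

Given (or simulating) a multi-site case-control cohort, the pipeline runs:

1. full-data PCA and control-only PCA, outlier flagging (union of both
   models) and removal;
2. on the cleaned cohort: full PCA, AIMs-panel-only PCA, control-only PCA
   with projection of all samples, loading-peak detection, region thinning
   and LD-thinned PCA;
3. per-SNP logistic scans under each configured PC-correction set, genomic
   inflation factors, PC ~ site + disease regressions, PC cross-correlation
   tables, p-value correlations between corrections and top-hit retention.

Everything is deterministic given the configuration (and its seed when
simulating).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry as anc_mod
from . import assoc, pca, qc, sim
from .data import GenotypeMatrix

logger = logging.getLogger(__name__)

VARIANTS = ("full", "panel", "control", "thinned")


@dataclass
class PipelineConfig:
    sim_config: sim.SimConfig | None = None
    plink_prefix: str | None = None
    metadata_path: str | None = None
    panel_snp_file: str | None = None  # AIMs SNP id list for real inputs
    k: int = 10
    outlier_threshold: float = 6.0
    outlier_rounds: int = 1
    peak_c: float = 6.0
    peak_min_run: int = 10
    peak_gap: int = 50
    trim_fraction: float = 0.1
    # each entry: (variant, tuple of 1-based PC numbers); () is handled as uncorrected
    correction_sets: tuple[tuple[str, tuple[int, ...]], ...] = (
        ("full", (1,)),
        ("full", (1, 2, 3, 4)),
        ("control", (1, 2, 3, 4)),
        ("panel", (1,)),
        ("thinned", (1, 2, 3, 4)),
    )
    reference_site: str | None = None
    n_top_hits: int = 20
    run_ancestry: bool = True

    def __post_init__(self) -> None:
        if self.sim_config is None and self.plink_prefix is None:
            raise ValueError("need either a sim_config or a plink_prefix")
        for variant, pcs in self.correction_sets:
            if variant not in VARIANTS:
                raise ValueError(f"unknown PCA variant {variant!r}")
            if any(not 1 <= p <= self.k for p in pcs):
                raise ValueError("correction PCs must lie in 1..k")

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class ComparisonReport:
    config_hash: str
    n_samples_initial: int
    n_samples_final: int
    outlier_audit: list[dict]
    eigenvalues: dict[str, np.ndarray]
    scores: dict[str, pd.DataFrame]          # per variant; "control" holds projected scores
    loadings_track: pd.DataFrame             # snp_id, chromosome, position, PC loadings (full)
    regions: pd.DataFrame
    lambda_table: pd.DataFrame               # correction label -> lambda
    pc_site_regression: pd.DataFrame
    pc_correlations: dict[str, pd.DataFrame]  # variant vs full
    pvalue_correlations: pd.DataFrame
    top_hits: dict[str, pd.DataFrame]
    scans: dict[str, assoc.AssociationScan] = field(default_factory=dict)
    ancestry_estimates: pd.DataFrame | None = None
    truth: sim.SimTruth | None = None


def _load_inputs(config: PipelineConfig):
    from . import io as gio

    if config.sim_config is not None:
        genotypes, truth = sim.simulate_dataset(config.sim_config)
        aims = sim.select_aims(truth, config.sim_config.aims_count)
        return genotypes, truth, aims
    genotypes = gio.read_plink(config.plink_prefix)
    if config.metadata_path:
        meta = gio.read_metadata(config.metadata_path, genotypes)
        genotypes.samples = meta
    aims = None
    if config.panel_snp_file:
        wanted = [l.strip() for l in Path(config.panel_snp_file).read_text().split() if l.strip()]
        present = [s for s in wanted if s in set(genotypes.snp_ids)]
        logger.info("AIMs panel: %d of %d listed SNPs available", len(present), len(wanted))
        aims = present
    return genotypes, None, aims


def run_pipeline(config: PipelineConfig) -> ComparisonReport:
    genotypes, truth, aims = _load_inputs(config)
    n_initial = genotypes.n_samples
    logger.info("stage load: %d samples x %d SNPs", n_initial, genotypes.n_snps)

    # ---- outlier pass: union of full-data and control-only flags ---------
    full0 = pca.fit_pca(genotypes, k=config.k)
    controls0 = genotypes.subset_samples(genotypes.status_vector() == 0)
    control0 = pca.fit_pca(controls0, k=config.k)
    flagged = sorted(
        set(qc.flag_outliers(full0, k=min(config.k, full0.k), threshold=config.outlier_threshold))
        | set(qc.flag_outliers(control0, k=min(config.k, control0.k), threshold=config.outlier_threshold))
    )
    genotypes, audit = qc.remove_and_recompute(
        genotypes, flagged, rounds=config.outlier_rounds,
        k=config.k, threshold=config.outlier_threshold,
    )
    logger.info("stage outliers: removed %d, %d samples remain",
                n_initial - genotypes.n_samples, genotypes.n_samples)
    if truth is not None:
        keep = np.isin(truth_sample_ids(truth, n_initial), genotypes.sample_ids.astype(str))
        truth = _subset_truth(truth, keep)

    # ---- PCA variants ----------------------------------------------------
    models: dict[str, pca.PCAModel] = {}
    scores: dict[str, pd.DataFrame] = {}
    models["full"] = pca.fit_pca(genotypes, k=config.k)
    scores["full"] = models["full"].scores_frame()

    if aims:
        panel_geno = genotypes.subset_snps(np.asarray(aims))
        models["panel"] = pca.fit_pca(panel_geno, k=min(config.k, len(aims) - 1))
        scores["panel"] = models["panel"].scores_frame()

    controls = genotypes.subset_samples(genotypes.status_vector() == 0)
    models["control"] = pca.fit_pca(controls, k=config.k)
    scores["control"] = pca.project(genotypes, models["control"])

    snp_map_full = genotypes.snps.set_index("id").loc[models["full"].snp_ids].reset_index().rename(
        columns={"index": "id"}
    )
    regions = qc.detect_peaks_all_components(
        models["full"], snp_map_full, components=range(1, min(4, models["full"].k) + 1),
        c=config.peak_c, min_run=config.peak_min_run, gap=config.peak_gap,
    )
    logger.info("stage peaks: %d loading-peak regions", len(regions))
    thinned_geno = qc.thin_regions(genotypes, regions)
    models["thinned"] = pca.fit_pca(thinned_geno, k=config.k)
    scores["thinned"] = models["thinned"].scores_frame()

    # ---- association scans ----------------------------------------------
    scans: dict[str, assoc.AssociationScan] = {}
    scans["uncorrected"] = assoc.logistic_snp_scan(genotypes, covariate_label="uncorrected")
    for variant, pcs in config.correction_sets:
        if variant not in scores:
            logger.warning("skipping correction set on unavailable variant %r", variant)
            continue
        label = f"{variant}:PC{'+PC'.join(map(str, pcs))}"
        cov = scores[variant][[f"PC{i}" for i in pcs]].to_numpy()
        scans[label] = assoc.logistic_snp_scan(genotypes, covariates=cov, covariate_label=label)
    logger.info("stage scans: %d correction sets", len(scans))

    lambda_rows = [
        {
            "correction": label,
            "lambda": assoc.inflation_factor(s.chisq(), config.trim_fraction).lam,
            "n_tested": int((s.table["flag"] == "ok").sum()),
        }
        for label, s in scans.items()
    ]
    lambda_table = pd.DataFrame(lambda_rows)

    # ---- comparisons -----------------------------------------------------
    site = genotypes.samples["site"].to_numpy()
    status = genotypes.samples["status"].to_numpy()
    pc_site = assoc.pc_regression(scores["full"], site, status, config.reference_site)

    pc_correlations = {
        v: pca.pc_correlation_table(scores[v], scores["full"]) for v in scores if v != "full"
    }

    labels = list(scans)
    pv_rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            pv_rows.append(
                {"scan_a": a, "scan_b": b, "pearson_r": assoc.pvalue_correlation(scans[a], scans[b])}
            )
    pvalue_correlations = pd.DataFrame(pv_rows)

    top_hits = {}
    corrected = [l for l in labels if l != "uncorrected"]
    for a, b in zip(corrected, corrected[1:]):
        top_hits[f"{a} vs {b}"] = assoc.top_hits_comparison(
            scans[a], scans[b], n_top=min(config.n_top_hits, len(scans[a].tested))
        )

    # ---- ancestry MLE on the simulated panel -----------------------------
    ancestry_estimates = None
    if config.run_ancestry and truth is not None and aims:
        panel = anc_mod.panel_from_truth(truth, list(aims))
        ancestry_estimates = anc_mod.estimate_cohort(genotypes, panel)

    loadings_track = models["full"].loadings_frame().merge(
        genotypes.snps.rename(columns={"id": "snp_id"})[["snp_id", "chromosome", "position"]],
        on="snp_id",
    )

    return ComparisonReport(
        config_hash=config.config_hash(),
        n_samples_initial=n_initial,
        n_samples_final=genotypes.n_samples,
        outlier_audit=audit,
        eigenvalues={v: m.eigenvalues for v, m in models.items()},
        scores=scores,
        loadings_track=loadings_track,
        regions=qc.regions_frame(regions),
        lambda_table=lambda_table,
        pc_site_regression=pc_site,
        pc_correlations=pc_correlations,
        pvalue_correlations=pvalue_correlations,
        top_hits=top_hits,
        scans=scans,
        ancestry_estimates=ancestry_estimates,
        truth=truth,
    )


def truth_sample_ids(truth: sim.SimTruth, n: int) -> np.ndarray:
    return np.array([f"S{i:05d}" for i in range(n)])


def _subset_truth(truth: sim.SimTruth, keep: np.ndarray) -> sim.SimTruth:
    out = dataclasses.replace(truth)
    out.ancestry = truth.ancestry[keep]
    out.site = truth.site[keep]
    out.status = truth.status[keep] if truth.status is not None else None
    out.block_latents = {s: v[keep] for s, v in truth.block_latents.items()}
    return out


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def render_report(report: ComparisonReport, outdir: str | Path) -> None:
    """Write the report's tables as TSV plus a JSON summary.

    Emits: pcs_<variant>.tsv, eigenvalues.tsv (scree data),
    loadings.tsv (loadings-by-position track), regions.tsv, lambda.json,
    scan_<set>.tsv, pc_regression.tsv, pc_correlation_<variant>.tsv,
    pvalue_correlations.tsv, top_hits_<pair>.tsv, ancestry.tsv, report.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for variant, frame in report.scores.items():
        frame.to_csv(outdir / f"pcs_{variant}.tsv", sep="\t", index=False)
    scree = pd.DataFrame(
        [
            {"variant": v, "component": i + 1, "eigenvalue": float(val)}
            for v, vals in report.eigenvalues.items()
            for i, val in enumerate(vals)
        ]
    )
    scree.to_csv(outdir / "eigenvalues.tsv", sep="\t", index=False)
    report.loadings_track.to_csv(outdir / "loadings.tsv", sep="\t", index=False)
    with open(outdir / "regions.tsv", "w") as fh:
        fh.write("# coordinates are 1-based inclusive bp at the bracketing SNPs\n")
        report.regions.to_csv(fh, sep="\t", index=False)
    lambda_payload = {
        "config_hash": report.config_hash,
        "trim_fraction_expected_mean": None,
        "rows": report.lambda_table.to_dict(orient="records"),
    }
    (outdir / "lambda.json").write_text(json.dumps(lambda_payload, indent=2, sort_keys=True))
    for label, scan in report.scans.items():
        safe = label.replace(":", "_").replace("+", "-")
        scan.table.to_csv(outdir / f"scan_{safe}.tsv", sep="\t", index=False)
    report.pc_site_regression.to_csv(outdir / "pc_regression.tsv", sep="\t", index=False)
    for variant, table in report.pc_correlations.items():
        table.to_csv(outdir / f"pc_correlation_{variant}.tsv", sep="\t")
    report.pvalue_correlations.to_csv(outdir / "pvalue_correlations.tsv", sep="\t", index=False)
    for pair, table in report.top_hits.items():
        safe = pair.replace(":", "_").replace(" ", "_").replace("+", "-")
        table.to_csv(outdir / f"top_hits_{safe}.tsv", sep="\t", index=False)
    if report.ancestry_estimates is not None:
        report.ancestry_estimates.to_csv(outdir / "ancestry.tsv", sep="\t", index=False)
    summary = {
        "config_hash": report.config_hash,
        "n_samples_initial": report.n_samples_initial,
        "n_samples_final": report.n_samples_final,
        "outlier_audit": report.outlier_audit,
        "n_regions": int(len(report.regions)),
        "lambda": report.lambda_table.to_dict(orient="records"),
        "pvalue_correlations": report.pvalue_correlations.to_dict(orient="records"),
    }
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
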