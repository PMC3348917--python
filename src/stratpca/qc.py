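"""Structure QC: PC-score outlier removal and loading-peak (LD region)
detection and thinning.

A principal component driven by a single high-LD region rather than by
genome-wide ancestry shows up as a localized "peak" in its per-SNP loadings
track.  Peak detection here is an automated operationalization of the visual
bracketing procedure: runs of consecutive SNPs whose absolute loading
exceeds a robust threshold are merged and reported as regions, each of which
is then thinned to its single most extreme SNP before PCA is recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GenotypeMatrix
from .pca import PCAModel, fit_pca

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Outliers
# ---------------------------------------------------------------------------

def flag_outliers(model: PCAModel, k: int = 10, threshold: float = 6.0) -> list[str]:
    """Samples more than ``threshold`` SDs from the mean score on any of the
    first ``k`` components.  Mean and SD are computed over all samples in the
    model; invariant to component sign flips and sample order."""
    if k > model.k:
        raise ValueError(f"requested k={k} but model has {model.k} components")
    s = model.scores[:, :k]
    mean = s.mean(axis=0)
    sd = s.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs(s - mean) / sd
    z = np.where(sd == 0, 0.0, z)
    flagged = (z > threshold).any(axis=1)
    return [str(i) for i in model.sample_ids[flagged]]


def remove_and_recompute(
    genotypes: GenotypeMatrix,
    flagged: list[str] | None = None,
    rounds: int = 1,
    k: int = 10,
    threshold: float = 6.0,
    scale: bool = True,
) -> tuple[GenotypeMatrix, list[dict]]:
    """Remove flagged samples; optionally re-fit PCA and repeat.

    If ``flagged`` is None the first round flags from a fresh PCA fit.  Each
    round's removals are recorded in the audit log; iteration stops when a
    round flags nothing or the round limit is reached.
    """
    audit: list[dict] = []
    current = genotypes
    for rnd in range(1, rounds + 1):
        if rnd == 1 and flagged is not None:
            ids = list(flagged)
            unknown = set(ids) - set(map(str, current.sample_ids))
            if unknown:
                raise ValueError(f"flagged ids not in dataset: {sorted(unknown)[:5]}")
        else:
            model = fit_pca(current, k=k, scale=scale)
            ids = flag_outliers(model, k=min(k, model.k), threshold=threshold)
        audit.append({"round": rnd, "removed": ids, "n_before": current.n_samples})
        if not ids:
            break
        keep = ~np.isin(current.sample_ids.astype(str), ids)
        current = current.subset_samples(keep)
        _warn_empty_strata(current)
    return current, audit


def _warn_empty_strata(genotypes: GenotypeMatrix) -> None:
    if {"site", "status"}.issubset(genotypes.samples.columns):
        counts = genotypes.samples.groupby(["site", "status"], observed=True).size()
        if (counts == 0).any():  # pragma: no cover - defensive
            logger.warning("outlier removal emptied a site x status stratum")


# ---------------------------------------------------------------------------
# Loading peaks
# ---------------------------------------------------------------------------

@dataclass
class LDRegion:
    """A contiguous loading-peak interval flagged on one component.

    Coordinates are 1-based inclusive base pairs at the bracketing SNPs'
    positions; ``n_snps`` counts every SNP inside the interval and
    ``retained_snp_id`` is the single SNP kept when the region is thinned.
    """

    chromosome: str
    start_bp: int
    end_bp: int
    bracket_snp_ids: tuple[str, str]
    n_snps: int
    retained_snp_id: str
    peak_loading: float
    component: int
    snp_indices: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise ValueError("end_bp must exceed start_bp")
        if self.n_snps < 1:
            raise ValueError("region must contain at least one SNP")


def region_density(region: LDRegion) -> float:
    """Region span in kilobases per SNP: (end - start)/1000/n_snps."""
    if region.n_snps == 0:
        raise ValueError("region has no SNPs")
    return (region.end_bp - region.start_bp) / 1000.0 / region.n_snps


def detect_loading_peaks(
    model: PCAModel,
    snp_map: pd.DataFrame,
    component: int,
    c: float = 6.0,
    min_run: int = 10,
    gap: int = 50,
) -> list[LDRegion]:
    """Find loading peaks on one component (1-based).

    A SNP exceeds when |loading| > c * robust SD (1.4826 * MAD) of the
    component's loadings.  Maximal runs of exceeding SNPs on the same
    chromosome are merged when separated by fewer than ``gap`` non-exceeding
    SNPs; merged regions with fewer than ``min_run`` exceeding SNPs are
    discarded.  The region interval spans from the first to the last
    exceeding SNP (the "bracket" SNPs) and every SNP in between counts
    toward ``n_snps``.
    """
    if not 1 <= component <= model.k:
        raise ValueError(f"component {component} out of range 1..{model.k}")
    snp_map = snp_map.reset_index(drop=True)
    if len(snp_map) != model.loadings.shape[0]:
        raise ValueError("SNP map length does not match loadings")
    load = model.loadings[:, component - 1]
    med = np.median(load)
    robust_sd = 1.4826 * np.median(np.abs(load - med))
    if robust_sd == 0:
        robust_sd = load.std() or 1.0
    exceed = np.abs(load) > c * robust_sd

    regions: list[LDRegion] = []
    chroms = snp_map["chromosome"].to_numpy()
    pos = snp_map["position"].to_numpy()
    ids = snp_map["id"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        hits = idx[exceed[idx]]
        if hits.size == 0:
            continue
        # cluster hit indices separated by < gap map positions
        breaks = np.flatnonzero(np.diff(hits) >= gap)
        clusters = np.split(hits, breaks + 1)
        for cl in clusters:
            if cl.size < min_run:
                continue
            lo, hi = int(cl[0]), int(cl[-1])
            span = np.arange(lo, hi + 1)
            peak = span[np.argmax(np.abs(load[span]))]
            regions.append(
                LDRegion(
                    chromosome=str(chrom),
                    start_bp=int(pos[lo]),
                    end_bp=int(pos[hi]),
                    bracket_snp_ids=(str(ids[lo]), str(ids[hi])),
                    n_snps=len(span),
                    retained_snp_id=str(ids[peak]),
                    peak_loading=float(load[peak]),
                    component=component,
                    snp_indices=span,
                )
            )
    return regions


def detect_peaks_all_components(
    model: PCAModel, snp_map: pd.DataFrame, components: range | list[int] | None = None, **kw
) -> list[LDRegion]:
    """Union of per-component peak regions, merged on genomic overlap.

    When regions found on different components overlap, the one with the
    larger |peak loading| is kept.
    """
    components = components if components is not None else range(1, model.k + 1)
    found: list[LDRegion] = []
    for comp in components:
        found.extend(detect_loading_peaks(model, snp_map, comp, **kw))
    found.sort(key=lambda r: -abs(r.peak_loading))
    merged: list[LDRegion] = []
    for region in found:
        if not any(_overlaps(region, m) for m in merged):
            merged.append(region)
    merged.sort(key=lambda r: (r.chromosome, r.start_bp))
    return merged


def _overlaps(a: LDRegion, b: LDRegion) -> bool:
    return a.chromosome == b.chromosome and a.start_bp <= b.end_bp and b.start_bp <= a.end_bp


def thin_regions(genotypes: GenotypeMatrix, regions: list[LDRegion]) -> GenotypeMatrix:
    """Drop every SNP inside each region except its retained SNP."""
    if not regions:
        return genotypes
    drop = np.zeros(genotypes.n_snps, dtype=bool)
    claimed = np.zeros(genotypes.n_snps, dtype=bool)
    pos = genotypes.snps["position"].to_numpy()
    chroms = genotypes.snps["chromosome"].to_numpy()
    ids = genotypes.snps["id"].to_numpy()
    for region in regions:
        inside = (
            (chroms == region.chromosome)
            & (pos >= region.start_bp)
            & (pos <= region.end_bp)
        )
        if (claimed & inside).any():
            raise ValueError("overlapping LD regions")
        claimed |= inside
        keep_one = inside & (ids == region.retained_snp_id)
        if not keep_one.any():
            raise ValueError(f"retained SNP {region.retained_snp_id} not inside its region")
        drop |= inside & ~keep_one
    return genotypes.subset_snps(~drop)


def regions_frame(regions: list[LDRegion]) -> pd.DataFrame:
    """Tabular (Table-4-shaped) view of detected regions."""
    return pd.DataFrame(
        {
            "chromosome": [r.chromosome for r in regions],
            "start_bp": [r.start_bp for r in regions],
            "end_bp": [r.end_bp for r in regions],
            "bracket_first": [r.bracket_snp_ids[0] for r in regions],
            "bracket_last": [r.bracket_snp_ids[1] for r in regions],
            "n_snps": [r.n_snps for r in regions],
            "retained_snp": [r.retained_snp_id for r in regions],
            "component": [r.component for r in regions],
            "density_kb_per_snp": [round(region_density(r), 2) for r in regions],
        }
    )


def write_regions(regions: list[LDRegion], path) -> None:
    frame = regions_frame(regions)
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive bp at the bracketing SNPs\n")
        frame.to_csv(fh, sep="\t", index=False)
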