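"""Synthetic multi-site case-control cohorts with European-American-style
substructure.

The generator realises the statistical structure the stratification pipeline
assumes, with full ground truth, so every downstream stage is testable
without external data:

* two ancestral populations differentiated by a Balding-Nichols model at a
  configurable FST, mixed along one dominant cline (each individual carries
  an ancestry proportion in [0, 1], interpreted as its share of the
  "southeastern" population);
* several study sites whose ancestry-proportion distributions differ
  (site-specific Beta distributions on the cline), creating PC-site
  associations;
* localized high-LD blocks of three kinds: a cline-correlated block (LCT
  gene-like), a locally structured block uncorrelated with genome-wide
  ancestry (HLA-like) and a common-inversion-like block whose latent variable
  is a three-level Hardy-Weinberg genotype;
* case/control labels confounded with ancestry through a logistic disease
  model, optionally with truly causal SNPs;
* a small ancestry-informative-marker (AIMs) subset emulating a pre-designed
  panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data import MISSING, GenotypeMatrix


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LDBlockSpec:
    """A contiguous run of SNP-map indices regenerated from one latent variable.

    ``start_index``/``end_index`` are half-open map indices ``[start, end)``.
    ``kind`` is one of ``cline_linked`` (latent allele frequency tracks the
    ancestry cline), ``local_only`` (latent independent of ancestry) or
    ``inversion_like`` (latent is the Hardy-Weinberg genotype of an
    "inversion allele").  ``copy_fidelity`` is the per-allele probability
    that a block SNP copies the latent haplotype.
    """

    start_index: int
    end_index: int
    kind: str
    copy_fidelity: float = 0.95
    latent_freq: float | None = None  # local_only/inversion_like allele frequency

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ConfigurationError("block end_index must exceed start_index")
        if self.kind not in ("cline_linked", "local_only", "inversion_like"):
            raise ConfigurationError(f"unknown block kind {self.kind!r}")
        if not 0.5 < self.copy_fidelity <= 1.0:
            raise ConfigurationError("copy_fidelity must lie in (0.5, 1]")

    @property
    def n_snps(self) -> int:
        return self.end_index - self.start_index


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease model: logit P(case) = c_site + beta_ancestry * a + sum(beta_j * g_j)."""

    beta_ancestry: float = 2.0
    causal_effects: dict[int, float] = field(default_factory=dict)  # snp index -> log-OR


@dataclass(frozen=True)
class SimConfig:
    """Full description of a simulated cohort; the seed determines everything."""

    n_per_site: tuple[int, ...] = (500, 500, 500, 500)
    n_snps: int = 5000
    fst: float = 0.01
    site_names: tuple[str, ...] = ("MAYO", "NCO", "TBO", "TOR")
    # per-site (mean, concentration) of the Beta ancestry distribution:
    # MAYO least southeastern ancestry, TBO most, NCO/TOR intermediate
    cline_site_params: tuple[tuple[float, float], ...] = (
        (0.10, 8.0), (0.35, 8.0), (0.70, 8.0), (0.40, 8.0)
    )
    ld_blocks: tuple[LDBlockSpec, ...] = ()
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    # scalar, or one target case fraction per site (unequal recruitment of
    # cases vs controls across sites is itself a stratification confounder)
    case_fraction_per_site: float | tuple[float, ...] = 0.5
    aims_count: int = 500
    missing_rate: float = 0.001
    n_chromosomes: int = 10
    snp_spacing_bp: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_site) != len(self.site_names) or len(self.site_names) != len(
            self.cline_site_params
        ):
            raise ConfigurationError("n_per_site, site_names and cline_site_params must align")
        if any(n <= 0 for n in self.n_per_site) or self.n_snps <= 0:
            raise ConfigurationError("counts must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ConfigurationError("fst must lie in [0, 1)")
        fracs = (
            (self.case_fraction_per_site,)
            if np.isscalar(self.case_fraction_per_site)
            else tuple(self.case_fraction_per_site)
        )
        if not np.isscalar(self.case_fraction_per_site) and len(fracs) != len(self.site_names):
            raise ConfigurationError("per-site case fractions must align with site_names")
        if any(not 0.0 < f < 1.0 for f in fracs):
            raise ConfigurationError("case_fraction_per_site must lie in (0, 1)")
        for mean, conc in self.cline_site_params:
            if not (0.0 < mean < 1.0 and conc > 0):
                raise ConfigurationError("cline params need mean in (0,1), concentration > 0")
        for b in self.ld_blocks:
            if b.end_index > self.n_snps:
                raise ConfigurationError("LD block exceeds SNP map")
        spans = sorted((b.start_index, b.end_index) for b in self.ld_blocks)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ConfigurationError("LD blocks overlap")

    @property
    def n_samples(self) -> int:
        return sum(self.n_per_site)


def headline_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study conditions: 4 sites x 500 samples, 5000 SNPs over 10
    synthetic chromosomes at FST 0.01, ancestry-confounded disease and three
    LD blocks (cline-linked on chromosome 2, local-only on chromosome 6,
    inversion-like on chromosome 8).

    Block widths are chosen proportional to the marker fractions the paper
    scale implies (a few tenths of a percent of the map) so that their
    eigenvalues fall between the random-matrix bulk and the cline component,
    reproducing the ranking in which localized LD drives middle components
    while the cline leads.  Case fractions differ across sites in step with
    site ancestry, so unequal recruitment confounds ancestry with disease.
    """
    blocks = (
        LDBlockSpec(700, 720, "cline_linked", 0.8),        # chromosome "2"
        LDBlockSpec(2700, 2720, "local_only", 0.8),        # chromosome "6"
        LDBlockSpec(3700, 3715, "inversion_like", 0.8),    # chromosome "8"
    )
    cfg = SimConfig(
        ld_blocks=blocks,
        case_fraction_per_site=(0.35, 0.50, 0.65, 0.50),
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Everything the generator knows that an analyst would not."""

    ancestry: np.ndarray            # per-sample cline proportion in [0, 1]
    site: np.ndarray                # per-sample site label
    status: np.ndarray | None       # per-sample "case"/"control" (None until assigned)
    ancestral_freq: np.ndarray      # per-SNP ancestral allele frequency
    pop_freqs: np.ndarray           # (P, 2) population allele frequencies
    blocks: tuple[LDBlockSpec, ...]
    block_latents: dict[int, np.ndarray]  # block start_index -> latent dosage per sample
    flipped: np.ndarray             # per-SNP bool: dosage reported as 2 - d
    causal_snp_ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _rng(config: SimConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, _STAGES[stage])))


_STAGES = {"ancestry": 0, "genotypes": 1, "blocks": 2, "status": 3, "missing": 4}


def simulate_ancestry(config: SimConfig) -> pd.DataFrame:
    """Draw per-sample site labels and cline ancestry proportions.

    Each site's ancestry distribution is Beta(mean*conc, (1-mean)*conc); the
    proportion is the individual's share of the second ("southeastern")
    ancestral population.
    """
    rng = _rng(config, "ancestry")
    sites, anc = [], []
    for name, n, (mean, conc) in zip(config.site_names, config.n_per_site, config.cline_site_params):
        sites.extend([name] * n)
        anc.append(rng.beta(mean * conc, (1.0 - mean) * conc, size=n))
    ancestry = np.concatenate(anc)
    ids = [f"S{i:05d}" for i in range(config.n_samples)]
    return pd.DataFrame({"id": ids, "site": sites, "ancestry": ancestry})


def simulate_genotypes(ancestry: pd.DataFrame, config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw background genotypes under the Balding-Nichols model.

    Per SNP an ancestral frequency p ~ Uniform(0.05, 0.95) is drawn and two
    population frequencies from Beta(p(1-F)/F, (1-p)(1-F)/F); an individual's
    expected frequency is the ancestry-weighted mixture and its dosage is
    Binomial(2, q).  F=0 degenerates to both populations sharing p.
    """
    a = np.asarray(ancestry["ancestry"], dtype=float)
    if ((a < 0) | (a > 1)).any():
        raise ConfigurationError("ancestry proportions must lie in [0, 1]")
    rng = _rng(config, "genotypes")
    p_anc = rng.uniform(0.05, 0.95, size=config.n_snps)
    if config.fst == 0.0:
        pop_freqs = np.stack([p_anc, p_anc], axis=1)
    else:
        shape = (1.0 - config.fst) / config.fst
        pop_freqs = np.stack(
            [rng.beta(p_anc * shape, (1.0 - p_anc) * shape) for _ in range(2)], axis=1
        )
    q = np.outer(1.0 - a, pop_freqs[:, 0]) + np.outer(a, pop_freqs[:, 1])
    dosages = rng.binomial(2, q).astype(np.int8)

    snps = _snp_map(config)
    samples = ancestry[["id", "site"]].copy()
    genotypes = GenotypeMatrix(dosages, snps, samples)
    truth = SimTruth(
        ancestry=a,
        site=ancestry["site"].to_numpy(),
        status=None,
        ancestral_freq=p_anc,
        pop_freqs=pop_freqs,
        blocks=config.ld_blocks,
        block_latents={},
        flipped=np.zeros(config.n_snps, dtype=bool),
    )
    return genotypes, truth


def _snp_map(config: SimConfig) -> pd.DataFrame:
    per_chrom = int(np.ceil(config.n_snps / config.n_chromosomes))
    idx = np.arange(config.n_snps)
    chrom = (idx // per_chrom + 1).astype(str)
    pos = (idx % per_chrom + 1) * config.snp_spacing_bp
    return pd.DataFrame(
        {
            "id": [f"snp{i:06d}" for i in idx],
            "chromosome": chrom,
            "position": pos,
            "allele1": "A",
            "allele2": "B",
        }
    )


def inject_ld_block(
    genotypes: GenotypeMatrix,
    spec: LDBlockSpec,
    ancestry: np.ndarray,
    truth: SimTruth | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Regenerate the dosages of one SNP block from a shared latent variable.

    Each sample carries two latent haplotype alleles; every block SNP copies
    each latent allele with probability ``copy_fidelity``, otherwise draws an
    independent allele at the latent frequency.  Half of the block SNPs
    (chosen at random) are reported allele-flipped (dosage 2-d) so blocks are
    not trivially detectable from allele frequencies.
    """
    if spec.end_index > genotypes.n_snps:
        raise ConfigurationError("block interval outside SNP map")
    rng = rng or np.random.default_rng(0)
    a = np.asarray(ancestry, dtype=float)
    n = genotypes.n_samples

    if spec.kind == "cline_linked":
        # LCT-like: frequency ~0.80 at the northern end of the cline, ~0.05 at
        # the southeastern end (the lactase-persistence differential)
        freq = np.clip(0.80 - 0.75 * a, 0.01, 0.99)
    else:
        f0 = spec.latent_freq if spec.latent_freq is not None else (
            0.30 if spec.kind == "local_only" else 0.45
        )
        freq = np.full(n, f0)

    latent_alleles = (rng.random((n, 2)) < freq[:, None]).astype(np.int8)
    latent = latent_alleles.sum(axis=1)

    mean_freq = float(freq.mean())
    m = spec.n_snps
    copy_mask = rng.random((n, 2, m)) < spec.copy_fidelity
    noise = (rng.random((n, 2, m)) < mean_freq).astype(np.int8)
    alleles = np.where(copy_mask, latent_alleles[:, :, None], noise)
    block = alleles.sum(axis=1).astype(np.int8)

    flip = rng.random(m) < 0.5
    block[:, flip] = 2 - block[:, flip]

    out = genotypes.copy()
    out.dosages[:, spec.start_index:spec.end_index] = block
    if truth is not None:
        truth.block_latents[spec.start_index] = latent
        truth.flipped[spec.start_index:spec.end_index] = flip
    return out


def inject_all_blocks(
    genotypes: GenotypeMatrix, config: SimConfig, truth: SimTruth
) -> GenotypeMatrix:
    rng = _rng(config, "blocks")
    for spec in config.ld_blocks:
        genotypes = inject_ld_block(genotypes, spec, truth.ancestry, truth, rng)
    return genotypes


def assign_case_control(
    ancestry: np.ndarray,
    genotypes: GenotypeMatrix,
    config: SimConfig,
    site: np.ndarray | None = None,
) -> np.ndarray:
    """Draw case/control labels from the logistic disease model.

    The per-site intercept is solved numerically so the expected case
    fraction matches ``case_fraction_per_site`` given that site's realised
    ancestry (and causal-genotype) distribution.
    """
    rng = _rng(config, "status")
    a = np.asarray(ancestry, dtype=float)
    site = site if site is not None else genotypes.samples["site"].to_numpy()
    dm = config.disease_model
    risk = dm.beta_ancestry * a
    for snp_idx, log_or in dm.causal_effects.items():
        d = genotypes.dosages[:, snp_idx].astype(float)
        d[d == MISSING] = np.nan
        d = np.where(np.isnan(d), np.nanmean(d), d)
        risk = risk + log_or * d
    if np.isscalar(config.case_fraction_per_site):
        targets = {name: config.case_fraction_per_site for name in config.site_names}
    else:
        targets = dict(zip(config.site_names, config.case_fraction_per_site))
    status = np.empty(len(a), dtype=object)
    for name in pd.unique(site):
        mask = site == name
        r = risk[mask]
        target = targets.get(name, 0.5)

        def gap(c, r=r):
            return expit(c + r).mean() - target

        try:
            c = brentq(gap, -30.0, 30.0)
        except ValueError as exc:  # pragma: no cover - extreme configs only
            raise ConfigurationError(
                f"case fraction {target} unattainable at site {name}"
            ) from exc
        status[mask] = np.where(rng.random(mask.sum()) < expit(c + r), "case", "control")
    return status.astype(str)


def select_aims(truth: SimTruth, k: int) -> list[str]:
    """Rank SNPs by absolute between-population frequency differential and
    return the top ``k`` outside declared LD blocks (ties to the smaller map
    index)."""
    p = truth.pop_freqs.shape[0]
    in_block = np.zeros(p, dtype=bool)
    for b in truth.blocks:
        in_block[b.start_index:b.end_index] = True
    eligible = np.flatnonzero(~in_block)
    if k > eligible.size:
        raise ConfigurationError(f"requested {k} AIMs but only {eligible.size} eligible SNPs")
    diff = np.abs(truth.pop_freqs[:, 0] - truth.pop_freqs[:, 1])
    # stable sort on (-differential, index) makes the tie-break explicit
    order = eligible[np.lexsort((eligible, -diff[eligible]))]
    chosen = np.sort(order[:k])
    return [f"snp{i:06d}" for i in chosen]


def inject_missing(genotypes: GenotypeMatrix, config: SimConfig) -> GenotypeMatrix:
    if config.missing_rate <= 0:
        return genotypes
    rng = _rng(config, "missing")
    out = genotypes.copy()
    mask = rng.random(out.dosages.shape) < config.missing_rate
    out.dosages[mask] = MISSING
    return out


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Run every stage in order; fully determined by ``config.seed``."""
    anc = simulate_ancestry(config)
    genotypes, truth = simulate_genotypes(anc, config)
    genotypes = inject_all_blocks(genotypes, config, truth)
    status = assign_case_control(truth.ancestry, genotypes, config, truth.site)
    truth.status = status
    genotypes.samples["status"] = status
    genotypes = inject_missing(genotypes, config)
    truth.causal_snp_ids = tuple(
        f"snp{i:06d}" for i in sorted(config.disease_model.causal_effects)
    )
    return genotypes, truth


def truth_frame(truth: SimTruth, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Tidy per-sample ground-truth table for writing alongside the cohort."""
    return pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "site": truth.site,
            "status": truth.status,
            "ancestry": truth.ancestry,
        }
    )
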