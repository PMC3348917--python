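"""Case-control association scans, genomic inflation factor and the
cross-correction comparison statistics.

The per-SNP test is a logistic regression of status on allele dosage
(log-additive coding) plus optional covariates (typically PC scores), fitted
by Newton-Raphson/IRLS simultaneously across all SNPs, with a 1-df Wald
chi-square on the dosage coefficient.  The genomic inflation factor lambda
is the ratio of the upper-tail-trimmed mean of the observed chi-square
statistics to the same trimmed mean of the chi-square(1) reference
distribution; trimming shields lambda from genuine signals, which live in
the upper tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import expit

from .data import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_MAX_ITER = 30
_GRAD_TOL = 1e-8
_BETA_CAP = 15.0  # |dosage log-OR| beyond this is treated as separation


@dataclass
class AssociationScan:
    """Per-SNP scan results plus the covariate set used."""

    table: pd.DataFrame  # snp_id, chromosome, position, beta, se, chisq, p, flag
    covariates: str
    n_samples: int

    @property
    def tested(self) -> pd.DataFrame:
        return self.table[self.table["flag"] == "ok"]

    def chisq(self) -> np.ndarray:
        return self.tested["chisq"].to_numpy()


# ---------------------------------------------------------------------------
# Logistic scan
# ---------------------------------------------------------------------------

def logistic_snp_scan(
    genotypes: GenotypeMatrix,
    status: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
    covariate_label: str = "",
    test: str = "wald",
) -> AssociationScan:
    """Scan every SNP with a log-additive logistic model.

    ``status`` defaults to the genotype matrix's own case/control column.
    ``covariates`` is an (N, m) array added to the intercept + dosage design.
    Missing dosages are mean-imputed per SNP.  Constant-dosage SNPs and SNPs
    showing separation or non-convergence are flagged and excluded from any
    downstream lambda computation.  ``test`` selects the 1-df statistic on
    the dosage term: ``wald`` (default) or ``lrt`` (likelihood ratio against
    the shared covariate-only null).
    """
    if test not in ("wald", "lrt"):
        raise ValueError("test must be 'wald' or 'lrt'")
    y = genotypes.status_vector() if status is None else np.asarray(status, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("status must be binary 0/1")
    n, p = genotypes.dosages.shape
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate rows do not match sample count")
        if not np.isfinite(cov).all():
            raise ValueError("covariates must be finite")

    g = genotypes.dosages.astype(np.float64)
    miss = genotypes.dosages == MISSING
    if miss.any():
        g[miss] = np.nan
        col_mean = np.nanmean(g, axis=0)
        g = np.where(np.isnan(g), col_mean, g)

    constant = g.std(axis=0) == 0

    beta_g, se, converged, loglik_snp, loglik_null = _batched_logistic(y, cov, g)
    separated = np.abs(beta_g) > _BETA_CAP

    flag = np.full(p, "ok", dtype=object)
    flag[~converged] = "not_converged"
    flag[separated] = "separated"
    flag[constant] = "constant"

    with np.errstate(invalid="ignore", divide="ignore"):
        if test == "wald":
            chisq = (beta_g / se) ** 2
        else:
            chisq = np.clip(2.0 * (loglik_snp - loglik_null), 0.0, None)
    pvals = stats.chi2.sf(chisq, df=1)
    bad = flag != "ok"
    chisq[bad] = np.nan
    pvals[bad] = np.nan
    beta_g = np.where(bad, np.nan, beta_g)
    se = np.where(bad, np.nan, se)

    table = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "chromosome": genotypes.snps["chromosome"].to_numpy(),
            "position": genotypes.snps["position"].to_numpy(),
            "beta": beta_g,
            "se": se,
            "chisq": chisq,
            "p": pvals,
            "flag": flag,
        }
    )
    label = covariate_label or ("uncorrected" if cov.shape[1] == 0 else f"{cov.shape[1]} covariates")
    return AssociationScan(table=table, covariates=label, n_samples=n)


def _batched_logistic(
    y: np.ndarray, cov: np.ndarray, g: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Newton-Raphson for P logistic models sharing (intercept + covariates)
    and differing only in the dosage column.

    Returns (dosage log-OR, Wald SE, converged flag, per-SNP log-likelihood,
    covariate-only null log-likelihood).
    """
    n, p = g.shape
    c = np.column_stack([np.ones(n), cov])  # shared columns
    m = c.shape[1]
    d = m + 1

    # warm start at the null (covariate-only) fit, dosage coefficient 0
    beta_null = _single_logistic(y, c)
    beta = np.tile(np.append(beta_null, 0.0), (p, 1))  # (P, d): [c..., g]

    active = np.ones(p, dtype=bool)
    converged = np.zeros(p, dtype=bool)
    for _ in range(_MAX_ITER):
        if not active.any():
            break
        ga = g[:, active]
        ba = beta[active]
        eta = c @ ba[:, :m].T + ga * ba[:, m]
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        r = y[:, None] - mu
        grad = np.empty((active.sum(), d))
        grad[:, :m] = (c.T @ r).T
        grad[:, m] = (ga * r).sum(axis=0)
        hess = np.empty((active.sum(), d, d))
        hess[:, :m, :m] = np.einsum("ni,np,nj->pij", c, w, c, optimize=True)
        hcg = np.einsum("ni,np->pi", c, w * ga, optimize=True)
        hess[:, :m, m] = hcg
        hess[:, m, :m] = hcg
        hess[:, m, m] = (w * ga * ga).sum(axis=0)
        try:
            delta = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - singular Hessians
            delta = np.stack(
                [np.linalg.lstsq(h, gr, rcond=None)[0] for h, gr in zip(hess, grad)]
            )
        # damp huge steps (separation paths) to keep the iteration finite
        norms = np.linalg.norm(delta, axis=1)
        with np.errstate(divide="ignore"):
            scale = np.where(norms > 10.0, 10.0 / np.where(norms > 0, norms, 1.0), 1.0)
        beta[active] = ba + delta * scale[:, None]
        done = np.abs(grad).max(axis=1) < _GRAD_TOL
        runaway = np.abs(beta[active][:, m]) > _BETA_CAP
        converged[np.flatnonzero(active)[done]] = True
        still = np.flatnonzero(active)[~(done | runaway)]
        active = np.zeros(p, dtype=bool)
        active[still] = True

    # Wald SE and log-likelihoods from the final fit of every SNP
    eta = c @ beta[:, :m].T + g * beta[:, m]
    mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
    loglik_snp = (y[:, None] * np.log(mu) + (1.0 - y)[:, None] * np.log1p(-mu)).sum(axis=0)
    mu0 = np.clip(expit(c @ beta_null), 1e-12, 1.0 - 1e-12)
    loglik_null = float(np.sum(y * np.log(mu0) + (1.0 - y) * np.log1p(-mu0)))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    hess = np.empty((p, d, d))
    hess[:, :m, :m] = np.einsum("ni,np,nj->pij", c, w, c, optimize=True)
    hcg = np.einsum("ni,np->pi", c, w * g, optimize=True)
    hess[:, :m, m] = hcg
    hess[:, m, :m] = hcg
    hess[:, m, m] = (w * g * g).sum(axis=0)
    se = np.full(p, np.nan)
    ok = np.zeros(p, dtype=bool)
    try:
        inv = np.linalg.inv(hess)
        var = inv[:, m, m]
        ok = var > 0
        se[ok] = np.sqrt(var[ok])
    except np.linalg.LinAlgError:  # pragma: no cover
        for j in range(p):
            try:
                se[j] = np.sqrt(np.linalg.inv(hess[j])[m, m])
                ok[j] = True
            except np.linalg.LinAlgError:
                pass
    converged &= ok
    return beta[:, m], se, converged, loglik_snp, loglik_null


def _single_logistic(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta = np.zeros(design.shape[1])
    for _ in range(_MAX_ITER):
        mu = expit(design @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = design.T @ (y - mu)
        hess = (design * w[:, None]).T @ design
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(grad).max() < _GRAD_TOL:
            break
    return beta


# ---------------------------------------------------------------------------
# Inflation factor
# ---------------------------------------------------------------------------

@dataclass
class InflationReport:
    lam: float
    trim_fraction: float
    n_stats: int
    expected_trimmed_mean: float
    two_sided: bool = False

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "trim_fraction": self.trim_fraction,
            "n_stats": self.n_stats,
            "expected_trimmed_mean": self.expected_trimmed_mean,
            "two_sided": self.two_sided,
        }


def expected_trimmed_mean_chi2(trim_fraction: float, two_sided: bool = False) -> float:
    """Mean of chi-square(1) restricted to its central trimmed region.

    Upper-tail rule (default): mean conditional on lying below the
    (1 - trim) quantile.  Two-sided rule: conditional on lying between the
    trim/2 and 1 - trim/2 quantiles.  Computed by quadrature.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    if trim_fraction == 0.0:
        return 1.0
    chi2 = stats.chi2(df=1)
    if two_sided:
        lo = chi2.ppf(trim_fraction / 2.0)
        hi = chi2.ppf(1.0 - trim_fraction / 2.0)
        mass = 1.0 - trim_fraction
    else:
        lo, hi = 0.0, chi2.ppf(1.0 - trim_fraction)
        mass = 1.0 - trim_fraction
    val, _ = integrate.quad(lambda x: x * chi2.pdf(x), lo, hi, epsabs=1e-12, limit=200)
    return val / mass


def _trimmed_mean(values: np.ndarray, trim_fraction: float, two_sided: bool) -> float:
    v = np.sort(values)
    n = len(v)
    if two_sided:
        lo = int(np.floor(n * trim_fraction / 2.0))
        hi = n - lo
    else:
        lo, hi = 0, n - int(np.floor(n * trim_fraction))
    return float(v[lo:hi].mean())


def inflation_factor(
    statistics: np.ndarray, trim_fraction: float = 0.1, two_sided: bool = False
) -> InflationReport:
    """Genomic inflation factor from 1-df chi-square statistics."""
    v = np.asarray(statistics, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) < 100:
        raise ValueError(f"need >= 100 finite statistics, got {len(v)}")
    observed = _trimmed_mean(v, trim_fraction, two_sided)
    expected = expected_trimmed_mean_chi2(trim_fraction, two_sided)
    return InflationReport(
        lam=observed / expected,
        trim_fraction=trim_fraction,
        n_stats=len(v),
        expected_trimmed_mean=expected,
        two_sided=two_sided,
    )


# ---------------------------------------------------------------------------
# PC ~ site + disease regression
# ---------------------------------------------------------------------------

def pc_regression(
    scores: pd.DataFrame,
    site: np.ndarray,
    status: np.ndarray,
    reference_site: str | None = None,
) -> pd.DataFrame:
    """OLS of each PC's scores on site indicators plus disease status.

    Returns a tidy table (pc, term, estimate, p_value); the reference site
    (first lexicographically unless given) is absorbed in the intercept,
    matching the convention of reporting site contrasts against one center.
    """
    import statsmodels.api as sm

    site = np.asarray(site).astype(str)
    status01 = _status01(status)
    levels = sorted(np.unique(site))
    if reference_site is not None:
        if reference_site not in levels:
            raise ValueError(f"reference site {reference_site!r} not present")
        levels = [reference_site] + [s for s in levels if s != reference_site]
    cols, names = [], []
    for lvl in levels[1:]:
        cols.append((site == lvl).astype(float))
        names.append(lvl)
    if not names:
        logger.info("single site; site terms omitted")
    design = sm.add_constant(
        np.column_stack(cols + [status01]) if cols else status01[:, None]
    )
    term_names = ["Intercept"] + names + ["Disease"]

    pc_cols = [c for c in scores.columns if c.startswith("PC")]
    rows = []
    for pc in pc_cols:
        fit = sm.OLS(scores[pc].to_numpy(), design).fit()
        for name, est, pv in zip(term_names, fit.params, fit.pvalues):
            rows.append({"pc": pc, "term": name, "estimate": est, "p_value": pv})
    return pd.DataFrame(rows)


def site_associated_pcs(
    scores: pd.DataFrame,
    site: np.ndarray,
    status: np.ndarray,
    alpha: float = 1e-4,
    reference_site: str | None = None,
) -> list[int]:
    """1-based indices of PCs significantly associated with study site.

    Site association (smallest site-term p-value below ``alpha``, controlling
    for disease status) is the working proxy for a component reflecting
    ancestry rather than localized LD or noise.
    """
    table = pc_regression(scores, site, status, reference_site)
    sites = table[~table["term"].isin(["Intercept", "Disease"])]
    hits = []
    for pc, grp in sites.groupby("pc", sort=False):
        if grp["p_value"].min() < alpha:
            hits.append(int(pc[2:]))
    return sorted(hits)


def _status01(status: np.ndarray) -> np.ndarray:
    s = np.asarray(status)
    if s.dtype.kind in "OUS":
        return (s.astype(str) == "case").astype(float)
    return s.astype(float)


# ---------------------------------------------------------------------------
# Cross-correction comparisons
# ---------------------------------------------------------------------------

def pvalue_correlation(
    scan_a: AssociationScan, scan_b: AssociationScan, log10: bool = False
) -> float:
    """Pearson correlation of the two scans' p-values on shared tested SNPs."""
    a = scan_a.tested.set_index("snp_id")["p"]
    b = scan_b.tested.set_index("snp_id")["p"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("scans share no tested SNPs")
    x, y = a.loc[shared].to_numpy(), b.loc[shared].to_numpy()
    if log10:
        x, y = -np.log10(x), -np.log10(y)
    return float(np.corrcoef(x, y)[0, 1])


def top_hits_comparison(
    scan_a: AssociationScan, scan_b: AssociationScan, n_top: int = 20
) -> pd.DataFrame:
    """Pair the top hits of scan A with their strength in scan B.

    Returns one row per top-A SNP with both scans' -log10 p-values, a
    ``mover`` flag for the SNPs in the top decile of |delta|, and
    ``retained`` marking whether the SNP also sits in scan B's own top
    ``n_top``.
    """
    a = scan_a.tested.set_index("snp_id")["p"]
    b = scan_b.tested.set_index("snp_id")["p"]
    shared = a.index.intersection(b.index)
    if n_top > len(shared):
        raise ValueError("n_top exceeds shared tested SNP count")
    a, b = a.loc[shared], b.loc[shared]
    top_a = a.nsmallest(n_top).index
    top_b = set(b.nsmallest(n_top).index)
    la, lb = -np.log10(a.loc[top_a]), -np.log10(b.loc[top_a])
    delta = np.abs(la.to_numpy() - lb.to_numpy())
    cut = np.quantile(delta, 0.9) if n_top > 1 else np.inf
    return pd.DataFrame(
        {
            "snp_id": top_a,
            "neglog10_p_a": la.to_numpy(),
            "neglog10_p_b": lb.to_numpy(),
            "delta": delta,
            "mover": delta >= cut if n_top > 1 else [delta[0] > 0],
            "retained": [s in top_b for s in top_a],
        }
    ).reset_index(drop=True)
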