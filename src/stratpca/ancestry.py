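"""Maximum-likelihood ancestry proportions from an AIMs frequency panel.

Model: conditional on mixing proportions pi over K reference populations,
each of a sample's two alleles at panel SNP j is an independent Bernoulli
draw with success probability q_j = sum_k pi_k f_jk, where f_jk is the
reference allele frequency; SNPs are treated as independent (linkage
equilibrium across AIMs).  The dosage likelihood is Binomial(2, q_j) and
pi is estimated by EM on allele-level mixture responsibilities, which
guarantees monotone ascent of the log-likelihood on the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data import MISSING

_FREQ_CLIP = 1e-6
_SIMPLEX_TOL = 1e-8


@dataclass
class AIMsPanel:
    """Per-SNP reference allele frequencies for K labelled populations."""

    snp_ids: np.ndarray
    freqs: np.ndarray  # (M, K) in [0, 1]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[0] != len(self.snp_ids):
            raise ValueError("freqs must be (n_snps, n_populations)")
        if self.freqs.shape[1] != len(self.labels):
            raise ValueError("labels must match population count")
        if len(self.labels) < 1:
            raise ValueError("need at least one population")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        if len(np.unique(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in panel")

    @property
    def k(self) -> int:
        return len(self.labels)

    @classmethod
    def read(cls, path) -> "AIMsPanel":
        frame = pd.read_csv(path, sep="\t")
        labels = tuple(c for c in frame.columns if c != "snp_id")
        return cls(frame["snp_id"].to_numpy(), frame[list(labels)].to_numpy(), labels)

    def write(self, path) -> None:
        pd.DataFrame(
            {"snp_id": self.snp_ids, **{l: self.freqs[:, i] for i, l in enumerate(self.labels)}}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class AncestryEstimate:
    proportions: np.ndarray  # (K,) on the simplex
    log_likelihood: float
    converged: bool
    identifiable: bool
    labels: tuple[str, ...]

    def argmax_label(self) -> tuple[str, bool]:
        """Label of the largest proportion; ties go to the first label, with
        a tie flag."""
        p = self.proportions
        best = float(p.max())
        winners = np.flatnonzero(np.isclose(p, best, atol=1e-12))
        return self.labels[int(winners[0])], len(winners) > 1


def _clipped(freqs: np.ndarray) -> np.ndarray:
    return np.clip(freqs, _FREQ_CLIP, 1.0 - _FREQ_CLIP)


def loglik(pi: np.ndarray, dosages: np.ndarray, panel: AIMsPanel) -> float:
    """Binomial log-likelihood of one sample's panel dosages at mixture pi.

    Missing dosages are skipped; reference frequencies are clipped away from
    0/1 so fixed panel entries cannot produce -inf.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (panel.k,):
        raise ValueError("pi length must equal panel population count")
    if (pi < -_SIMPLEX_TOL).any() or abs(pi.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError("pi must lie on the probability simplex")
    d = np.asarray(dosages, dtype=float)
    ok = d != MISSING
    d = d[ok]
    q = _clipped(panel.freqs[ok]) @ pi
    const = gammaln(3) - gammaln(d + 1) - gammaln(3 - d)  # log C(2, d)
    return float(np.sum(const + d * np.log(q) + (2 - d) * np.log1p(-q)))


def _em(
    pi0: np.ndarray, d: np.ndarray, f: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, bool]:
    """Allele-level EM from one start; returns (pi, loglik, converged)."""
    pi = pi0.copy()
    m = len(d)
    const = float(np.sum(gammaln(3) - gammaln(d + 1) - gammaln(3 - d)))
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        q = f @ pi
        ll = const + float(np.sum(d * np.log(q) + (2 - d) * np.log1p(-q)))
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        # responsibilities of population k for alt and ref alleles
        r_alt = (pi * f) / q[:, None]
        r_ref = (pi * (1.0 - f)) / (1.0 - q)[:, None]
        counts = (d[:, None] * r_alt + (2.0 - d)[:, None] * r_ref).sum(axis=0)
        pi = counts / (2.0 * m)
        # renormalize: float error in sum(pi) is otherwise amplified by the
        # 1/(1-q) factors and the iterate drifts off the simplex
        pi = pi / pi.sum()
    q = f @ pi
    ll = const + float(np.sum(d * np.log(q) + (2 - d) * np.log1p(-q)))
    return pi, ll, converged


def estimate_ancestry(
    dosages: np.ndarray,
    panel: AIMsPanel,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> AncestryEstimate:
    """EM estimate of one sample's mixing proportions.

    Multi-start (uniform plus each near-vertex corner), keeping the best
    optimum; deterministic given the inputs.
    """
    d = np.asarray(dosages, dtype=float)
    ok = d != MISSING
    if not ok.any():
        raise ValueError("no non-missing panel dosages")
    d = d[ok]
    f = _clipped(panel.freqs[ok])
    k = panel.k

    if k == 1:
        pi = np.array([1.0])
        return AncestryEstimate(pi, loglik(pi, dosages, panel), True, True, panel.labels)

    identifiable = not np.allclose(f, f[:, [0]])
    starts = [np.full(k, 1.0 / k)]
    for j in range(k):
        v = np.full(k, 0.01 / (k - 1))
        v[j] = 0.99
        starts.append(v)
    best = None
    for pi0 in starts:
        pi, ll, conv = _em(pi0, d, f, tol, max_iter)
        if best is None or ll > best[1]:
            best = (pi, ll, conv)
    pi, ll, conv = best
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    return AncestryEstimate(pi, ll, conv, identifiable, panel.labels)


def _em_cohort(
    pi0: np.ndarray, alt: np.ndarray, ref: np.ndarray, f: np.ndarray,
    tol: float, max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM for all samples at once from one start; (pi, loglik, converged)."""
    n = alt.shape[0]
    pi = np.tile(pi0, (n, 1))
    total = alt.sum(axis=1) + ref.sum(axis=1)
    ll = np.full(n, -np.inf)
    converged = np.zeros(n, dtype=bool)
    active = np.arange(n)
    for _ in range(max_iter):
        a, r, t = alt[active], ref[active], total[active]
        q = np.clip(pi[active] @ f.T, 1e-12, 1.0 - 1e-12)  # (n_active, M)
        ll_new = (a * np.log(q) + r * np.log1p(-q)).sum(axis=1)
        done = np.isfinite(ll[active]) & (ll_new - ll[active] < tol)
        ll[active] = ll_new
        converged[active[done]] = True
        keep = ~done  # converged samples take no further M-step
        upd = active[keep]
        counts = pi[upd] * ((a[keep] / q[keep]) @ f + (r[keep] / (1.0 - q[keep])) @ (1.0 - f))
        pi_new = counts / t[keep][:, None]
        pi[upd] = pi_new / pi_new.sum(axis=1, keepdims=True)
        active = upd
        if active.size == 0:
            break
    if active.size:  # final log-likelihood for the non-converged
        q = np.clip(pi[active] @ f.T, 1e-12, 1.0 - 1e-12)
        ll[active] = (alt[active] * np.log(q) + ref[active] * np.log1p(-q)).sum(axis=1)
    return pi, ll, converged


def estimate_cohort(
    genotypes, panel: AIMsPanel, tol: float = 1e-8, max_iter: int = 1000
) -> pd.DataFrame:
    """Per-sample ancestry estimates for every sample in a genotype matrix.

    Runs the same multi-start EM as :func:`estimate_ancestry` but vectorized
    across samples.
    """
    idx = pd.Index(genotypes.snp_ids).get_indexer(panel.snp_ids)
    present = idx >= 0
    if not present.any():
        raise ValueError("no panel SNPs present in the genotype matrix")
    f = _clipped(panel.freqs[present])
    dos = genotypes.dosages[:, idx[present]]
    obs = dos != MISSING
    if not obs.any(axis=1).all():
        raise ValueError("some samples have no non-missing panel dosages")
    d = np.where(obs, dos, 0).astype(float)
    alt = d * obs
    ref = (2.0 - d) * obs
    k = panel.k

    if k == 1:
        pis = np.ones((genotypes.n_samples, 1))
        q = f[:, 0]
        lls = alt @ np.log(q) + ref @ np.log1p(-q)
        best = (pis, lls, np.ones(len(lls), dtype=bool))
    else:
        starts = [np.full(k, 1.0 / k)]
        for j in range(k):
            v = np.full(k, 0.01 / (k - 1))
            v[j] = 0.99
            starts.append(v)
        best = None
        for pi0 in starts:
            pi, ll, conv = _em_cohort(pi0, alt, ref, f, tol, max_iter)
            if best is None:
                best = (pi, ll, conv)
            else:
                better = ll > best[1]
                best = (
                    np.where(better[:, None], pi, best[0]),
                    np.where(better, ll, best[1]),
                    np.where(better, conv, best[2]),
                )
    pis, lls, conv = best
    pis = np.clip(pis, 0.0, None)
    pis = pis / pis.sum(axis=1, keepdims=True)
    # binomial coefficient term, so per-sample values match loglik()
    const = ((gammaln(3) - gammaln(d + 1) - gammaln(3 - d)) * obs).sum(axis=1)
    lls = lls + const
    order = np.argsort(-pis, axis=1, kind="stable")
    argmax = [panel.labels[int(o[0])] for o in order]
    second = pis[np.arange(len(pis)), order[:, 1]] if k > 1 else np.zeros(len(pis))
    ties = np.isclose(pis.max(axis=1), second, atol=1e-12) if k > 1 else np.zeros(len(pis), bool)
    out = pd.DataFrame({"sample_id": genotypes.sample_ids})
    for j, label in enumerate(panel.labels):
        out[label] = pis[:, j]
    out["log_likelihood"] = lls
    out["converged"] = conv
    out["argmax"] = argmax
    out["tie"] = ties
    return out


def panel_from_truth(truth, aims_ids: list[str], labels=("NW", "SE")) -> AIMsPanel:
    """Build a synthetic reference panel from simulation ground-truth
    population frequencies (the stand-in for a published AIMs panel)."""
    idx = np.array([int(s[3:]) for s in aims_ids])
    return AIMsPanel(np.asarray(aims_ids), truth.pop_freqs[idx], tuple(labels))
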