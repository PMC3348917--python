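"""Synthetic-cohort generator: cline sampling, Balding-Nichols genotypes,
LD-block injection, confounded case-control labels and AIMs selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stratpca as sp
from stratpca.data import MISSING
from stratpca.sim import ConfigurationError, LDBlockSpec, simulate_ancestry

from conftest import small_config


# ---------------------------------------------------------------------------
# ancestry sampling
# ---------------------------------------------------------------------------

def test_identical_outputs_for_identical_config():
    cfg = small_config(seed=7)
    g1, t1 = sp.simulate_dataset(cfg)
    g2, t2 = sp.simulate_dataset(cfg)
    np.testing.assert_array_equal(g1.dosages, g2.dosages)
    np.testing.assert_array_equal(t1.ancestry, t2.ancestry)
    assert list(t1.status) == list(t2.status)


def test_exchangeable_sites_have_equal_ancestry_means():
    cfg = sp.headline_config(
        seed=3, cline_site_params=((0.4, 10.0),) * 4, n_per_site=(500,) * 4
    )
    anc = simulate_ancestry(cfg)
    a = anc[anc.site == cfg.site_names[0]]["ancestry"]
    b = anc[anc.site == cfg.site_names[1]]["ancestry"]
    assert stats.ttest_ind(a, b).pvalue > 0.001


def test_site_means_ordered_by_cline_parameter():
    cfg = sp.headline_config(
        seed=1, cline_site_params=((0.2, 50.0), (0.8, 50.0), (0.5, 50.0), (0.5, 50.0))
    )
    anc = simulate_ancestry(cfg)
    means = anc.groupby("site")["ancestry"].mean()
    assert means["MAYO"] < means["NCO"]  # configured 0.2 < 0.8


def test_invalid_cline_parameters_rejected():
    with pytest.raises(ConfigurationError):
        sp.headline_config(cline_site_params=((1.5, 10.0),) * 4)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def test_no_differentiation_no_structure():
    cfg = small_config(seed=2, fst=0.0, ld_blocks=(), n_per_site=(100,) * 4)
    g, truth = sp.simulate_dataset(cfg)
    model = sp.fit_pca(g, k=2)
    assert abs(np.corrcoef(model.scores[:, 0], truth.ancestry)[0, 1]) < 0.2


@pytest.mark.parametrize("seed", range(10))
def test_cline_emerges_on_pc1_at_fst_001(seed):
    cfg = sp.headline_config(
        seed=100 + seed, n_per_site=(125,) * 4, ld_blocks=(),
        missing_rate=0.0, n_snps=5000,
    )
    g, truth = sp.simulate_dataset(cfg)
    model = sp.fit_pca(g, k=2)
    assert abs(np.corrcoef(model.scores[:, 0], truth.ancestry)[0, 1]) > 0.9


def test_sample_frequencies_track_ancestry_weighted_mixture():
    cfg = small_config(seed=5, n_per_site=(500,) * 4, n_snps=500, ld_blocks=(),
                       missing_rate=0.0)
    g, truth = sp.simulate_dataset(cfg)
    a = truth.ancestry
    expected = (1 - a).mean() * truth.pop_freqs[:, 0] + a.mean() * truth.pop_freqs[:, 1]
    observed = g.allele_freqs()
    assert np.max(np.abs(observed - expected)) < 0.05


def test_missingness_rate_matches_configuration():
    cfg = small_config(seed=8, missing_rate=0.01, n_per_site=(100,) * 4, n_snps=1000,
                       ld_blocks=())
    g, _ = sp.simulate_dataset(cfg)
    assert abs(g.missing_rate() - 0.01) < 0.01


def _hudson_fst(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Hudson FST estimator (ratio of averages) between two sample sets."""
    pa, pb = dos_a.mean(axis=0) / 2.0, dos_b.mean(axis=0) / 2.0
    na, nb = dos_a.shape[0], dos_b.shape[0]
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na - 1) - pb * (1 - pb) / (nb - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return float(num.sum() / den.sum())


def test_realized_fst_monotone_in_configured_fst():
    means = []
    for fst in (0.0, 0.005, 0.01, 0.05):
        vals = []
        for seed in range(10):
            cfg = small_config(
                seed=200 + seed, fst=fst, ld_blocks=(), n_per_site=(100,) * 4,
                n_snps=800, missing_rate=0.0,
            )
            g, truth = sp.simulate_dataset(cfg)
            lo = truth.ancestry <= np.quantile(truth.ancestry, 0.1)
            hi = truth.ancestry >= np.quantile(truth.ancestry, 0.9)
            vals.append(_hudson_fst(g.dosages[lo].astype(float), g.dosages[hi].astype(float)))
        means.append(np.mean(vals))
    assert all(b > a for a, b in zip(means, means[1:]))


# ---------------------------------------------------------------------------
# LD blocks
# ---------------------------------------------------------------------------

def _block_r2(dosages: np.ndarray) -> float:
    c = np.corrcoef(dosages.T) ** 2
    iu = np.triu_indices_from(c, k=1)
    return float(np.nanmean(c[iu]))


def test_perfect_fidelity_copies_block_up_to_flips():
    cfg = small_config(seed=4, ld_blocks=(), missing_rate=0.0)
    g, truth = sp.simulate_dataset(cfg)
    spec = LDBlockSpec(100, 130, "local_only", copy_fidelity=1.0)
    rng = np.random.default_rng(0)
    out = sp.inject_ld_block(g, spec, truth.ancestry, truth, rng)
    block = out.dosages[:, 100:130].astype(float)
    flips = truth.flipped[100:130]
    unflipped = np.where(flips[None, :], 2 - block, block)
    assert np.all(unflipped == unflipped[:, [0]])
    assert _block_r2(block) == pytest.approx(1.0)


def test_partial_fidelity_block_r2_dominates_background():
    cfg = sp.headline_config(seed=6, n_per_site=(125,) * 4, ld_blocks=(), missing_rate=0.0)
    g, truth = sp.simulate_dataset(cfg)
    spec = LDBlockSpec(200, 300, "local_only", copy_fidelity=0.95)
    out = sp.inject_ld_block(g, spec, truth.ancestry, truth, np.random.default_rng(1))
    r2_block = _block_r2(out.dosages[:, 200:300].astype(float))
    r2_bg = _block_r2(out.dosages[:, 1000:1100].astype(float))
    assert r2_block > 0.5
    assert r2_block > 10 * r2_bg


def test_cline_linked_latent_tracks_ancestry_and_local_does_not():
    corr_cline, corr_local = [], []
    for seed in range(10):
        cfg = small_config(
            seed=300 + seed, n_per_site=(250,) * 4,
            ld_blocks=(
                LDBlockSpec(100, 120, "cline_linked", 0.9),
                LDBlockSpec(300, 320, "local_only", 0.9),
            ),
        )
        g, truth = sp.simulate_dataset(cfg)
        corr_cline.append(np.corrcoef(truth.block_latents[100], truth.ancestry)[0, 1])
        corr_local.append(abs(np.corrcoef(truth.block_latents[300], truth.ancestry)[0, 1]))
    assert np.mean(np.abs(corr_cline)) > 0.5
    assert np.mean(corr_local) < 0.1


def test_overlapping_blocks_rejected():
    with pytest.raises(ConfigurationError, match="overlap"):
        small_config(ld_blocks=(
            LDBlockSpec(10, 50, "local_only", 0.9),
            LDBlockSpec(40, 80, "local_only", 0.9),
        ))


def test_inversion_like_block_shows_three_latent_levels(small_cohort):
    _, truth = small_cohort
    inv_start = [b.start_index for b in truth.blocks if b.kind == "inversion_like"][0]
    assert set(np.unique(truth.block_latents[inv_start])) <= {0, 1, 2}


# ---------------------------------------------------------------------------
# case/control assignment
# ---------------------------------------------------------------------------

def test_null_disease_model_leaves_ancestry_balanced():
    pvals = []
    for seed in range(10):
        cfg = small_config(
            seed=400 + seed, n_per_site=(250,) * 4, n_snps=200, ld_blocks=(),
            disease_model=sp.DiseaseModel(beta_ancestry=0.0),
            case_fraction_per_site=0.5,
        )
        g, truth = sp.simulate_dataset(cfg)
        y = g.status_vector()
        pvals.append(stats.ttest_ind(truth.ancestry[y == 1], truth.ancestry[y == 0]).pvalue)
    assert min(pvals) > 0.001


def test_confounded_model_shifts_case_ancestry_upward():
    signs = 0
    for seed in range(10):
        cfg = small_config(
            seed=500 + seed, n_per_site=(250,) * 4, n_snps=200, ld_blocks=(),
            disease_model=sp.DiseaseModel(beta_ancestry=2.0),
            case_fraction_per_site=0.5,
        )
        g, truth = sp.simulate_dataset(cfg)
        y = g.status_vector()
        signs += truth.ancestry[y == 1].mean() > truth.ancestry[y == 0].mean()
    assert signs >= 9


def test_case_fraction_hits_target_per_site():
    cfg = small_config(seed=9, n_per_site=(500,) * 4, n_snps=200, ld_blocks=())
    g, _ = sp.simulate_dataset(cfg)
    frac = g.samples.groupby("site", observed=True)["status"].apply(
        lambda s: (s == "case").mean()
    )
    targets = dict(zip(cfg.site_names, cfg.case_fraction_per_site))
    for site, f in frac.items():
        assert abs(f - targets[site]) < 0.1


def test_causal_snp_ranks_high_in_uncorrected_scan():
    medians_causal, medians_all = [], []
    for seed in range(5):
        cfg = small_config(
            seed=600 + seed, n_per_site=(250,) * 4, n_snps=400, ld_blocks=(),
            disease_model=sp.DiseaseModel(beta_ancestry=0.0, causal_effects={37: 0.5}),
            case_fraction_per_site=0.5,
        )
        g, _ = sp.simulate_dataset(cfg)
        scan = sp.logistic_snp_scan(g)
        stats_ = scan.table.set_index("snp_id")["chisq"]
        medians_causal.append(stats_["snp000037"])
        medians_all.append(stats_.median())
    assert np.median(medians_causal) > np.median(medians_all)


# ---------------------------------------------------------------------------
# AIMs selection
# ---------------------------------------------------------------------------

def test_select_aims_exhaustive_and_excludes_blocks(small_cohort):
    _, truth = small_cohort
    n_block = sum(b.n_snps for b in truth.blocks)
    eligible = len(truth.ancestral_freq) - n_block
    aims = sp.select_aims(truth, eligible)
    assert len(aims) == eligible
    block_ids = {
        f"snp{i:06d}" for b in truth.blocks for i in range(b.start_index, b.end_index)
    }
    assert not block_ids & set(aims)
    with pytest.raises(ConfigurationError):
        sp.select_aims(truth, eligible + 1)


def test_select_aims_tie_breaks_to_lower_index(small_cohort):
    _, truth = small_cohort
    import copy

    t = copy.deepcopy(truth)
    t.pop_freqs[:, :] = 0.5  # all differentials zero -> pure tie-break
    aims = sp.select_aims(t, 3)
    block_starts = {b.start_index for b in t.blocks}
    expected = []
    i = 0
    while len(expected) < 3:
        if not any(b.start_index <= i < b.end_index for b in t.blocks):
            expected.append(f"snp{i:06d}")
        i += 1
    assert aims == expected


def test_panel_pca_recovers_full_pca_cline():
    cfg = sp.headline_config(seed=11, n_per_site=(125,) * 4, ld_blocks=())
    g, truth = sp.simulate_dataset(cfg)
    full = sp.fit_pca(g, k=2)
    aims = sp.select_aims(truth, 500)
    panel = sp.fit_pca(g.subset_snps(np.asarray(aims)), k=2)
    r = np.corrcoef(full.scores[:, 0], panel.scores[:, 0])[0, 1]
    assert abs(r) > 0.7
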