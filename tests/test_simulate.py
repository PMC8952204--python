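import numpy as np
import pytest
from scipy.stats import binom

from exomestrat.io import GROUPS, alt_allele_frequency
from exomestrat.simulate import (
    PlantedEffect,
    SimulationConfig,
    simulate_catalog,
    simulate_cohort,
    simulate_replication_pair,
)


def test_same_seed_is_deterministic():
    cfg = SimulationConfig(n_variants=100, seed=42)
    m1, d1, t1 = simulate_cohort(cfg)
    m2, d2, t2 = simulate_cohort(cfg)
    assert np.array_equal(m1.genotypes, m2.genotypes)
    assert t1.equals(t2)
    assert d1.assignments == d2.assignments


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(missing_rate=1.0)
    with pytest.raises(ValueError):
        SimulationConfig(n_per_group=1)
    with pytest.raises(ValueError):
        PlantedEffect(f_high=0.2, f_low=0.8)


def test_group_frequencies_converge_to_truth():
    # At n_per_group = 1000 the observed group frequency should sit within
    # 3 binomial SE of the configured truth.
    cfg = SimulationConfig(
        n_per_group=1000, n_variants=40, frac_planted=0.5, missing_rate=0.0, seed=3
    )
    m, d, truth = simulate_cohort(cfg)
    for g in GROUPS:
        samples = d.samples(group=g)
        for vi in range(0, cfg.n_variants, 7):
            f_true = truth.loc[vi, f"f_{g}"]
            f_obs = alt_allele_frequency(m, vi, samples)
            se = np.sqrt(f_true * (1 - f_true) / (2 * 1000))
            assert abs(f_obs - f_true) <= 3 * se + 1e-12


def test_truth_profiles_agree_with_frequency_ordering():
    cfg = SimulationConfig(n_variants=200, frac_planted=0.3, seed=9)
    _, _, truth = simulate_cohort(cfg)
    planted = truth[truth.planted]
    assert len(planted) == 60
    for _, r in planted.iterrows():
        g_hi, g_lo = r["pair"].split("-")
        assert r[f"f_{g_hi}"] > r[f"f_{g_lo}"]
        assert r["profile"] == f"{g_hi}+{g_lo}-"
    assert (truth.loc[~truth.planted, "pair"] == "").all()


def test_missingness_rate_within_binomial_ci():
    cfg = SimulationConfig(n_variants=500, missing_rate=0.05, seed=21)
    m, _, _ = simulate_cohort(cfg)
    n_cells = m.genotypes.size
    obs = (m.genotypes == -1).mean()
    se = np.sqrt(0.05 * 0.95 / n_cells)
    assert abs(obs - 0.05) <= 3 * se


def test_planted_difference_usually_exceeds_half():
    # (0.9, 0.1) on V vs K with 36 alleles per group: the exact probability
    # that the observed frequency difference exceeds 0.5 (by binomial
    # convolution) is > 0.95, and the simulated fraction agrees within 3 SE.
    n_alleles = 36
    pmf_hi = binom.pmf(np.arange(n_alleles + 1), n_alleles, 0.9)
    pmf_lo = binom.pmf(np.arange(n_alleles + 1), n_alleles, 0.1)
    exact = sum(
        pmf_hi[i] * pmf_lo[j]
        for i in range(n_alleles + 1)
        for j in range(n_alleles + 1)
        if (i - j) / n_alleles > 0.5
    )
    assert exact >= 0.95

    cfg = SimulationConfig(
        n_variants=400,
        frac_planted=1.0,
        effects=(PlantedEffect(pair=("V", "K"), f_high=0.9, f_low=0.1),),
        missing_rate=0.0,
        seed=17,
    )
    m, d, _ = simulate_cohort(cfg)
    fv = np.array([alt_allele_frequency(m, v, d.samples(group="V")) for v in range(400)])
    fk = np.array([alt_allele_frequency(m, v, d.samples(group="K")) for v in range(400)])
    frac = ((fv - fk) > 0.5).mean()
    se = np.sqrt(exact * (1 - exact) / 400)
    assert abs(frac - exact) <= 3 * se + 1e-9


class TestReplicationPair:
    def test_planted_profiles_shared_when_replicating(self):
        cfg = SimulationConfig(n_variants=100, frac_planted=0.5, seed=2)
        (_, _), (_, _), truth = simulate_replication_pair(cfg, labels=("NI", "VADU"))
        planted = truth[truth.planted]
        assert (planted["profile_NI"] == planted["profile_VADU"]).all()
        assert (planted["profile_NI"] == planted["profile"]).all()

    def test_independent_directions_agree_at_chance(self):
        cfg = SimulationConfig(
            n_variants=400, frac_planted=1.0, replicate_profiles=False, seed=13
        )
        _, _, truth = simulate_replication_pair(cfg, labels=("A", "B"))
        agree = (truth["profile_A"] == truth["profile_B"]).sum()
        se = np.sqrt(400 * 0.25)
        assert abs(agree - 200) <= 3 * se

    def test_control_frequency_differs_between_cohorts(self):
        cfg = SimulationConfig(n_variants=50, frac_planted=1.0, seed=4)
        _, _, truth = simulate_replication_pair(cfg, labels=("A", "B"))
        assert not np.allclose(truth["f_C_A"], truth["f_C_B"])


class TestCatalog:
    def test_expected_entry_count_and_membership(self):
        cfg = SimulationConfig(n_variants=2000, seed=6)
        m, _, _ = simulate_cohort(cfg)
        cat = simulate_catalog(m, seed=1, catalog_fraction=0.05)
        assert cat["SNPS"].nunique() == 100  # round(0.05 * 2000)
        matrix_ids = set(m.variant_ids)
        assert set(cat["SNPS"]) <= matrix_ids

    def test_risk_allele_is_ref_or_alt(self):
        cfg = SimulationConfig(n_variants=200, seed=6)
        m, _, _ = simulate_cohort(cfg)
        cat = simulate_catalog(m, seed=2)
        by_id = {v.id: v for v in m.variants}
        for _, r in cat.iterrows():
            v = by_id[r["SNPS"]]
            assert r["RISK_ALLELE"] in (v.ref, v.alt)
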