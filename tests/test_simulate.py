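import numpy as np
import pytest

from pearid.model import ModelError
from pearid.ploidy import detect_g1_peaks
from pearid.simulate import (
    SyntheticConfig,
    default_panel,
    sample_allele_frequencies,
    simulate_cytometry,
    simulate_missingness,
    simulate_population,
    variety_name,
)


def test_frequency_vectors_are_normalized():
    config = SyntheticConfig(seed=0, n_loci=5)
    g, prov, sizes = sample_allele_frequencies(config)
    for locus, p in g.items():
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(sizes[locus]) == len(p)
    for by_locus in prov.values():
        for p in by_locus.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_zero_fst_limit_matches_global_frequencies():
    config = SyntheticConfig(seed=0, n_loci=5, fst=1e-6)
    g, prov, _ = sample_allele_frequencies(config)
    for code, by_locus in prov.items():
        for locus, q in by_locus.items():
            assert np.max(np.abs(q - g[locus])) < 1e-2


def test_single_allele_locus_has_unit_frequency():
    config = SyntheticConfig(seed=0, n_loci=2, alleles_per_locus=(1, 1))
    g, prov, _ = sample_allele_frequencies(config)
    for p in g.values():
        np.testing.assert_allclose(p, [1.0])


def test_invalid_fst_is_fatal():
    with pytest.raises(ModelError):
        SyntheticConfig(seed=0, fst=0.0)
    with pytest.raises(ModelError):
        SyntheticConfig(seed=0, fst=1.0)


def test_balding_nichols_fst_recovery_monte_carlo():
    """Over many replicate loci the realized among-province differentiation
    matches the configured Fst: E[var_prov(q)] = Fst * p * (1-p)."""
    config = SyntheticConfig(
        seed=11, n_loci=10000, alleles_per_locus=(5,) * 10000, fst=0.15,
        n_provinces=5,
    )
    g, prov, _ = sample_allele_frequencies(config)
    provinces = list(prov)
    num = 0.0
    den = 0.0
    for locus, p in g.items():
        q = np.array([prov[c][locus] for c in provinces])  # (5, k)
        num += q.var(axis=0, ddof=1).sum()
        den += (p * (1 - p)).sum()
    assert num / den == pytest.approx(0.15, abs=0.02)


def test_diploids_never_show_three_alleles():
    config = SyntheticConfig(
        seed=2, n_accessions=300, triploid_fraction=0.0, clone_groups=(),
        homonym_groups=(), genotyping_error_rate=0.0,
    )
    table, truth = simulate_population(config)
    for acc in table.accessions:
        for l in table.loci:
            assert acc.allele_set(l).n_alleles <= 2


def test_triploids_show_at_most_three_alleles(panel311):
    table, truth, _ = panel311
    for acc in table.accessions:
        n_max = max(acc.allele_set(l).n_alleles for l in table.loci)
        assert n_max <= 3
        if n_max == 3:
            assert truth.ploidy[acc.accession_id] == 3


def test_planted_clone_group_is_exact_copy():
    config = SyntheticConfig(
        seed=3, n_accessions=30, clone_groups=((3, "alias"),), homonym_groups=(),
        missing_rate=0.0,
    )
    table, truth = simulate_population(config)
    groups = {}
    for acc_id, g in truth.clone_group.items():
        groups.setdefault(g, []).append(acc_id)
    (members,) = [m for m in groups.values() if len(m) == 3]
    genos = [table.get(a).genotype for a in members]
    assert genos[0] == genos[1] == genos[2]
    assert truth.n_synonym_cases == 1


def test_triploid_share_within_binomial_ci():
    config = SyntheticConfig(
        seed=4, n_accessions=500, triploid_fraction=0.25, clone_groups=(),
        homonym_groups=(),
    )
    _, truth = simulate_population(config)
    n_tri = sum(1 for p in truth.ploidy.values() if p == 3)
    sd = np.sqrt(500 * 0.25 * 0.75)
    assert abs(n_tri - 125) < 2.576 * sd  # 99% CI


def test_missingness_rate_zero_is_identity(small_panel):
    table, _, _ = small_panel
    rng = np.random.default_rng(0)
    out = simulate_missingness(table, 0.0, rng)
    for a, b in zip(table.accessions, out.accessions):
        assert a.genotype == b.genotype


def test_missingness_count_within_binomial_ci():
    config = SyntheticConfig(
        seed=5, n_accessions=1000, clone_groups=(), homonym_groups=(),
        missing_rate=0.0,
    )
    table, _ = simulate_population(config)
    out = simulate_missingness(table, 0.5, np.random.default_rng(5))
    n_cells = 1000 * len(table.loci)
    n_missing = sum(
        1 for acc in out.accessions for l in out.loci if acc.allele_set(l).missing
    )
    sd = np.sqrt(n_cells * 0.25)
    assert abs(n_missing - n_cells / 2) < 2.576 * sd


def test_low_missingness_gives_paperlike_sample_sizes():
    table, _, _ = default_panel(6, missing_rate=1 - 300 / 311)
    sizes = list(table.locus_sample_sizes().values())
    assert all(280 <= s <= 311 for s in sizes)
    assert np.mean(sizes) == pytest.approx(311 * 300 / 311, rel=0.03)


def test_clones_diverge_only_in_missingness(small_panel):
    table, truth, _ = small_panel
    noisy = simulate_missingness(table, 0.2, np.random.default_rng(9))
    groups = {}
    for acc_id, g in truth.clone_group.items():
        groups.setdefault(g, []).append(acc_id)
    for members in groups.values():
        for l in noisy.loci:
            cells = [noisy.get(a).allele_set(l) for a in members]
            present = [c.alleles for c in cells if not c.missing]
            assert len(set(present)) <= 1


def test_cytometry_peak_positions_track_ploidy():
    rng = np.random.default_rng(0)
    h2 = simulate_cytometry(2, base_channel=200, cv=0.03, rng=rng)
    h3 = simulate_cytometry(3, base_channel=200, cv=0.03, rng=rng)
    assert abs(h2.channels[np.argmax(h2.counts)] - 200) <= 5
    assert abs(h3.channels[np.argmax(h3.counts)] - 300) <= 5


def test_cytometry_detector_closed_loop():
    rng = np.random.default_rng(1)
    hist = simulate_cytometry(2, base_channel=240, cv=0.03, n_events=20000, rng=rng)
    peaks = detect_g1_peaks(hist)
    best = peaks.positions[np.argmax(peaks.heights)]
    assert abs(best - 240) <= 2


def test_allele_frequency_recovery_at_large_n():
    """Estimated diploid allele frequencies converge to generator truth."""
    from pearid.markers import allele_frequencies

    config = SyntheticConfig(
        seed=8, n_accessions=1000, n_provinces=1, triploid_fraction=0.0,
        clone_groups=(), homonym_groups=(), missing_rate=0.0,
    )
    table, truth = simulate_population(config)
    for locus in table.loci:
        est = allele_frequencies(table, locus)
        true_p = dict(zip(truth.allele_sizes[locus].tolist(),
                          truth.province_freqs["FR"][locus]))
        max_err = max(abs(est.get(a, 0.0) - p) for a, p in true_p.items())
        assert max_err < 0.03


def test_variety_names_unique_and_numeral_free():
    names = [variety_name(i) for i in range(300)]
    assert len(set(names)) == 300
    assert not any(any(ch.isdigit() for ch in n) for n in names)


def test_default_panel_reproducible():
    t1, _, _ = default_panel(42, n_accessions=50, clone_groups=(), homonym_groups=())
    t2, _, _ = default_panel(42, n_accessions=50, clone_groups=(), homonym_groups=())
    for a, b in zip(t1.accessions, t2.accessions):
        assert a.genotype == b.genotype and a.raw_name == b.raw_name
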