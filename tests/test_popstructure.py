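import math
from pathlib import Path

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway

from pearid.identity import binarize, similarity_matrix
from pearid.io import read_structure_runs
from pearid.model import ModelError
from pearid.popstructure import amova, distance_matrix, evanno_delta_k, pcoa
from tests.conftest import make_table

FIXTURE = Path(__file__).parent / "data" / "structure_runs_fixture.csv"


# ---------------------------------------------------------------- distances


def test_band_mismatch_distance_hand_example():
    rows = [
        ("A1", "X", "FR", {"L1": [134, 138], "L2": [200]}),
        ("A2", "Y", "FR", {"L1": [134, 140], "L2": [200]}),
        ("A3", "Z", "FR", {"L1": [134, 138], "L2": []}),
    ]
    table = make_table(rows, ["L1", "L2"])
    bands = binarize(table)
    d2 = distance_matrix(bands, "band_mismatch")
    # columns: L1 in {134,138,140}, L2 in {200}
    # A1 vs A2 differ at 138 and 140 -> 2; A1 vs A3 identical on L1 -> 0
    assert d2[0, 1] == pytest.approx(2.0)
    assert d2[0, 2] == pytest.approx(0.0)
    assert np.all(np.diag(d2) == 0.0)
    assert np.allclose(d2, d2.T)


def test_one_minus_gs_distance(toy_table):
    mat = similarity_matrix(binarize(toy_table))
    d2 = distance_matrix(mat, "one_minus_gs")
    i, j = mat.accession_ids.index("A3"), mat.accession_ids.index("A4")
    assert d2[i, j] == pytest.approx(0.0)  # clones
    assert np.nanmax(d2) <= 1.0


def test_band_mismatch_is_squared_euclidean_when_complete():
    rows = [
        ("A1", "X", "FR", {"L1": [134, 138], "L2": [200, 204]}),
        ("A2", "Y", "FR", {"L1": [134, 140], "L2": [200]}),
        ("A3", "Z", "FR", {"L1": [138, 140], "L2": [204]}),
    ]
    table = make_table(rows, ["L1", "L2"])
    bands = binarize(table)
    d2 = distance_matrix(bands, "band_mismatch")
    expected = squareform(pdist(bands.presence.astype(float), "sqeuclidean"))
    np.testing.assert_allclose(d2, expected)


# -------------------------------------------------------------------- AMOVA


def _scalar_d2(x):
    x = np.asarray(x, dtype=float)
    return (x[:, None] - x[None, :]) ** 2


def test_amova_matches_scalar_anova_decomposition():
    """On squared differences of a scalar trait the distance decomposition
    reproduces the classical one-way ANOVA sums of squares exactly."""
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(0, 1, 10), rng.normal(2, 1, 12), rng.normal(-1, 1, 8)])
    labels = ["a"] * 10 + ["b"] * 12 + ["c"] * 8
    res = amova(_scalar_d2(x), labels, n_permutations=0, seed=0)
    groups = [x[:10], x[10:22], x[22:]]
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    assert res.ss_total == pytest.approx(ss_total, abs=1e-9)
    assert res.ss_within == pytest.approx(ss_within, abs=1e-9)
    assert res.ss_among == pytest.approx(ss_total - ss_within, abs=1e-9)
    # F statistic from the same decomposition agrees with scipy
    f_stat = (res.ss_among / res.df_among) / (res.ss_within / res.df_within)
    assert f_stat == pytest.approx(f_oneway(*groups).statistic)


def test_amova_variance_components_closed_form_balanced():
    """Balanced two-group case checked against hand-derived components."""
    x = np.array([0.0, 0.0, 1.0, 1.0])
    labels = ["a", "a", "b", "b"]
    res = amova(_scalar_d2(x), labels, n_permutations=0)
    # SS_within = 0, SS_among = 1; sigma_w = 0, n0 = 2, sigma_a = 0.5
    assert res.ss_within == pytest.approx(0.0, abs=1e-12)
    assert res.ss_among == pytest.approx(1.0)
    assert res.sigma2_within == pytest.approx(0.0, abs=1e-12)
    assert res.sigma2_among == pytest.approx(0.5)
    assert res.phi_st == pytest.approx(1.0)
    assert res.pct_among == pytest.approx(100.0)


def test_amova_null_phi_is_near_zero_and_p_large():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 40)
    labels = ["a"] * 20 + ["b"] * 20
    res = amova(_scalar_d2(x), labels, n_permutations=499, seed=5)
    assert abs(res.phi_st) < 0.15
    assert res.p_value > 0.05


def test_amova_permutation_p_detects_strong_structure():
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(0, 1, 15), rng.normal(5, 1, 15)])
    labels = ["a"] * 15 + ["b"] * 15
    res = amova(_scalar_d2(x), labels, n_permutations=999, seed=3)
    assert res.p_value == pytest.approx(1 / 1000)
    assert res.phi_st > 0.5


def test_amova_input_validation():
    d2 = _scalar_d2([0.0, 1.0, 2.0])
    with pytest.raises(ModelError, match="2 groups"):
        amova(d2, ["a", "a", "a"])
    with pytest.raises(ModelError, match="mismatch"):
        amova(d2, ["a", "b"])
    nan_d2 = d2.copy()
    nan_d2[0, 1] = nan_d2[1, 0] = np.nan
    with pytest.raises(ModelError, match="undefined"):
        amova(nan_d2, ["a", "b", "c"])
    asym = d2.copy()
    asym[0, 1] += 1
    with pytest.raises(ModelError, match="symmetric"):
        amova(asym, ["a", "b", "c"])


def test_amova_negative_component_warns():
    # groups cutting across the real split -> among-group variance below zero
    x = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
    labels = ["a", "a", "b", "b", "c", "c"]
    with pytest.warns(UserWarning, match="negative"):
        res = amova(_scalar_d2(x), labels, n_permutations=0)
    assert res.sigma2_among < 0


def test_amova_reproducible_with_seed(panel311):
    table, truth, _ = panel311
    bands = binarize(table)
    d2 = np.nan_to_num(distance_matrix(bands, "band_mismatch"))
    labels = [truth.provinces[a] for a in table.accession_ids]
    r1 = amova(d2, labels, n_permutations=99, seed=7)
    r2 = amova(d2, labels, n_permutations=99, seed=7)
    assert r1.p_value == r2.p_value
    assert r1.phi_st == pytest.approx(r2.phi_st)
    assert 0 <= r1.pct_among <= 10  # weak provincial structure, as configured


# --------------------------------------------------------------------- PCoA


def test_pcoa_reconstructs_euclidean_distances():
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(12, 3))
    d = squareform(pdist(pts))
    res = pcoa(d)
    rec = squareform(pdist(res.coordinates))
    np.testing.assert_allclose(rec, d, atol=1e-8)
    assert res.n_negative == 0
    assert res.pct_variance.sum() == pytest.approx(100.0)
    assert np.all(np.diff(res.pct_variance) <= 1e-12)  # descending axes


def test_pcoa_matches_reference_implementation(small_panel):
    skbio_ord = pytest.importorskip("skbio.stats.ordination")
    table, _, _ = small_panel
    bands = binarize(table)
    d2 = distance_matrix(bands, "band_mismatch")
    d = np.sqrt(d2)
    res = pcoa(d)
    ref = skbio_ord.pcoa(d, method="eigh")
    ref_eig = np.asarray(ref.eigvals)
    k = min(5, res.coordinates.shape[1])
    np.testing.assert_allclose(res.eigenvalues[:k], ref_eig[:k], atol=1e-8)
    ref_coords = np.asarray(ref.samples)[:, :k]
    for j in range(k):  # axes match up to sign
        dot = float(np.dot(res.coordinates[:, j], ref_coords[:, j]))
        np.testing.assert_allclose(
            res.coordinates[:, j] * np.sign(dot), ref_coords[:, j], atol=1e-8
        )


def test_pcoa_flags_negative_eigenvalues_for_nonmetric_input():
    # a violated triangle inequality forces a negative eigenvalue
    d = np.array(
        [
            [0.0, 1.0, 1.0, 4.0],
            [1.0, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 1.0],
            [4.0, 1.0, 1.0, 0.0],
        ]
    )
    res = pcoa(d)
    assert res.n_negative >= 1
    assert res.coordinates.shape[1] < 4


def test_pcoa_input_validation():
    with pytest.raises(ModelError, match="symmetric"):
        pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ModelError, match="undefined"):
        pcoa(np.array([[0.0, np.nan], [np.nan, 0.0]]))


# ------------------------------------------------------------------- Evanno


def test_evanno_fixture_matches_hand_arithmetic():
    """Frozen fixture: means L(1..4) = -5000/-4500/-4300/-4250 with replicate
    offsets (0, -10, +10), so sd(L) = 10 at every K and each replicate has
    L' = 500, 200, 50.  Hence |L''(2)| = 300, |L''(3)| = 150 and
    ΔK(2) = 30, ΔK(3) = 15; the optimum is K = 2."""
    runs = read_structure_runs(FIXTURE)
    res = evanno_delta_k(runs)
    assert res.ks == [1, 2, 3, 4]
    np.testing.assert_allclose(res.mean_lnp, [-5000, -4500, -4300, -4250])
    np.testing.assert_allclose(res.sd_lnp, [10, 10, 10, 10])
    np.testing.assert_allclose(res.l_prime[1:], [500, 200, 50])
    assert res.delta_k_of(2) == pytest.approx(30.0)
    assert res.delta_k_of(3) == pytest.approx(15.0)
    assert math.isnan(res.delta_k_of(1)) and math.isnan(res.delta_k_of(4))
    assert res.optimal_k == 2
    assert 2 in res.local_maxima


def test_evanno_zero_sd_is_undefined_with_warning(tmp_path):
    path = tmp_path / "runs.csv"
    rows = ["K,replicate,lnP"]
    for k, mean in ((1, -5000), (2, -4500), (3, -4400), (4, -4380)):
        for r, off in ((1, 0), (2, -10 if k != 2 else 0), (3, 10 if k != 2 else 0)):
            rows.append(f"{k},{r},{mean + off}")
    path.write_text("\n".join(rows) + "\n")
    runs = read_structure_runs(path)
    with pytest.warns(UserWarning, match="undefined"):
        res = evanno_delta_k(runs)
    assert math.isnan(res.delta_k_of(2))
    assert math.isfinite(res.delta_k_of(3))


def test_evanno_on_simulated_runs_finds_planted_kink():
    from pearid.simulate import simulate_structure_runs

    runs = simulate_structure_runs(rng=np.random.default_rng(6), k_max=8, kink_k=3)
    res = evanno_delta_k(runs)
    assert res.optimal_k == 3
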