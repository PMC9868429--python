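import numpy as np
import pytest

from pearid.model import Histogram, ModelError
from pearid.ploidy import (
    PloidyCall,
    assign_peaks_to_standards,
    call_ploidy_dapi,
    classify_panel_ssr,
    classify_ploidy_ssr,
    concordance,
    count_triallelic_loci,
    detect_g1_peaks,
    estimate_genome_size_pi,
)
from pearid.simulate import simulate_cytometry, simulate_pi_run
from tests.conftest import make_table

PI_STANDARDS = (("Raphanus sativus", 1.11), ("Solanum lycopersicum", 1.96))


def _acc(genotype):
    table = make_table([("A1", "X", "FR", genotype)], sorted(genotype))
    return table.get("A1"), table.loci


def test_ssr_call_thresholds():
    acc, loci = _acc({"L1": [1, 2], "L2": [1], "L3": [1, 2]})
    assert classify_ploidy_ssr(acc, loci).call == "diploid"

    acc, loci = _acc({"L1": [1, 2, 3], "L2": [1], "L3": [1, 2]})
    call = classify_ploidy_ssr(acc, loci)
    assert call.call == "putative_triploid" and call.n_triallelic == 1

    acc, loci = _acc({"L1": [1, 2, 3], "L2": [1, 2, 4], "L3": [1, 2]})
    assert classify_ploidy_ssr(acc, loci).call == "triploid"

    # raising min_loci reclassifies a two-locus case as putative
    assert classify_ploidy_ssr(acc, loci, min_loci=3).call == "putative_triploid"
    with pytest.raises(ModelError):
        classify_ploidy_ssr(acc, loci, min_loci=0)


def test_missing_loci_do_not_count_as_triallelic():
    acc, loci = _acc({"L1": [], "L2": [1, 2, 3]})
    assert count_triallelic_loci(acc, loci) == 1


def test_panel_tally_percentages(toy_table):
    tally = classify_panel_ssr(toy_table)
    # A5 is triallelic at L1 and L2 -> triploid; everyone else diploid
    assert tally.n == 6
    assert tally.n_triploid == 1
    assert tally.n_putative_or_triploid == 1
    assert tally.pct_triploid == pytest.approx(100 / 6)


def test_ssr_sensitivity_and_specificity_on_panel(panel311):
    table, truth, _ = panel311
    tally = classify_panel_ssr(table, min_loci=2)
    calls = {c.accession_id: c.call for c in tally.calls}
    true_tri = {a for a, p in truth.ploidy.items() if p == 3}
    called_tri = {a for a, c in calls.items() if c == "triploid"}
    assert called_tri <= true_tri  # no diploid is ever called triploid
    assert len(called_tri) / len(true_tri) >= 0.9


def test_dapi_ratio_windows():
    assert call_ploidy_dapi(200, 200).call == "diploid"
    assert call_ploidy_dapi(205, 200).call == "diploid"
    assert call_ploidy_dapi(300, 200).call == "triploid"
    assert call_ploidy_dapi(290, 200).call == "triploid"
    assert call_ploidy_dapi(250, 200).call == "unassigned"  # ratio 1.25
    tetra = call_ploidy_dapi(400, 200)
    assert tetra.call == "unassigned" and tetra.note == "tetraploid-candidate"
    with pytest.warns(UserWarning, match="plausible"):
        assert call_ploidy_dapi(500, 200).call == "unassigned"
    with pytest.raises(ModelError):
        call_ploidy_dapi(-1, 200)


def test_peak_detection_on_flat_histogram_is_flagged():
    hist = Histogram(np.arange(100.0), np.ones(100))
    peaks = detect_g1_peaks(hist)
    assert peaks.flagged and peaks.n_peaks == 0


def test_peak_detection_recovers_two_gaussians():
    rng = np.random.default_rng(3)
    channels = np.arange(1024.0)
    counts = np.zeros(1024)
    for mu, n in ((200, 8000), (300, 5000)):
        events = rng.normal(mu, 0.03 * mu, size=n)
        counts += np.histogram(events, bins=np.arange(1025.0))[0]
    peaks = detect_g1_peaks(Histogram(channels, counts))
    assert peaks.n_peaks == 2
    assert abs(peaks.positions[0] - 200) <= 3
    assert abs(peaks.positions[1] - 300) <= 3


def test_dapi_closed_loop_against_generator():
    rng = np.random.default_rng(4)
    ref = simulate_cytometry(2, base_channel=200, cv=0.03, rng=rng)
    tri = simulate_cytometry(3, base_channel=200, cv=0.03, rng=rng)
    ref_peak = detect_g1_peaks(ref).positions[0]
    tri_peaks = detect_g1_peaks(tri)
    tri_peak = tri_peaks.positions[np.argmax(tri_peaks.heights)]
    assert call_ploidy_dapi(tri_peak, ref_peak).call == "triploid"
    assert call_ploidy_dapi(ref_peak, ref_peak).call == "diploid"


def test_genome_size_single_standard_linear_ratio():
    est = estimate_genome_size_pi(210, [("R", 200, 2.0)])
    assert est.combined_2c_pg == pytest.approx(2.0 * 210 / 200)
    assert not est.slope_warning


def test_genome_size_mean_over_agreeing_standards():
    # both standards at exactly 100 channels/pg -> estimates coincide
    standards = [("R", 111, 1.11), ("S", 196, 1.96)]
    est = estimate_genome_size_pi(117, standards)
    assert est.per_standard["R"] == pytest.approx(1.17)
    assert est.per_standard["S"] == pytest.approx(1.17)
    assert est.combined_2c_pg == pytest.approx(1.17)
    assert not est.slope_warning


def test_genome_size_warns_on_slope_disagreement():
    with pytest.warns(UserWarning, match="slopes disagree"):
        est = estimate_genome_size_pi(117, [("R", 111, 1.11), ("S", 240, 1.96)])
    assert est.slope_warning


def test_assign_peaks_picks_slope_consistent_standards():
    # true slope 180 channels/pg: standards at 199.8 and 352.8, sample at 210.6
    positions = [199.8, 210.6, 352.8]
    sample, assigned = assign_peaks_to_standards(positions, PI_STANDARDS)
    assert sample == pytest.approx(210.6)
    assert dict((n, p) for n, p, _ in assigned) == {
        "Raphanus sativus": pytest.approx(199.8),
        "Solanum lycopersicum": pytest.approx(352.8),
    }


def test_assign_peaks_requires_enough_peaks():
    with pytest.raises(ModelError, match="peaks"):
        assign_peaks_to_standards([100.0, 200.0], PI_STANDARDS)


def test_pi_closed_loop_recovers_genome_size():
    """simulate -> detect -> assign -> estimate recovers the configured 2C."""
    for true_2c, rng_seed in ((1.17, 5), (1.70, 6)):
        rng = np.random.default_rng(rng_seed)
        hist = simulate_pi_run(true_2c, standards=PI_STANDARDS,
                               channels_per_pg=180, cv=0.01, rng=rng)
        peaks = detect_g1_peaks(hist)
        sample, assigned = assign_peaks_to_standards(peaks.positions, PI_STANDARDS)
        est = estimate_genome_size_pi(sample, assigned)
        assert est.combined_2c_pg == pytest.approx(true_2c, rel=0.03)


def test_concordance_counts_and_drops_unassigned():
    ssr = [
        PloidyCall("A1", "diploid", "ssr"),
        PloidyCall("A2", "triploid", "ssr"),
        PloidyCall("A3", "putative_triploid", "ssr"),
        PloidyCall("A4", "diploid", "ssr"),
    ]
    cyto = [
        PloidyCall("A1", "diploid", "cytometry"),
        PloidyCall("A2", "triploid", "cytometry"),
        PloidyCall("A3", "diploid", "cytometry"),
        PloidyCall("A4", "unassigned", "cytometry"),
    ]
    res = concordance(ssr, cyto)
    # A4 dropped; putative A3 treated as diploid and agrees
    assert res.n == 3
    assert res.agreement == pytest.approx(1.0)
    assert res.confusion[("diploid", "diploid")] == 2
    assert res.confusion[("triploid", "triploid")] == 1
    assert res.discordant == []

    res_tri = concordance(ssr, cyto, putative_as="triploid")
    assert res_tri.discordant == ["A3"]
    assert res_tri.agreement == pytest.approx(2 / 3)


def test_concordance_requires_shared_ids():
    with pytest.raises(ModelError, match="share"):
        concordance(
            [PloidyCall("A1", "diploid", "ssr")],
            [PloidyCall("B1", "diploid", "cytometry")],
        )
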