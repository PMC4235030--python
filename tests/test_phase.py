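"""Common-marker matching and persistence-of-phase estimation."""

import numpy as np
import pytest

from ldscape.genotype_io import HaplotypePanel, Marker
from ldscape.phase import (
    binned_phase_decay,
    common_markers,
    local_phase,
    phase_correlation,
)
from ldscape.synthetic import SyntheticSpec, gen_diverged_populations

from conftest import make_panel, random_polymorphic_panel


def panel_at(positions, rng, label, alleles=None, n_hap=20):
    H = rng.integers(0, 2, size=(len(positions), n_hap)).astype(np.int8)
    p = H.mean(axis=1)
    for row in np.flatnonzero((p == 0) | (p == 1)):
        H[row, 0] ^= 1
    alleles = alleles or [("A", "G")] * len(positions)
    markers = [
        Marker(id=f"{label}_m{k}", chrom="1", pos=int(p), allele0=a0, allele1=a1)
        for k, (p, (a0, a1)) in enumerate(zip(positions, alleles))
    ]
    return HaplotypePanel(
        markers=markers,
        haplotypes=H,
        sample_ids=[f"{label}{k}" for k in range(n_hap // 2)],
        population_label=label,
    )


def copy_panel(panel, label):
    return HaplotypePanel(
        markers=list(panel.markers),
        haplotypes=panel.haplotypes.copy(),
        sample_ids=list(panel.sample_ids),
        population_label=label,
    )


class TestCommonMarkers:
    def test_scenario_one_is_three_way_intersection(self, rng):
        A = panel_at([1000, 2000, 3000], rng, "A")
        B = panel_at([2000, 3000, 4000], rng, "B")
        C = panel_at([2000, 3000, 5000], rng, "C")
        cms = common_markers([A, B, C], scenario="I")
        assert sorted(cms.table["pos"]) == [2000, 3000]

    def test_scenario_two_is_pairwise_intersection(self, rng):
        A = panel_at([1000, 2000, 3000], rng, "A")
        B = panel_at([2000, 3000, 4000], rng, "B")
        cms = common_markers([A, B], scenario="II")
        assert sorted(cms.table["pos"]) == [2000, 3000]

    def test_scenario_one_subset_of_each_scenario_two(self, rng):
        A = panel_at([1000, 2000, 3000, 4000], rng, "A")
        B = panel_at([2000, 3000, 4000, 5000], rng, "B")
        C = panel_at([1000, 2000, 4000, 6000], rng, "C")
        s1 = common_markers([A, B, C], scenario="I").positions()
        for pair in ([A, B], [A, C], [B, C]):
            s2 = common_markers(pair, scenario="II").positions()
            assert s1 <= s2

    def test_swapped_alleles_matched_with_flip_flag(self, rng):
        A = panel_at([1000, 2000], rng, "A")
        B = panel_at([1000, 2000], rng, "B", alleles=[("G", "A"), ("A", "G")])
        cms = common_markers([A, B], scenario="II")
        flags = dict(zip(cms.table["pos"], cms.table["flip_B"]))
        assert flags == {1000: True, 2000: False}

    def test_allele_set_mismatch_dropped(self, rng):
        A = panel_at([1000, 2000], rng, "A")
        B = panel_at([1000, 2000], rng, "B", alleles=[("C", "T"), ("A", "G")])
        cms = common_markers([A, B], scenario="II")
        assert sorted(cms.table["pos"]) == [2000]
        assert cms.n_dropped_allele_mismatch == 1

    def test_empty_intersection_is_error(self, rng):
        A = panel_at([1000], rng, "A")
        B = panel_at([9000], rng, "B")
        with pytest.raises(ValueError, match="no common"):
            common_markers([A, B], scenario="II")

    def test_scenario_two_rejects_three_panels(self, rng):
        panels = [panel_at([1000], rng, lab) for lab in "ABC"]
        with pytest.raises(ValueError, match="pair"):
            common_markers(panels, scenario="II")


class TestPhaseCorrelation:
    def test_identity_and_negation(self):
        r = np.array([0.2, -0.5, 0.7, 0.1])
        assert phase_correlation(r, r) == pytest.approx(1.0)
        assert phase_correlation(r, -r) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        rA = [0.1, 0.5, 0.9]
        rB = [0.2, 0.4, 1.0]
        # deviations: A (-0.4, 0, 0.4); B (-2/15, -2/15, 4/15) around 8/15...
        # direct formula: 0.32 / sqrt(0.32 * 0.346667) = 0.960769
        assert phase_correlation(rA, rB) == pytest.approx(0.9607689, abs=1e-6)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(phase_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3]))

    def test_symmetry(self, rng):
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert phase_correlation(a, b) == pytest.approx(phase_correlation(b, a))

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            phase_correlation([0.1, 0.2], [0.3, 0.4])


class TestBinnedPhaseDecay:
    def test_identical_panels_give_correlation_one_everywhere(self, rng):
        A = random_polymorphic_panel(rng, 40, 30, span_bp=4_000_000)
        A.population_label = "A"
        B = copy_panel(A, "B")
        cms = common_markers([A, B], scenario="II")
        curve = binned_phase_decay(A, B, cms).table
        nonempty = curve.dropna(subset=["cor_r"])
        assert len(nonempty) > 0
        np.testing.assert_allclose(nonempty["cor_r"], 1.0, atol=1e-9)

    def test_identical_panels_scenarios_agree(self, rng):
        A = random_polymorphic_panel(rng, 30, 30, span_bp=3_000_000)
        A.population_label = "A"
        B, C = copy_panel(A, "B"), copy_panel(A, "C")
        c1 = binned_phase_decay(A, B, common_markers([A, B, C], "I")).table
        c2 = binned_phase_decay(A, B, common_markers([A, B], "II")).table
        np.testing.assert_allclose(c1["cor_r"], c2["cor_r"], atol=1e-12)

    def test_independent_populations_fluctuate_around_zero(self, rng):
        # same marker map, haplotypes drawn independently: no shared ancestry
        A = random_polymorphic_panel(rng, 120, 60, span_bp=12_000_000)
        A.population_label = "A"
        B = random_polymorphic_panel(rng, 120, 60, span_bp=12_000_000)
        B = make_panel(B.haplotypes, A.positions, label="B")
        cms = common_markers([A, B], scenario="II")
        curve = binned_phase_decay(A, B, cms).table.dropna(subset=["cor_r"])
        # mean bin correlation within Monte-Carlo noise of zero
        assert abs(curve["cor_r"].mean()) < 3.5 / np.sqrt(curve["n_pairs"].sum())

    def test_global_allele_relabel_leaves_curve_unchanged(self, rng):
        A = random_polymorphic_panel(rng, 40, 30, span_bp=4_000_000)
        A.population_label = "A"
        B = copy_panel(A, "B")
        curve0 = binned_phase_decay(A, B, common_markers([A, B], "II")).table
        # relabel every B marker: swap allele labels AND complement codes
        B2 = HaplotypePanel(
            markers=[
                Marker(id=m.id, chrom=m.chrom, pos=m.pos,
                       allele0=m.allele1, allele1=m.allele0)
                for m in B.markers
            ],
            haplotypes=(1 - B.haplotypes).astype(np.int8),
            sample_ids=list(B.sample_ids),
            population_label="B",
        )
        curve1 = binned_phase_decay(A, B2, common_markers([A, B2], "II")).table
        np.testing.assert_allclose(curve0["cor_r"], curve1["cor_r"], atol=1e-12)

    def test_correlation_decreases_with_divergence_time(self):
        short = {}
        for t in (20, 200):
            spec = SyntheticSpec(n_markers=250, chrom_length_bp=25_000_000,
                                 ne=150, n_individuals=80, seed=31)
            A, B = gen_diverged_populations(spec, [("A", t), ("B", t)])
            cms = common_markers([A, B], scenario="II")
            curve = binned_phase_decay(A, B, cms).table
            short[t] = curve[curve["mid"] < 1.0]["cor_r"].mean()
        assert short[200] < short[20]


class TestLocalPhase:
    def test_identical_panels_track_constant_one(self, rng):
        A = random_polymorphic_panel(rng, 40, 30, span_bp=4_000_000)
        A.population_label = "A"
        B = copy_panel(A, "B")
        track = local_phase(A, B, common_markers([A, B], "II"), N=10).table
        np.testing.assert_allclose(track["cor_r"], 1.0, atol=1e-9)
        assert (track["n_pairs"] == 45).all()

    def test_window_count_and_single_point_track(self, rng):
        A = random_polymorphic_panel(rng, 25, 30, span_bp=2_500_000)
        A.population_label = "A"
        B = copy_panel(A, "B")
        cms = common_markers([A, B], "II")
        track = local_phase(A, B, cms, N=10).table
        assert len(track) == 25 - 10 + 1
        track1 = local_phase(A, B, cms, N=25).table
        assert len(track1) == 1

    def test_locally_diverged_segment_depresses_track(self, rng):
        # B equals A except haplotypes are re-randomized inside one segment
        A = random_polymorphic_panel(rng, 90, 60, span_bp=9_000_000)
        A.population_label = "A"
        H = A.haplotypes.copy()
        seg = slice(30, 60)
        H[seg] = rng.integers(0, 2, size=H[seg].shape).astype(np.int8)
        p = H.mean(axis=1)
        for row in np.flatnonzero((p == 0) | (p == 1)):
            H[row, 0] ^= 1
        B = make_panel(H, A.positions, label="B")
        track = local_phase(A, B, common_markers([A, B], "II"), N=15).table
        pos = track["mid_pos"].to_numpy()
        cor = track["cor_r"].to_numpy()
        inside = (pos > A.positions[32]) & (pos < A.positions[57])
        outside = (pos < A.positions[28]) | (pos > A.positions[61])
        assert np.nanmean(cor[inside]) < np.nanmean(cor[outside])
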