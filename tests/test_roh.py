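import numpy as np
import pytest

from rohscope.roh import (
    IslandRegion,
    ROHCriteria,
    ROHSegment,
    call_islands,
    compute_froh,
    detect_roh_cohort,
    detect_roh_individual,
    snp_roh_incidence,
    summarize_breed_counts,
    verify_segment,
)
from rohscope.synthetic_data import PlantedSegment, SimConfig, simulate_cohort

from _oracles import brute_force_roh, random_roh_instance
from conftest import make_gm

# small criteria for hand-built toys: the rules scale, the logic does not
TOY = ROHCriteria(
    min_snps=5, min_density_bp_per_snp=100_000, min_length_bp=100_000,
    max_missing=2, max_het=1, max_gap_bp=1_000_000,
)


def _one_row_gm(pos, dosages):
    return make_gm(np.array([dosages], dtype=np.int8), pos=pos)


class TestDetectIndividual:
    def test_all_heterozygous_yields_nothing(self):
        gm = _one_row_gm(np.arange(1, 201) * 20_000, [1] * 200)
        assert detect_roh_individual(gm, "s0") == []

    def test_min_snps_boundary_excludes_99(self):
        # 99 homozygous SNPs over 2 Mb flanked by hets: fails min_snps=100
        pos = np.concatenate([[5_000], np.linspace(1e6, 3e6, 99).astype(int), [4_000_000]])
        d = [1] + [0] * 99 + [1]
        gm = _one_row_gm(pos, d)
        assert detect_roh_individual(gm, "s0") == []

    def test_qualifying_run_with_tolerated_het_and_missing(self):
        # 150 SNPs spanning 1,000,000..3,000,000 with 1 het + 2 missing inside
        pos = np.concatenate([[5_000], np.linspace(1e6, 3e6, 150).astype(int), [4_000_000]])
        d = np.array([1] + [0] * 150 + [1], dtype=np.int8)
        d[40], d[80], d[110] = 1, -1, -1
        gm = _one_row_gm(pos, d)
        segs = detect_roh_individual(gm, "s0")
        assert len(segs) == 1
        seg = segs[0]
        assert (seg.start, seg.end) == (1_000_000, 3_000_000)
        assert seg.length == 2_000_001
        assert seg.n_het == 1 and seg.n_missing == 2 and seg.n_snps == 150

    def test_min_length_boundary_excludes_short_run(self):
        pos = np.linspace(1e6, 1.9e6, 150).astype(int)  # 0.9 Mb span
        gm = _one_row_gm(pos, [0] * 150)
        assert detect_roh_individual(gm, "s0") == []

    def test_large_gap_splits_run(self):
        half = np.linspace(1e6, 3e6, 150).astype(int)
        pos = np.concatenate([half, half + 3_200_000])  # 1.2 Mb gap in the middle
        gm = _one_row_gm(pos, [0] * 300)
        segs = detect_roh_individual(gm, "s0")
        assert len(segs) == 2
        assert all(s.length == pytest.approx(2_000_001, abs=2) for s in segs)

    def test_density_rule_excludes_sparse_run(self):
        # 10 SNPs over 2 Mb: 200 kb per SNP > 100 kb per SNP
        pos = np.linspace(1e6, 3e6, 10).astype(int)
        crit = ROHCriteria(min_snps=5, min_length_bp=1_000_000)
        gm = _one_row_gm(pos, [0] * 10)
        assert detect_roh_individual(gm, "s0", crit) == []

    def test_boundaries_are_homozygous(self):
        # run bracketed by a het and a missing call: termini must be hom
        pos = np.linspace(1e6, 3e6, 152).astype(int)
        d = np.array([1] + [0] * 150 + [-1], dtype=np.int8)
        gm = _one_row_gm(pos, d)
        (seg,) = detect_roh_individual(gm, "s0")
        assert seg.start == pos[1] and seg.end == pos[150]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        """Scanner equals the exhaustive window enumerator on random instances."""
        rng = np.random.default_rng(seed)
        crit = ROHCriteria(
            min_snps=8, min_density_bp_per_snp=20_000, min_length_bp=50_000,
            max_missing=2, max_het=1, max_gap_bp=50_000,
        )
        for _ in range(20):
            pos, d = random_roh_instance(
                rng, n_snps=300,
                het_rate=float(rng.uniform(0.01, 0.15)),
                miss_rate=float(rng.uniform(0.0, 0.05)),
                mean_spacing=int(rng.integers(2_000, 8_000)),
            )
            gm = _one_row_gm(pos, d)
            got = [(s.start, s.end) for s in detect_roh_individual(gm, "s0", crit)]
            want = [(int(pos[i]), int(pos[j])) for i, j in brute_force_roh(pos, d, crit)]
            assert got == want

    def test_reported_segments_reverify_against_criteria(self):
        cfg = SimConfig(n_pops=1, n_per_pop=10, n_sites=8_000, f_autozygous=0.1, seed=21)
        gm, _ = simulate_cohort(cfg)
        segs = detect_roh_cohort(gm)
        assert segs and all(verify_segment(s, gm) for s in segs)

    def test_raising_min_length_never_increases_count(self):
        cfg = SimConfig(n_pops=1, n_per_pop=10, n_sites=8_000, f_autozygous=0.1, seed=22)
        gm, _ = simulate_cohort(cfg)
        counts = [
            len(detect_roh_cohort(gm, ROHCriteria(min_length_bp=L)))
            for L in (1_000_000, 2_000_000, 3_000_000)
        ]
        assert counts[0] >= counts[1] >= counts[2]


class TestDetectCohort:
    def test_single_qualifying_individual(self):
        pos = np.linspace(1e6, 3e6, 150).astype(int)
        d = np.vstack([[0] * 150, [1] * 150]).astype(np.int8)
        gm = make_gm(d, pos=pos)
        segs = detect_roh_cohort(gm)
        assert len(segs) == 1 and segs[0].sample == "s0"

    def test_planted_carriers_recovered_with_boundary_tolerance(self):
        cfg = SimConfig(
            n_pops=4, n_per_pop=10, n_sites=10_000, seed=23,
            planted_segments=[PlantedSegment("P2", "1", 20_000_000, 23_000_000, 0.5)],
        )
        gm, truth = simulate_cohort(cfg)
        segs = detect_roh_cohort(gm)
        truth_iv = truth.autozygous_intervals
        assert len(truth_iv) == 5
        spacing = np.diff(gm.pos[gm.chrom == "1"]).max()
        for _, row in truth_iv.iterrows():
            match = [
                s for s in segs
                if s.sample == row["sample"] and s.chrom == row.chrom
                and s.start <= row.start + spacing and s.end >= row.end - spacing
            ]
            assert len(match) == 1

    def test_per_breed_counts_match_planted_design(self):
        cfg = SimConfig(
            n_pops=4, n_per_pop=10, n_sites=10_000, seed=24,
            planted_segments=[
                PlantedSegment("P1", "1", 10_000_000, 13_000_000, 1.0),
                PlantedSegment("P3", "2", 10_000_000, 13_000_000, 0.5),
            ],
        )
        gm, _ = simulate_cohort(cfg)
        per_breed, _ = summarize_breed_counts(detect_roh_cohort(gm), gm.populations)
        assert per_breed.loc["P1", "count"] == 10
        assert per_breed.loc["P3", "count"] == 5
        assert per_breed.loc["P2", "count"] == 0 and per_breed.loc["P4", "count"] == 0


def _fake_segments(counts: dict[str, int]):
    segs, pops = [], {}
    for breed, n in counts.items():
        sample = f"{breed}_x"
        pops[sample] = breed
        segs += [
            ROHSegment(sample, "1", 1_000_000 * (k + 1), 1_000_000 * (k + 1) + 10, 10)
            for k in range(n)
        ]
    return segs, pops


class TestBreedSummary:
    def test_published_style_share_arithmetic(self):
        segs, pops = _fake_segments({"JD": 1751, "LC": 1853, "PT": 788, "SM": 981})
        per_breed, _ = summarize_breed_counts(segs, pops)
        assert per_breed["count"].sum() == 5373
        assert per_breed.loc["JD", "share_pct"] == 32.59
        assert per_breed.loc["LC", "share_pct"] == 34.49
        assert per_breed.loc["PT", "share_pct"] == 14.67
        assert per_breed.loc["SM", "share_pct"] == 18.26

    def test_single_breed_gets_full_share(self):
        segs, pops = _fake_segments({"A": 7})
        per_breed, _ = summarize_breed_counts(segs, pops)
        assert per_breed.loc["A", "share_pct"] == 100.0

    def test_symmetric_counts_split_evenly(self):
        segs, pops = _fake_segments({"A": 1, "B": 1, "C": 1, "D": 1})
        per_breed, _ = summarize_breed_counts(segs, pops)
        assert (per_breed["share_pct"] == 25.0).all()

    def test_zero_segments_warns(self):
        with pytest.warns(UserWarning):
            per_breed, _ = summarize_breed_counts([], {"a": "A"})
        assert (per_breed["count"] == 0).all()


class TestFroh:
    def test_no_roh_gives_zero(self):
        gm = make_gm([[1, 1, 1]], pos=[1, 500_000, 1_000_000])
        (res,) = compute_froh([], gm)
        assert res.froh == 0.0

    def test_full_coverage_gives_one(self):
        pos = np.linspace(1e6, 3e6, 150).astype(int)
        gm = make_gm([[0] * 150], pos=pos)
        segs = detect_roh_cohort(gm)
        (res,) = compute_froh(segs, gm)
        assert res.froh == 1.0

    def test_invariant_to_chromosome_relabel_and_segment_order(self):
        cfg = SimConfig(n_pops=1, n_per_pop=5, n_sites=6_000, f_autozygous=0.1, seed=25)
        gm, _ = simulate_cohort(cfg)
        segs = detect_roh_cohort(gm)
        base = {r.sample: r.froh for r in compute_froh(segs, gm)}
        relabel = {"1": "chrA", "2": "chrB"}
        gm2 = make_gm(
            gm.dosages, pos=gm.pos,
            chrom=np.array([relabel[str(c)] for c in gm.chrom], object),
            samples=gm.samples,
        )
        segs2 = [
            ROHSegment(s.sample, relabel[s.chrom], s.start, s.end, s.n_snps,
                       s.n_het, s.n_missing)
            for s in reversed(segs)
        ]
        assert {r.sample: r.froh for r in compute_froh(segs2, gm2)} == base

    def test_autosome_restriction(self):
        pos = np.concatenate([np.linspace(1e6, 3e6, 150), np.linspace(1e6, 3e6, 150)]).astype(int)
        chrom = np.array(["1"] * 150 + ["Z"] * 150, object)
        gm = make_gm([[0] * 300], pos=pos, chrom=chrom)
        segs = detect_roh_cohort(gm)
        (res,) = compute_froh(segs, gm, autosomes=["1"])
        assert res.froh == 1.0 and res.denominator_bp == 2_000_001

    def test_empty_autosome_intersection_raises(self):
        gm = make_gm([[0, 0]], pos=[1, 2])
        with pytest.raises(ValueError):
            compute_froh([], gm, autosomes=["Z"])

    def test_recovers_planted_autozygosity_fraction(self):
        """Mean F_ROH tracks the planted genome fraction (single condition;
        the full sweep runs in the acceptance suite)."""
        frohs = []
        for seed in (0, 1):
            cfg = SimConfig(n_pops=1, n_per_pop=10, n_sites=20_000,
                            f_autozygous=0.10, seed=seed)
            gm, _ = simulate_cohort(cfg)
            res = compute_froh(detect_roh_cohort(gm), gm)
            frohs += [r.froh for r in res]
        assert np.mean(frohs) == pytest.approx(0.10, abs=0.02)


class TestIncidenceAndIslands:
    def test_incidence_arithmetic(self):
        pos = np.linspace(1e6, 3e6, 150).astype(int)
        n = 10
        d = np.vstack([[0] * 150] * 3 + [[1] * 150] * 7).astype(np.int8)
        gm = make_gm(d, pos=pos)
        inc = snp_roh_incidence(detect_roh_cohort(gm), gm)
        assert np.allclose(inc, 0.3)

    def test_site_outside_all_segments_is_zero(self):
        pos = np.concatenate([np.linspace(1e6, 3e6, 150), [10_000_000]]).astype(int)
        d = np.array([[0] * 150 + [1]], dtype=np.int8)
        gm = make_gm(d, pos=pos)
        inc = snp_roh_incidence(detect_roh_cohort(gm), gm)
        assert inc[-1] == 0.0 and inc[0] == 1.0

    def test_island_threshold_is_inclusive(self):
        gm = make_gm(np.zeros((10, 5), np.int8), pos=[10, 20, 30, 40, 50])
        inc = np.array([0.1, 0.3, 0.3, 0.3, 0.29])
        (isl,) = call_islands(inc, gm, threshold=0.30)
        assert (isl.start, isl.end, isl.n_snps) == (20, 40, 3)
        assert isl.length == 21

    def test_all_below_threshold_gives_no_islands(self):
        gm = make_gm(np.zeros((10, 4), np.int8))
        assert call_islands(np.full(4, 0.29), gm) == []

    def test_runs_split_by_single_below_threshold_snp(self):
        gm = make_gm(np.zeros((10, 7), np.int8))
        inc = np.array([0.4, 0.4, 0.1, 0.5, 0.5, 0.0, 0.9])
        islands = call_islands(inc, gm)
        assert len(islands) == 3
        assert [i.n_snps for i in islands] == [2, 2, 1]

    def test_raising_threshold_never_increases_island_count(self):
        rng = np.random.default_rng(26)
        gm = make_gm(np.zeros((10, 200), np.int8))
        inc = rng.random(200)
        counts = [len(call_islands(inc, gm, t)) for t in (0.2, 0.5, 0.8)]
        # island count can go either way between thresholds when runs split,
        # but the number of member SNPs is monotone
        snps = [sum(i.n_snps for i in call_islands(inc, gm, t)) for t in (0.2, 0.5, 0.8)]
        assert snps[0] >= snps[1] >= snps[2]
        assert counts[-1] <= 200

    def test_published_style_length_convention(self):
        """Island length is end - start + 1 (1-based inclusive ends)."""
        isl = IslandRegion("1", 45_626_183, 50_131_802, 108, ())
        assert isl.length == 4_505_620

    def test_planted_shared_segment_gives_expected_pooled_incidence(self):
        cfg = SimConfig(
            n_pops=4, n_per_pop=10, n_sites=10_000, seed=27,
            planted_segments=[PlantedSegment("P1", "1", 20_000_000, 23_000_000, 0.5)],
        )
        gm, truth = simulate_cohort(cfg)
        inc = snp_roh_incidence(detect_roh_cohort(gm), gm)
        lo = np.searchsorted(gm.pos[gm.chrom == "1"], 20_500_000)
        hi = np.searchsorted(gm.pos[gm.chrom == "1"], 22_500_000)
        interior = inc[lo:hi]
        # 5 carriers of 40 samples pooled = 0.125
        assert np.median(interior) == pytest.approx(0.125, abs=0.01)
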