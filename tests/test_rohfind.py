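"""ROH detection against hand-worked cases and a brute-force oracle."""

import numpy as np
import pytest

from conftest import windows_frame
from roh_oracle import oracle_detect
from rohdel.rohfind import ROH, ROHParams, classify_roh, detect_roh, genome_fraction

GM = 10.0  # genome-mean heterozygosity used throughout


class TestDetectExamples:
    def test_flat_at_genome_mean_yields_nothing(self):
        win = windows_frame([GM] * 50, [True] * 50)
        assert detect_roh(win, GM) == []

    def test_interior_zero_stretch_trimmed_to_its_bins(self):
        """Bins 5-20 at zero het inside 30 average bins give one ROH
        covering exactly bins 5-20 (160 kb, medium class)."""
        het = np.full(30, GM)
        het[5:21] = 0.0
        (roh,) = detect_roh(windows_frame(het, [True] * 30), GM)
        assert (roh.start, roh.end) == (50_000, 210_000)
        assert roh.length == 160_000
        assert roh.size_class == "medium"

    def test_relaxed_interior_bin_does_not_break_roh(self):
        """One bin at 1.9x the mean inside 40 zero bins is tolerated as
        long as the candidate's overall mean stays under a third of the
        genome mean."""
        het = np.zeros(44)
        het[:2] = GM
        het[-2:] = GM
        het[22] = 1.9 * GM
        (roh,) = detect_roh(windows_frame(het, [True] * 44), GM)
        assert (roh.start, roh.end) == (20_000, 420_000)

    def test_bin_above_relax_limit_breaks_roh(self):
        het = np.zeros(44)
        het[22] = 2.5 * GM  # above 2x the mean: never bridged
        rohs = detect_roh(windows_frame(het, [True] * 44), GM)
        assert len(rohs) == 2
        assert rohs[0].end <= 220_000 < rohs[1].start

    def test_unusable_bins_bridged_but_not_covered(self):
        usable = [True] * 30
        for i in range(12, 15):
            usable[i] = False
        het = np.zeros(30)
        (roh,) = detect_roh(windows_frame(het, usable), GM)
        assert roh.length == 300_000
        assert roh.covered_length == 270_000

    def test_insufficient_coverage_dropped(self):
        usable = [True] * 10 + [False] * 20
        het = np.zeros(30)
        params = ROHParams()
        rohs = detect_roh(windows_frame(het, usable), GM, params)
        # covered 100 kb of 300 kb span < 2/3 after bridging; the trim
        # step cuts the trailing unusable bins so the surviving run is
        # fully covered
        for r in rohs:
            assert r.covered_length / r.length >= params.min_covered_fraction

    def test_too_few_usable_bins_gives_empty(self):
        win = windows_frame([0.0] * 8, [True] * 8)
        assert detect_roh(win, GM) == []

    def test_rejects_nonpositive_genome_mean(self):
        with pytest.raises(ValueError):
            detect_roh(windows_frame([0.0] * 20, [True] * 20), 0.0)


class TestClassify:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (99_999, "short"),
            (100_000, "medium"),
            (2_999_999, "medium"),
            (3_000_000, "long"),  # >= 3 Mb convention
            (5_000_000, "long"),
        ],
    )
    def test_size_classes(self, length, expected):
        assert classify_roh(length) == expected

    def test_strict_long_boundary_configurable(self):
        params = ROHParams(long_boundary_inclusive=False)
        assert classify_roh(3_000_000, params) == "medium"

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            classify_roh(0)


class TestGenomeFraction:
    CHROMS = [("chr1", 1_000_000)]

    def _roh(self, start, end, cls=None):
        length = end - start
        return ROH("chr1", start, end, length, length, 0.0, cls or classify_roh(length))

    def test_empty(self):
        assert genome_fraction([], self.CHROMS) == 0.0

    def test_full_cover(self):
        assert genome_fraction([self._roh(0, 1_000_000)], self.CHROMS) == 1.0

    def test_class_fractions_sum_to_any(self):
        rohs = [
            self._roh(0, 50_000),
            self._roh(100_000, 400_000),
            self._roh(500_000, 900_000),
        ]
        total = sum(
            genome_fraction(rohs, self.CHROMS, c) for c in ("short", "medium", "long")
        )
        assert total == pytest.approx(genome_fraction(rohs, self.CHROMS, "any"))

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            genome_fraction([self._roh(0, 200_000), self._roh(100_000, 300_000)], self.CHROMS)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown size class"):
            genome_fraction([], self.CHROMS, "giant")


def _random_instance(rng, n_bins):
    """Het tracks mixing lows, background, relaxable spikes and gaps."""
    levels = np.array([0.0, 0.1 * GM, 0.5 * GM, GM, 1.9 * GM, 2.5 * GM])
    het = rng.choice(levels, size=n_bins, p=[0.35, 0.15, 0.1, 0.25, 0.1, 0.05])
    usable = rng.random(n_bins) > 0.1
    return het, usable


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(150):
            n_bins = int(rng.integers(12, 200))
            het, usable = _random_instance(rng, n_bins)
            got = detect_roh(windows_frame(het, usable), GM)
            want = oracle_detect(het.tolist(), usable.tolist(), GM)
            assert len(got) == len(want), (het.tolist(), usable.tolist())
            for r, w in zip(got, want):
                assert r.start == w["start_bin"] * 10_000
                assert r.end == w["end_bin"] * 10_000
                assert r.covered_length == w["covered"]
                assert r.mean_het == pytest.approx(w["mean_het"])
            checked += len(want)
        assert checked > 50  # the instances genuinely exercise detection


class TestRecovery:
    def test_planted_tracts_recovered(self):
        """Seeded simulation: base-level recall/precision >= 0.9 and the
        called genome fraction within 0.02 of the planted truth."""
        from rohdel import hetwin
        from rohdel.simdata import GroupSpec, SimConfig, simulate_population

        length = 20_000_000
        cfg = SimConfig(
            seed=17,
            chrom_lengths=(("chr1", length),),
            groups=(GroupSpec("nb", 4, roh_rate_per_mb=0.15,
                              roh_length_log_mean=np.log(2.5e6),
                              roh_length_log_sd=0.45),),
            n_sites_per_class={"synonymous": 160_000},
            sfs_shape={"synonymous": (0.5, 0.5)},
        )
        sim = simulate_population(cfg)
        pos = sim.sites["pos0"].to_numpy()
        for j, s in enumerate(sim.samples):
            truth = [(a, b) for _, a, b in sim.truth.planted_tracts[s]]
            if not truth:
                continue
            win = hetwin.window_heterozygosity(
                pos, sim.genotypes[:, j] == 1, sim.depths[:, j],
                cfg.mean_coverage, "chr1", length,
                wellcovered=sim.wellcovered[s]["chr1"],
            )
            rohs = detect_roh(win, hetwin.genome_mean_het(win))
            det = [(r.start, r.end) for r in rohs]
            inter = sum(
                max(0, min(e1, e2) - max(s1, s2))
                for s1, e1 in det
                for s2, e2 in truth
            )
            truth_len = sum(e - s for s, e in truth)
            det_len = sum(e - s for s, e in det)
            assert inter / truth_len >= 0.9
            assert inter / det_len >= 0.9
            g_true = truth_len / length
            g_det = genome_fraction(rohs, cfg.chrom_lengths)
            assert abs(g_det - g_true) < 0.02
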