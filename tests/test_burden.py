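"""Burden statistics: LRT, chi-square conversion, load, SFS, enrichment."""

import numpy as np
import pandas as pd
import pytest
from intervaltree import IntervalTree

from rohdel.burden import (
    chisq1_pvalue,
    daf_spectrum,
    daf_spectra_by_class,
    enrichment_correlation,
    genetic_load,
    lrt_homozygosity,
    positions_in_intervals,
    roh_enrichment,
    site_daf,
)
from rohdel.rohfind import ROH, classify_roh


def _counts(xa, na, xb, nb):
    rows = [("a", "A", x, n) for x, n in zip(xa, na)]
    rows += [("b", "B", x, n) for x, n in zip(xb, nb)]
    return pd.DataFrame(rows, columns=["sample", "group", "x", "n"])


class TestLRT:
    def test_identical_groups_give_null(self):
        res = lrt_homozygosity(_counts([3, 5], [10, 10], [4, 4], [10, 10]), "A", "B")
        assert res.lam == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_example_closed_form(self):
        """x=0/2 vs x=2/2: pooled p=1/2 gives ll0=-4 ln2, boundary MLEs
        give ll1=0, so Lambda = 8 ln 2."""
        res = lrt_homozygosity(_counts([0], [2], [2], [2]), "A", "B")
        assert res.lam == pytest.approx(8 * np.log(2), rel=1e-12)
        assert res.p_group == {"A": 0.0, "B": 1.0}
        assert res.loglik_alt == pytest.approx(0.0)

    def test_lambda_consistent_with_stored_logliks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(1, 50, size=6)
            x = rng.binomial(n, rng.random())
            res = lrt_homozygosity(
                _counts(x[:3], n[:3], x[3:], n[3:]), "A", "B"
            )
            assert res.lam == pytest.approx(
                -2 * (res.loglik_null - res.loglik_alt), abs=1e-10
            )
            assert res.loglik_alt >= res.loglik_null - 1e-12

    def test_mles_match_grid_search(self):
        """Analytic MLEs maximize the likelihood: a 1e-6-step grid search
        over p finds no better point, on 100 random small inputs."""
        rng = np.random.default_rng(42)
        grid = np.linspace(1e-6, 1 - 1e-6, 10**6)
        log_g, log_1mg = np.log(grid), np.log1p(-grid)
        for _ in range(100):
            n = rng.integers(1, 30, size=4)
            x = rng.binomial(n, rng.random())
            res = lrt_homozygosity(_counts(x[:2], n[:2], x[2:], n[2:]), "A", "B")
            for (xs, ns), p_hat in [
                ((x.sum(), n.sum()), res.p_pooled),
                ((x[:2].sum(), n[:2].sum()), res.p_group["A"]),
                ((x[2:].sum(), n[2:].sum()), res.p_group["B"]),
            ]:
                ll = xs * log_g + (ns - xs) * log_1mg
                best = grid[np.argmax(ll)]
                assert abs(p_hat - best) < 2e-6

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no genotypes"):
            lrt_homozygosity(_counts([1], [2], [], []), "A", "B")

    def test_x_bounds_validated(self):
        with pytest.raises(ValueError):
            lrt_homozygosity(_counts([3], [2], [1], [2]), "A", "B")


class TestChisq:
    @pytest.mark.parametrize(
        "lam, expected, rel",
        [
            (30.440, 3.44e-08, 0.01),
            (0.118, 0.730, 0.01),
            (1.202, 0.272, 0.01),
            # p printed to 2 significant figures from the unrounded
            # statistic; 5.843 itself converts to 0.0156
            (5.843, 0.015, 0.05),
        ],
    )
    def test_reported_conversions(self, lam, expected, rel):
        """Published Lambda/p pairs for the four functional classes."""
        assert chisq1_pvalue(lam) == pytest.approx(expected, rel=rel)

    def test_zero_statistic(self):
        assert chisq1_pvalue(0.0) == 1.0

    def test_monotone_decreasing(self):
        lams = np.linspace(0, 20, 50)
        ps = [chisq1_pvalue(l) for l in lams]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_erfc_closed_form(self):
        from scipy.special import erfc

        for lam in (0.5, 2.0, 10.0):
            assert chisq1_pvalue(lam) == pytest.approx(erfc(np.sqrt(lam / 2)))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chisq1_pvalue(-0.1)


def _state_counts(rows):
    return pd.DataFrame(rows, columns=["sample", "functional_class", "state", "count"])


class TestGeneticLoad:
    def test_hand_ratios_and_group_mean(self):
        rows = []
        for s, d_het, s_het in [("i1", 3, 12), ("i2", 2, 10), ("i3", 4, 10)]:
            rows += [
                (s, "deleterious", "het", d_het),
                (s, "synonymous", "het", s_het),
                (s, "deleterious", "hom_der", 0),
                (s, "synonymous", "hom_der", 5),
            ]
        res = genetic_load(_state_counts(rows), {"i1": "g1", "i2": "g2", "i3": "g2"})
        per = res.per_individual.set_index("sample")
        assert per.loc["i1", "het_load"] == pytest.approx(0.25)
        assert per.loc["i2", "het_load"] == pytest.approx(0.2)
        assert per.loc["i1", "hom_load"] == 0.0
        g2 = res.group_means.set_index("group").loc["g2"]
        assert g2["het_load"] == pytest.approx((0.2 + 0.4) / 2)

    def test_zero_synonymous_flagged_and_excluded(self):
        rows = [
            ("i1", "deleterious", "het", 3),
            ("i1", "synonymous", "het", 0),
            ("i2", "deleterious", "het", 1),
            ("i2", "synonymous", "het", 10),
        ]
        res = genetic_load(_state_counts(rows), {"i1": "g", "i2": "g"})
        per = res.per_individual.set_index("sample")
        assert np.isnan(per.loc["i1", "het_load"])
        assert res.group_means.set_index("group").loc["g", "het_load"] == pytest.approx(0.1)


class TestSFS:
    def test_hand_binning(self):
        counts = daf_spectrum([0.05, 0.05, 0.55, 1.0])
        assert counts.tolist() == [2, 0, 0, 0, 0, 1, 0, 0, 0, 1]

    def test_fixed_derived_in_closed_last_bin(self):
        assert daf_spectrum([1.0, 1.0]).tolist()[-1] == 2

    def test_conservation_and_permutation_invariance(self):
        rng = np.random.default_rng(7)
        codes = rng.integers(-1, 3, size=(500, 12))
        daf = site_daf(codes)
        assert daf_spectrum(daf).sum() == np.sum(~np.isnan(daf))
        perm = rng.permutation(12)
        assert np.allclose(site_daf(codes[:, perm]), daf, equal_nan=True)

    def test_all_missing_site_skipped(self):
        codes = np.array([[1, 1], [-1, -1]])
        daf = site_daf(codes)
        assert np.isnan(daf[1])
        assert daf_spectrum(daf).sum() == 1

    def test_spectra_by_class_keyed(self):
        res = daf_spectra_by_class([0.05, 0.95], ["deleterious", "synonymous"])
        assert res.counts["deleterious"][0] == 1
        assert res.counts["synonymous"][-1] == 1


def _mk_roh(chrom, start, end):
    return ROH(chrom, start, end, end - start, end - start, 0.0,
               classify_roh(end - start))


class TestEnrichment:
    CHROMS = [("chr1", 10_000_000)]

    def test_no_rohs(self):
        variants = {"i1": pd.DataFrame(
            {"chrom": ["chr1"] * 3, "pos0": [10, 20, 30], "damaging": [True, False, False]}
        )}
        rows = roh_enrichment(variants, {"i1": []}, self.CHROMS)
        assert (rows["count_in_roh"] == 0).all()
        assert (rows["fraction_in_roh"].dropna() == 0).all()

    def test_membership_hand_case(self):
        rohs = [_mk_roh("chr1", 1_000_000, 2_000_000)]
        variants = {"i1": pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos0": [1_500_000, 2_500_000],
             "damaging": [True, True]}
        )}
        rows = roh_enrichment(variants, {"i1": rohs}, self.CHROMS).set_index(
            ["size_class", "category"]
        )
        r = rows.loc[("any", "damaging")]
        assert (r["count_in_roh"], r["count_outside"]) == (1, 1)

    def test_whole_genome_roh(self):
        rohs = [_mk_roh("chr1", 0, 10_000_000)]
        variants = {"i1": pd.DataFrame(
            {"chrom": ["chr1"] * 4, "pos0": [1, 2, 3, 4],
             "damaging": [True, True, False, False]}
        )}
        rows = roh_enrichment(variants, {"i1": rohs}, self.CHROMS)
        any_rows = rows[rows["size_class"] == "any"]
        assert (any_rows["fraction_in_roh"] == 1.0).all()
        assert (any_rows["G"] == 1.0).all()

    def test_membership_matches_intervaltree_oracle(self):
        rng = np.random.default_rng(11)
        # random disjoint intervals on two chromosomes
        rohs = []
        for chrom in ("chr1", "chr2"):
            edges = np.sort(rng.choice(10_000_000, size=60, replace=False))
            for s, e in zip(edges[::2], edges[1::2]):
                if e > s:
                    rohs.append(_mk_roh(chrom, int(s), int(e)))
        trees = {}
        for r in rohs:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end)
        chroms = rng.choice(["chr1", "chr2"], size=100_000)
        pos = rng.integers(0, 10_000_000, size=100_000)
        got = positions_in_intervals(chroms, pos, rohs, "any")
        want = np.array([bool(trees[c][p]) for c, p in zip(chroms, pos)])
        assert np.array_equal(got, want)


class TestEnrichmentCorrelation:
    def _rows(self, pts, size_class="any", category="damaging"):
        return pd.DataFrame(
            [
                {"sample": f"i{k}", "size_class": size_class, "category": category,
                 "fraction_in_roh": y, "G": x}
                for k, (x, y) in enumerate(pts)
            ]
        )

    def test_perfect_positive(self):
        r, p = enrichment_correlation(
            self._rows([(0.1, 0.2), (0.2, 0.4), (0.3, 0.6)]), "any", "damaging"
        )
        assert r == pytest.approx(1.0)

    def test_perfect_negative(self):
        r, _ = enrichment_correlation(
            self._rows([(0.1, 0.9), (0.5, 0.5), (0.9, 0.1)]), "any", "damaging"
        )
        assert r == pytest.approx(-1.0)

    def test_undefined_on_constant_input(self):
        r, p = enrichment_correlation(
            self._rows([(0.1, 0.5), (0.2, 0.5), (0.3, 0.5)]), "any", "damaging"
        )
        assert np.isnan(r) and np.isnan(p)

    def test_undefined_below_three_points(self):
        r, _ = enrichment_correlation(self._rows([(0.1, 0.2), (0.2, 0.3)]), "any", "damaging")
        assert np.isnan(r)
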