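"""Phenotype-class splits, marker tests, window scan, environment links."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermadapt import association, simulate
from thermadapt.association import (class_coverage_filter, fisher_exact_2x2,
                                    local_score_segments,
                                    maf_temperature_association, mantel,
                                    marker_class_tests, split_phenotype_classes,
                                    structure_pca, summarize_regime,
                                    window_scan)

from conftest import make_matrix


def summaries_frame(values_by_pop):
    rows = []
    for pop, vals in values_by_pop.items():
        for i, v in enumerate(vals):
            rows.append({"fish_id": f"{pop}_{i:02d}", "population": pop,
                         "ecotype": "desert", "fh20": v})
    return pd.DataFrame(rows)


class TestPhenotypeClasses:
    def test_even_count_splits_in_half(self):
        labels = split_phenotype_classes(
            summaries_frame({"p1": [1.0, 2.0, 3.0, 4.0]}), "fh20")
        low = set(labels.loc[labels["phen_class"] == "low", "fh20"])
        assert low == {1.0, 2.0}

    def test_odd_count_median_goes_low(self):
        labels = split_phenotype_classes(
            summaries_frame({"p1": [5.0, 1.0, 4.0, 2.0, 3.0]}), "fh20")
        low = set(labels.loc[labels["phen_class"] == "low", "fh20"])
        assert low == {1.0, 2.0, 3.0}

    def test_populations_split_internally_before_pooling(self):
        labels = split_phenotype_classes(
            summaries_frame({"p1": [1.0, 2.0], "p2": [10.0, 20.0]}), "fh20")
        # each population contributes one low and one high fish even though
        # all of p2's values exceed p1's
        for pop in ("p1", "p2"):
            sub = labels[labels["population"] == pop]
            assert set(sub["phen_class"]) == {"low", "high"}

    def test_value_ties_break_by_fish_id(self):
        frame = summaries_frame({"p1": [2.0, 2.0, 2.0, 2.0]})
        l1 = split_phenotype_classes(frame, "fh20")
        l2 = split_phenotype_classes(frame.sample(frac=1, random_state=0), "fh20")
        merged = l1.merge(l2, on="fish_id", suffixes=("_a", "_b"))
        assert (merged["phen_class_a"] == merged["phen_class_b"]).all()

    def test_trait_absent_for_population_is_an_error(self):
        frame = summaries_frame({"p1": [1.0, 2.0]})
        frame.loc[frame["population"] == "p1", "fh20"] = np.nan
        with pytest.raises(ValueError):
            split_phenotype_classes(frame, "fh20")


class TestCoverageFilter:
    def test_threshold_is_inclusive(self):
        from thermadapt.genotypes import MISSING
        calls = np.ones((100, 2), dtype=np.int8)
        calls[:26, 0] = MISSING   # 74% called -> dropped
        calls[:25, 1] = MISSING   # 75% called -> kept
        g = make_matrix(calls, ["a"] * 100)
        keep = class_coverage_filter(g, np.arange(100), min_rate=0.75)
        np.testing.assert_array_equal(keep, [False, True])

    def test_empty_fish_set_is_an_error(self):
        g = make_matrix(np.ones((4, 2), dtype=np.int8), ["a"] * 4)
        with pytest.raises(ValueError):
            class_coverage_filter(g, np.array([], dtype=int))


class TestFisherExact:
    def test_balanced_table_gives_one(self):
        assert fisher_exact_2x2(np.array([[[10, 10], [10, 10]]]))[0] == 1.0

    def test_extreme_table_matches_enumeration(self):
        table = np.array([[20, 0], [0, 20]])
        p = fisher_exact_2x2(table[None])[0]
        # enumerate the hypergeometric outcomes no more likely than observed
        pm = [stats.hypergeom.pmf(x, 40, 20, 20) for x in range(21)]
        expected = sum(v for v in pm if v <= pm[20] * (1 + 1e-7))
        assert p == pytest.approx(expected, rel=1e-10)

    def test_matches_scipy_on_random_tables(self, rng):
        tables = rng.integers(0, 30, size=(200, 2, 2))
        mine = fisher_exact_2x2(tables)
        ref = np.array([stats.fisher_exact(t)[1] for t in tables])
        np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_null_permutations_not_anticonservative(self, rng):
        """With labels permuted on null genotypes, small p-values appear no
        more often than their nominal rate (Fisher p is discrete and
        conservative)."""
        calls = rng.binomial(2, 0.4, size=(40, 300)).astype(np.int8)
        g = make_matrix(calls, ["a"] * 40)
        pvals = []
        for _ in range(5):
            perm = rng.permutation(40)
            labels = pd.DataFrame({
                "fish_id": g.individuals["individual_id"],
                "population": "a", "ecotype": "a",
                "phen_class": np.where(np.isin(np.arange(40), perm[:20]),
                                       "low", "high"),
            })
            pvals.append(marker_class_tests(g, labels)["fisher_p"].to_numpy())
        pvals = np.concatenate(pvals)
        for alpha in (0.01, 0.05, 0.2):
            assert (pvals <= alpha).mean() <= alpha + 0.02


class TestWindowScan:
    @staticmethod
    def markers(chrom, pos, p, w, a=None, abc=None):
        n = len(pos)
        return pd.DataFrame({
            "chrom": chrom if not np.isscalar(chrom) else [chrom] * n,
            "pos_bp": pos,
            "fisher_p": p,
            "weight": w,
            "comp_a": a if a is not None else np.zeros(n),
            "comp_abc": abc if abc is not None else np.ones(n),
        })

    def test_single_marker_window_returns_marker_p(self):
        m = self.markers("chr1", [5000], [0.037], [6.0])
        win = window_scan(m)
        assert np.allclose(win["combined_p"], 0.037)

    def test_two_half_p_markers_combine_to_half(self):
        m = self.markers("chr1", [5000, 5100], [0.5, 0.5], [3.0, 3.0])
        win = window_scan(m)
        assert np.allclose(win["combined_p"], 0.5)

    def test_hand_arithmetic_oracle(self):
        rng = np.random.default_rng(8)
        pos = np.sort(rng.integers(0, 9000, 10))
        p = rng.uniform(0.001, 0.9, 10)
        w = np.sqrt(rng.integers(10, 40, 10).astype(float))
        m = self.markers("chr1", pos, p, w)
        win = window_scan(m)
        full = win[(win["n_markers"] == 10)].iloc[0]
        z = stats.norm.isf(p)
        Z = (w * z).sum() / np.sqrt((w ** 2).sum())
        assert full["combined_p"] == pytest.approx(stats.norm.sf(Z), rel=1e-12)

    def test_window_fst_is_ratio_of_sums(self):
        a = np.array([0.02, 0.05])
        abc = np.array([0.1, 0.4])
        m = self.markers("chr1", [100, 200], [0.5, 0.5], [1.0, 1.0], a, abc)
        win = window_scan(m)
        covers_both = win[win["n_markers"] == 2]
        assert np.allclose(covers_both["window_fst"], a.sum() / abc.sum())

    def test_shift_equivariance_and_emitted_window_geometry(self):
        # positions beyond one window size, so no window start clamps at 0
        m1 = self.markers("chr1", [11000, 12500, 24000], [0.1, 0.2, 0.3],
                          [2.0, 2.0, 2.0])
        m2 = m1.assign(pos_bp=m1["pos_bp"] + 40_000)
        w1, w2 = window_scan(m1), window_scan(m2)
        assert len(w1) == len(w2)
        np.testing.assert_array_equal(w1["start"] + 40_000, w2["start"])
        assert ((w1["end"] - w1["start"]) == 10_000).all()
        assert (w1["start"] % 200 == 0).all()
        assert (w1["n_markers"] >= 1).all()

    def test_unsorted_input_is_an_error(self):
        m = self.markers("chr1", [3000, 1000], [0.1, 0.2], [1.0, 1.0])
        with pytest.raises(ValueError):
            window_scan(m)


class TestLocalScore:
    def test_flat_ones_give_no_segments(self):
        assert local_score_segments(np.ones(50), xi=1.0).empty

    def test_single_strong_marker_scores_five(self):
        p = np.ones(21)
        p[10] = 1e-6
        seg = local_score_segments(p, xi=1.0)
        assert len(seg) == 1
        assert seg["score"].iloc[0] == pytest.approx(5.0)
        assert seg["start_idx"].iloc[0] <= 10 <= seg["end_idx"].iloc[0]

    def test_matches_exhaustive_subsegment_maximum(self, rng):
        """Peak Lindley score equals the best subsegment sum (n <= 12)."""
        for _ in range(25):
            p = rng.uniform(0.001, 1.0, size=rng.integers(3, 13))
            h = -np.log10(p) - 1.0
            seg = local_score_segments(p, xi=1.0)
            best = max((h[i:j + 1].sum()
                        for i in range(len(h)) for j in range(i, len(h))),
                       default=0.0)
            got = seg["score"].max() if len(seg) else 0.0
            assert got == pytest.approx(max(best, 0.0), abs=1e-12)

    def test_nonpositive_xi_is_an_error(self):
        with pytest.raises(ValueError):
            local_score_segments(np.ones(5), xi=0.0)


class TestMafTemperature:
    def test_perfectly_linear_locus_ranks_first(self):
        temps = pd.Series([14.0, 16.0, 18.0, 20.0],
                          index=["a", "b", "c", "d"])
        maf = pd.DataFrame(
            {"a": [0.1, 0.3], "b": [0.2, 0.31], "c": [0.3, 0.28],
             "d": [0.4, 0.33]}, index=["lin", "flat"])
        out = maf_temperature_association(maf, temps, top_n=2)
        assert out["locus_id"].iloc[0] == "lin"
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_constant_locus_has_zero_slope_and_last_rank(self):
        temps = pd.Series([14.0, 17.0, 20.0], index=list("abc"))
        maf = pd.DataFrame({"a": [0.2, 0.1], "b": [0.2, 0.25], "c": [0.2, 0.4]},
                           index=["flat", "lin"])
        out = maf_temperature_association(maf, temps)
        assert out["locus_id"].iloc[-1] == "flat"
        assert out.set_index("locus_id").loc["flat", "slope"] == pytest.approx(0.0)

    def test_planted_clinal_loci_occupy_top_ranks(self):
        """Within an outlier-sized candidate set (the regression's input in
        the analysis), planted clinal loci rank above neutral loci."""
        rng = np.random.default_rng(99)
        wins = 0
        for seed in range(10):
            truth = simulate.default_truth(n_loci=400, n_causal=4, seed=seed)
            g, truth = simulate.simulate_island_genotypes(n_loci=400, truth=truth)
            maf = association.minor_allele_frequencies(g)
            neutral = maf.index[~maf.index.isin(truth.causal_locus_ids)]
            candidates = list(truth.causal_locus_ids) + list(
                rng.choice(neutral, 36, replace=False))
            temps = pd.Series(simulate.DEFAULT_POP_TEMPS,
                              index=list(simulate.DEFAULT_POPS))
            top = maf_temperature_association(maf.loc[candidates], temps,
                                              top_n=4)
            wins += len(set(top["locus_id"]) & set(truth.causal_locus_ids)) >= 3
        assert wins >= 9

    def test_constant_temperature_is_an_error(self):
        temps = pd.Series([15.0, 15.0, 15.0], index=list("abc"))
        maf = pd.DataFrame({"a": [0.1], "b": [0.2], "c": [0.3]}, index=["x"])
        with pytest.raises(ValueError):
            maf_temperature_association(maf, temps)


class TestMantel:
    def test_identical_matrices_give_perfect_correlation(self):
        rng = np.random.default_rng(0)
        a = rng.random((7, 7))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        r, p = mantel(a, a, n_perm=999, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 1000, abs=5e-3)

    def test_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel
        rng = np.random.default_rng(2)
        a = rng.random((8, 8)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = 1.5 * a + rng.random((8, 8)) * 0.05
        b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        r, _ = mantel(a, b, n_perm=99, seed=0)
        r_ref, _, _ = skbio_mantel(DistanceMatrix(a), DistanceMatrix(b),
                                   permutations=99, alternative="greater")
        assert r == pytest.approx(float(r_ref), abs=1e-12)

    def test_seeded_permutation_is_reproducible(self):
        rng = np.random.default_rng(3)
        a = rng.random((6, 6)); a = (a + a.T) / 2; np.fill_diagonal(a, 0)
        b = rng.random((6, 6)); b = (b + b.T) / 2; np.fill_diagonal(b, 0)
        assert mantel(a, b, 499, seed=9) == mantel(a, b, 499, seed=9)

    def test_asymmetric_input_is_an_error(self):
        bad = np.arange(9.0).reshape(3, 3)
        with pytest.raises(ValueError):
            mantel(bad, bad)


class TestStructurePca:
    def test_diverged_demes_separate_on_pc1(self, two_deme_matrix):
        coords, ratio = structure_pca(two_deme_matrix)
        north = coords[coords["population"] == "north"]["PC1"]
        south = coords[coords["population"] == "south"]["PC1"]
        assert north.max() < south.min() or south.max() < north.min()
        assert ratio[0] == max(ratio)

    def test_without_missing_equals_plain_pca(self, two_deme_matrix):
        g = two_deme_matrix
        coords, _ = structure_pca(g)
        X = g.calls.astype(float)
        X = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        plain = U[:, 0] * S[0]
        got = coords["PC1"].to_numpy()
        # same up to overall sign
        err = min(np.abs(got - plain).max(), np.abs(got + plain).max())
        assert err < 1e-9

    def test_all_missing_locus_contributes_nothing(self, two_deme_matrix):
        from thermadapt.genotypes import MISSING
        g = two_deme_matrix
        calls = g.calls.copy()
        calls[:, 0] = MISSING
        g2 = make_matrix(calls, list(g.individuals["population"]))
        c1, _ = structure_pca(g.subset_loci(np.arange(1, g.n_loci)))
        c2, _ = structure_pca(g2)
        np.testing.assert_allclose(c1["PC1"], c2["PC1"], atol=1e-9)


def test_regime_summary_constant_series():
    p = simulate.RegimeParams(mean_c=15.0, seasonal_amplitude_c=0,
                              diurnal_amplitude_c=0, noise_sd_c=0)
    s = simulate.simulate_temperature_series(p)
    reg = summarize_regime(s)
    assert reg.mean_summer_temp == pytest.approx(15.0)
    assert reg.max_summer_temp == pytest.approx(15.0)
    assert reg.max_diurnal_range == pytest.approx(0.0)


def test_regime_summary_requires_window_coverage():
    p = simulate.RegimeParams(start="2015-06-01", end="2015-06-15")
    s = simulate.simulate_temperature_series(p)
    with pytest.raises(ValueError):
        summarize_regime(s, ("2016-07-01", "2016-08-31"))
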