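"""Quantile chi-like statistic, permutation null, and BH adjustment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from convergene import msea
from convergene._stats import bh_fdr


# ------------------------------------------------------------------ oracles

def direct_count_profile(module_genes, gene_markers, retained, cutpoints,
                         kappa=1.0):
    """Independent direct-count implementation of (O, E, chi).

    Builds the ranking by explicit sorting and counts set intersections
    per cutpoint; shares no code with the package internals.
    """
    ranked = [m for _, m in sorted(zip(retained["PVALUE"],
                                       retained["MARKER"]))]
    big_m = len(ranked)
    mod = sorted({m for g in module_genes for m in gene_markers.get(g, [])
                  if m in set(ranked)})
    obs, exp = [], []
    for q in cutpoints:
        k = math.floor((1.0 - q) * big_m + 1e-9)
        top = set(ranked[:k])
        obs.append(sum(1 for m in mod if m in top))
        exp.append(len(mod) * k / big_m)
    chi = sum((o - e) / math.sqrt(e + kappa) for o, e in zip(obs, exp))
    return obs, exp, chi


def random_micro_study(rng):
    n_markers = int(rng.integers(10, 51))
    markers = [f"m{i}" for i in range(n_markers)]
    retained = pd.DataFrame({
        "MARKER": markers,
        "PVALUE": rng.random(n_markers),
    })
    n_genes = int(rng.integers(5, 15))
    gene_markers = {
        f"g{j}": list(rng.choice(markers, size=int(rng.integers(1, 6)),
                                 replace=False))
        for j in range(n_genes)}
    n_modules = int(rng.integers(1, 9))
    modules = {f"M{k}": list(rng.choice(list(gene_markers), replace=False,
                                        size=int(rng.integers(2, n_genes))))
               for k in range(n_modules)}
    return retained, gene_markers, modules


class TestCutpoints:
    def test_formula(self):
        cps = msea.quantile_cutpoints(100, 10)
        assert cps[0] == 0.5 and np.isclose(cps[-1], 0.99)
        assert np.allclose(np.diff(cps), (0.99 - 0.5) / 9)

    def test_two_points(self):
        assert np.allclose(msea.quantile_cutpoints(10, 2), [0.5, 0.9])

    @pytest.mark.parametrize("mu", [1, 2])
    def test_degenerate_range_rejected(self, mu):
        with pytest.raises(ValueError, match="degenerate"):
            msea.quantile_cutpoints(mu, 10)


class TestPositiveCounts:
    def ranking(self, n):
        return msea.marker_ranking(pd.DataFrame({
            "MARKER": [f"m{i:03d}" for i in range(n)],
            "PVALUE": (np.arange(n) + 1) / n}))

    def test_arithmetic_example(self):
        rank = self.ranking(100)
        module = [f"m{i:03d}" for i in range(5)] + \
            [f"m{i:03d}" for i in range(50, 65)]  # 5 in top 10, 20 total
        o, e = msea.positive_counts(module, rank, 0.9)
        assert (o, e) == (5, 2.0)

    def test_saturation(self):
        rank = self.ranking(40)
        module = list(rank["MARKER"])
        for q in msea.quantile_cutpoints(10, 5):
            o, e = msea.positive_counts(module, rank, q)
            k = math.floor((1 - q) * 40 + 1e-9)
            assert o == k and np.isclose(e, k)

    def test_unknown_marker_is_error(self):
        with pytest.raises(ValueError):
            msea.positive_counts(["zz"], self.ranking(10), 0.5)

    def test_resampled_mean_matches_expectation(self, rng):
        # random 30-of-200 marker subsets: E[O] = E (hypergeometric mean)
        rank = self.ranking(200)
        markers = list(rank["MARKER"])
        q = 0.9
        os, es = [], []
        for _ in range(1000):
            module = rng.choice(markers, size=30, replace=False)
            o, e = msea.positive_counts(module, rank, q)
            os.append(o)
            es.append(e)
        se = np.std(os, ddof=1) / np.sqrt(len(os))
        assert abs(np.mean(os) - es[0]) < 3 * se


class TestChiStatistic:
    def test_zero_when_observed_equals_expected(self):
        assert msea.chi_statistic([3, 7, 1], [3, 7, 1]) == 0.0

    def test_single_point_arithmetic(self):
        assert msea.chi_statistic([5], [3], kappa=1.0) == pytest.approx(1.0)

    def test_deficits_subtract(self):
        assert msea.chi_statistic([1], [3], kappa=1.0) == pytest.approx(-1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            msea.chi_statistic([1, 2], [1])

    def test_strictly_increasing_in_observed(self):
        e = [2.0, 4.0]
        low = msea.chi_statistic([2, 4], e)
        high = msea.chi_statistic([3, 4], e)
        assert high > low


class TestNullDistribution:
    def build_index(self, rng, n_markers=200, n_genes=40):
        retained = pd.DataFrame({
            "MARKER": [f"m{i}" for i in range(n_markers)],
            "PVALUE": rng.random(n_markers)})
        ranking = msea.marker_ranking(retained)
        gm = {f"g{j}": list(rng.choice(retained["MARKER"], replace=False,
                                       size=int(rng.integers(1, 6))))
              for j in range(n_genes)}
        return msea.TissueIndex(gm, ranking)

    def test_seeded_determinism(self, rng):
        index = self.build_index(rng)
        cps = msea.quantile_cutpoints(10, 10)
        a = msea.null_distribution(8, index, cps, 1.0, 200,
                                   np.random.default_rng(5))
        b = msea.null_distribution(8, index, cps, 1.0, 200,
                                   np.random.default_rng(5))
        assert a[0] == b[0] and a[1] == b[1]

    def test_null_mean_near_zero_on_pure_null(self, rng):
        # E[O] = E by construction, so E[chi] ~ 0 over the joint randomness
        # of map and gene sampling; a single fixed map carries an O(1)
        # offset that the Z-standardization absorbs, so the check averages
        # over maps.
        cps = msea.quantile_cutpoints(12, 10)
        means = []
        for _ in range(30):
            index = self.build_index(rng, n_markers=400, n_genes=80)
            mean, _, _ = msea.null_distribution(
                10, index, cps, 1.0, 300, rng)
            means.append(mean)
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 4 * se

    def test_constant_pvalues_give_zero_sd_flag(self):
        retained = pd.DataFrame({"MARKER": [f"m{i}" for i in range(30)],
                                 "PVALUE": [0.5] * 30})
        ranking = msea.marker_ranking(retained)
        gm = {f"g{j}": [f"m{j}"] for j in range(30)}
        index = msea.TissueIndex(gm, ranking)
        cps = msea.quantile_cutpoints(5, 4)
        # every gene has exactly one marker, all ranks distinct but every
        # 5-gene set sees the same *distribution* only if degenerate; force
        # degeneracy with identical marker sets
        gm_deg = {f"g{j}": ["m0"] for j in range(30)}
        index_deg = msea.TissueIndex(gm_deg, ranking)
        mean, sd, _ = msea.null_distribution(5, index_deg, cps, 1.0, 200,
                                             np.random.default_rng(0))
        assert sd == 0.0
        cfg = msea.EnrichmentConfig()
        row = msea.score_module("M", "t", ["g0"], index_deg, cps, cfg, mean,
                                sd)
        assert row["P"] == 1.0 and row["FLAG"] == "null_sd_zero"


class TestOracleEquivalence:
    def test_micro_studies_match_direct_count(self):
        rng = np.random.default_rng(2024)
        cps = msea.quantile_cutpoints(10, 10)
        for _ in range(40):
            retained, gene_markers, modules = random_micro_study(rng)
            ranking = msea.marker_ranking(retained)
            index = msea.TissueIndex(gene_markers, ranking)
            ks = msea.positive_thresholds(cps, len(ranking))
            for mid, genes in modules.items():
                ranks = index.module_ranks(genes)
                if ranks is None:
                    continue
                o_got, e_got = msea._profile(ranks, ks, len(ranking))
                o_want, e_want, chi_want = direct_count_profile(
                    genes, gene_markers, retained, cps)
                assert list(o_got) == o_want
                assert np.allclose(e_got, e_want)
                assert np.isclose(msea.chi_statistic(o_got, e_got, 1.0),
                                  chi_want)


class TestBhFdr:
    def test_examples(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=200))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_step_up_formula(self, p):
        got = bh_fdr(p)
        m = len(p)
        order = np.argsort(np.asarray(p), kind="stable")
        ps = np.asarray(p)[order]
        qs = np.minimum.accumulate(
            (ps * m / np.arange(1, m + 1))[::-1])[::-1]
        want = np.empty(m)
        want[order] = np.minimum(qs, 1.0)
        assert np.allclose(got, want, atol=1e-12)


class TestRunMsea:
    def test_results_sorted_and_fdr_monotone_in_rank(self, mini_run):
        res = mini_run["msea"].results
        assert (res["P"].diff().dropna() >= 0).all()
        assert set(msea.RESULT_COLS) <= set(res.columns)

    def test_planted_modules_recovered(self, mini_run):
        res = mini_run["msea"].results
        planted = set(mini_run["truth"].planted_module_ids)
        assert planted <= set(res[res["FDR"] < 0.05]["MODULE"])
        assert planted <= set(res.head(len(planted) + 2)["MODULE"])

    def test_tissue_counts_cover_all_tissues(self, mini_run):
        counts = mini_run["msea"].tissue_counts
        assert set(counts["TISSUE"]) == set(mini_run["mdf"].gene_markers)
        sig = mini_run["msea"].results.query("FDR < 0.05")
        assert counts["N_SIGNIFICANT"].sum() == len(sig)

    def test_tissue_fdr_family(self, mini_run):
        cfg = msea.EnrichmentConfig(n_permutations=200, seed=11,
                                    fdr_family="tissue")
        bundle_modules = {
            t: {m: g for m, g in mods.items()} for t, mods in
            _modules_from_run(mini_run).items()}
        res = msea.run_msea(mini_run["mdf"].gene_markers,
                            mini_run["mdf"].retained, bundle_modules, cfg)
        for _, sub in res.results.groupby("TISSUE"):
            assert np.allclose(np.sort(sub["FDR"]),
                               np.sort(bh_fdr(sub["P"])))

    def test_undersized_modules_reported_not_dropped(self, mini_run):
        modules = _modules_from_run(mini_run)
        t = sorted(modules)[0]
        modules = {t: dict(modules[t])}
        modules[t]["tiny"] = list(modules[t][next(iter(modules[t]))])[:3]
        cfg = msea.EnrichmentConfig(n_permutations=200, seed=11)
        res = msea.run_msea(mini_run["mdf"].gene_markers,
                            mini_run["mdf"].retained, modules, cfg)
        assert "tiny" in set(res.skipped["MODULE"])
        assert "tiny" not in set(res.results["MODULE"])


def _modules_from_run(mini_run):
    from convergene import io
    from convergene.io import find_tissue_files
    return {t: {m: sorted(g) for m, g in io.read_gmt(p).items()}
            for t, p in find_tissue_files(mini_run["bundle_dir"], "modules",
                                          ".gmt").items()}
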