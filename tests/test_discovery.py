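"""Sample splitting, Spearman screening, rank-sum combination, CpG selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methcorr as mc


def _expr(genes, samples, values):
    return mc.ExpressionMatrix(genes, samples, np.asarray(values, dtype=float))


def _meth(probes, samples, values):
    return mc.MethylationMatrix(probes, samples, np.asarray(values, dtype=float))


class TestSplitSamples:
    def test_sizes_and_disjointness(self):
        ids = [f"S{i}" for i in range(100)]
        split = mc.split_samples(ids, seed=3)
        assert len(split.discovery1) == 40
        assert len(split.discovery2) == 40
        assert len(split.validation) == 20
        all_ids = set(split.discovery1) | set(split.discovery2) | set(split.validation)
        assert all_ids == set(ids)

    @pytest.mark.parametrize("n", [15, 37, 53, 101])
    def test_rounding_rule(self, n):
        split = mc.split_samples([f"S{i}" for i in range(n)], seed=0)
        assert len(split.discovery1) == round(0.4 * n)
        assert len(split.discovery2) == round(0.4 * n)
        assert split.n_samples == n

    def test_deterministic_and_seed_sensitive(self):
        ids = [f"S{i}" for i in range(100)]
        a = mc.split_samples(ids, seed=1)
        b = mc.split_samples(ids, seed=1)
        c = mc.split_samples(ids, seed=2)
        assert a == b
        assert a.discovery1 != c.discovery1

    def test_order_invariant(self):
        ids = [f"S{i}" for i in range(60)]
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(ids))
        assert mc.split_samples(ids, seed=5) == mc.split_samples(shuffled, seed=5)

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="at least 15"):
            mc.split_samples([f"S{i}" for i in range(14)], seed=0)


class TestSpearmanScreen:
    @pytest.mark.parametrize(
        "beta, expected_rho",
        [
            ([0.1, 0.2, 0.3], 1.0),     # monotone increasing
            ([0.3, 0.1, 0.2], -0.5),    # rank covariance -1, variances 2
            ([0.9, 0.5, 0.1], -1.0),    # anti-monotone
        ],
    )
    def test_three_point_examples(self, beta, expected_rho):
        expr = _expr(["G"], ["a", "b", "c"], [[1.0, 2.0, 3.0]])
        meth = _meth(["cg1"], ["a", "b", "c"], [beta])
        rec = mc.spearman_screen(expr, meth, ["a", "b", "c"], 1,
                                 p_threshold=2.0, min_pair_n=3)
        assert len(rec) == 1
        assert rec["rho"].iloc[0] == pytest.approx(expected_rho, abs=1e-12)

    def test_matches_midrank_pearson_oracle(self):
        """rho equals Pearson correlation of mid-ranks (average ranks for
        ties), cross-checked against scipy.stats.spearmanr."""
        rng = np.random.default_rng(2024)
        n = 20
        for _ in range(50):
            x = np.round(rng.normal(size=n), 1)  # rounding induces ties
            y = np.round(rng.normal(size=n), 1)
            expr = _expr(["G"], [f"s{i}" for i in range(n)], [x])
            meth = _meth(["cg1"], [f"s{i}" for i in range(n)], [(y - y.min()) / (np.ptp(y) + 1.0)])
            rec = mc.spearman_screen(expr, meth, expr.sample_ids, 1,
                                     p_threshold=2.0, min_pair_n=15)
            oracle = stats.pearsonr(stats.rankdata(x), stats.rankdata(meth.beta[0]))[0]
            ref = stats.spearmanr(x, meth.beta[0])
            assert rec["rho"].iloc[0] == pytest.approx(oracle, abs=1e-12)
            assert rec["rho"].iloc[0] == pytest.approx(ref.statistic, abs=1e-12)

    def test_pairwise_complete_observations(self):
        """A missing β drops only that sample from that probe's correlation."""
        n = 20
        x = np.arange(n, dtype=float)
        beta = np.linspace(0, 1, n)
        beta_missing = beta.copy()
        beta_missing[3] = np.nan
        samples = [f"s{i}" for i in range(n)]
        expr = _expr(["G"], samples, [x])
        meth = _meth(["full", "gappy"], samples, [beta, beta_missing])
        rec = mc.spearman_screen(expr, meth, samples, 1, p_threshold=2.0, min_pair_n=15)
        rec = rec.set_index("probe")
        assert rec.loc["full", "rho"] == pytest.approx(1.0)
        mask = ~np.isnan(beta_missing)
        oracle = stats.spearmanr(x[mask], beta_missing[mask])
        assert rec.loc["gappy", "rho"] == pytest.approx(oracle.statistic, abs=1e-12)

    def test_zero_variance_vector_skipped(self):
        n = 20
        samples = [f"s{i}" for i in range(n)]
        expr = _expr(["G"], samples, [np.arange(n, dtype=float)])
        meth = _meth(["flat"], samples, [np.full(n, 0.5)])
        rec = mc.spearman_screen(expr, meth, samples, 1, p_threshold=2.0, min_pair_n=15)
        assert rec.empty

    def test_nonsignificant_pairs_discarded(self):
        rng = np.random.default_rng(7)
        n = 40
        samples = [f"s{i}" for i in range(n)]
        expr = _expr(["G"], samples, [rng.normal(size=n)])
        meth = _meth(["cg1"], samples, [rng.uniform(size=n)])
        rec = mc.spearman_screen(expr, meth, samples, 1, p_threshold=0.01)
        assert rec.empty  # independent noise essentially never passes P < 0.01


def _records(rows):
    return pd.DataFrame(rows, columns=["gene", "probe", "rho", "p", "set_label"])


class TestCombineRankSum:
    def test_rank_sum_tie_broken_by_mean_abs_rho(self):
        # A ranks (1, 2), B ranks (2, 1): rank-sums tie at 3; B has larger
        # mean |rho| so it must come first
        r1 = _records([("G", "A", 0.9, 1e-5, 1), ("G", "B", 0.8, 1e-5, 1)])
        r2 = _records([("G", "A", 0.7, 1e-5, 2), ("G", "B", 0.95, 1e-5, 2)])
        ranked = mc.combine_rank_sum(r1, r2)
        assert ranked["probe"].tolist() == ["B", "A"]
        assert ranked["ranksum"].tolist() == [3.0, 3.0]

    def test_lexicographic_final_tie_break(self):
        r1 = _records([("G", "cgB", 0.8, 1e-5, 1), ("G", "cgA", 0.8, 1e-5, 1)])
        r2 = _records([("G", "cgB", 0.8, 1e-5, 2), ("G", "cgA", 0.8, 1e-5, 2)])
        ranked = mc.combine_rank_sum(r1, r2)
        assert ranked["probe"].tolist() == ["cgA", "cgB"]

    def test_probe_in_one_set_only_excluded(self):
        r1 = _records([("G", "A", 0.9, 1e-5, 1)])
        r2 = _records([("G", "B", 0.9, 1e-5, 2)])
        assert mc.combine_rank_sum(r1, r2).empty

    def test_sign_discordant_probe_excluded(self):
        r1 = _records([("G", "A", 0.9, 1e-5, 1)])
        r2 = _records([("G", "A", -0.9, 1e-5, 2)])
        assert mc.combine_rank_sum(r1, r2).empty

    def test_negative_candidates_ranked_ascending_rho(self):
        # "most negatively correlated" first: rho -0.95 outranks -0.5
        r1 = _records([("G", "A", -0.5, 1e-5, 1), ("G", "B", -0.95, 1e-5, 1)])
        r2 = _records([("G", "A", -0.5, 1e-5, 2), ("G", "B", -0.95, 1e-5, 2)])
        ranked = mc.combine_rank_sum(r1, r2)
        assert (ranked["direction"] == "neg").all()
        assert ranked["probe"].tolist() == ["B", "A"]


def _brute_force_selection(ranked, max_per_side):
    """Independent oracle: exhaustive sort of candidates per gene/direction."""
    out = {}
    for (gene, direction), sub in ranked.groupby(["gene", "direction"]):
        rows = sorted(
            sub.itertuples(),
            key=lambda r: (r.ranksum,
                           -(abs(r.rho_set1) + abs(r.rho_set2)) / 2,
                           r.probe),
        )
        out[(gene, direction)] = [r.probe for r in rows[:max_per_side]]
    return out


class TestSelectTopCpgs:
    def test_truncation_to_max_per_side(self):
        rows = [("G", "pos", f"cg{i:03d}", 0.9, 0.9, i + 1, i + 1, 2 * (i + 1))
                for i in range(150)]
        rows += [("G", "neg", f"ng{i:03d}", -0.9, -0.9, i + 1, i + 1, 2 * (i + 1))
                 for i in range(30)]
        ranked = pd.DataFrame(rows, columns=["gene", "direction", "probe",
                                             "rho_set1", "rho_set2",
                                             "rank_set1", "rank_set2", "ranksum"])
        matrix = mc.select_top_cpgs(ranked, max_per_side=100, min_cpg_total=10)
        assert len(matrix.genes["G"].pos) == 100
        assert len(matrix.genes["G"].neg) == 30

    def test_gene_with_too_few_candidates_dropped(self):
        rows = [("G", "pos", f"cg{i}", 0.9, 0.9, i + 1.0, i + 1.0, 2.0 * (i + 1))
                for i in range(4)]
        ranked = pd.DataFrame(rows, columns=["gene", "direction", "probe",
                                             "rho_set1", "rho_set2",
                                             "rank_set1", "rank_set2", "ranksum"])
        matrix = mc.select_top_cpgs(ranked, max_per_side=100, min_cpg_total=10)
        assert len(matrix) == 0

    def test_matches_exhaustive_sort_oracle(self):
        """Selection from 250 candidates per sign, with engineered rank-sum
        ties, equals brute-force sorting."""
        rng = np.random.default_rng(5)
        rows = []
        for sign, direction in ((1, "pos"), (-1, "neg")):
            rho1 = sign * np.round(rng.uniform(0.3, 1.0, 250), 2)  # ties likely
            rho2 = sign * np.round(rng.uniform(0.3, 1.0, 250), 2)
            for i in range(250):
                rows.append(("G", direction, f"cg{rng.integers(1e6):06d}{i}",
                             rho1[i], rho2[i]))
        df = pd.DataFrame(rows, columns=["gene", "direction", "probe",
                                         "rho_set1", "rho_set2"])
        sign = np.where(df["direction"] == "pos", -1.0, 1.0)
        grp = df.groupby(["gene", "direction"])
        df["rank_set1"] = df.assign(k=sign * df["rho_set1"]).groupby(
            ["gene", "direction"])["k"].rank(method="average")
        df["rank_set2"] = df.assign(k=sign * df["rho_set2"]).groupby(
            ["gene", "direction"])["k"].rank(method="average")
        df["ranksum"] = df["rank_set1"] + df["rank_set2"]
        ranked = df.sort_values(["gene", "direction", "ranksum", "probe"],
                                kind="mergesort")
        # re-apply the full ordering via the public path
        matrix = mc.select_top_cpgs(
            mc.combine_rank_sum(
                ranked.rename(columns={"rho_set1": "rho"}).assign(p=1e-5, set_label=1)[
                    ["gene", "probe", "rho", "p", "set_label"]],
                ranked.rename(columns={"rho_set2": "rho"}).assign(p=1e-5, set_label=2)[
                    ["gene", "probe", "rho", "p", "set_label"]],
            ),
            max_per_side=100,
        )
        oracle_ranked = mc.combine_rank_sum(
            ranked.rename(columns={"rho_set1": "rho"}).assign(p=1e-5, set_label=1)[
                ["gene", "probe", "rho", "p", "set_label"]],
            ranked.rename(columns={"rho_set2": "rho"}).assign(p=1e-5, set_label=2)[
                ["gene", "probe", "rho", "p", "set_label"]],
        )
        oracle = _brute_force_selection(oracle_ranked, 100)
        assert matrix.genes["G"].pos == oracle[("G", "pos")]
        assert matrix.genes["G"].neg == oracle[("G", "neg")]


class TestPermutationInvariance:
    def test_shuffling_probes_and_samples_changes_nothing(self):
        rng = np.random.default_rng(11)
        n, n_probes = 60, 40
        samples = [f"s{i}" for i in range(n)]
        z = rng.uniform(size=n)
        expr = _expr(["G"], samples, [5 + 3 * z + rng.normal(0, 0.5, n)])
        beta = np.clip(z + rng.normal(0, 0.1, (n_probes, n)), 0, 1)
        probes = [f"cg{i:04d}" for i in range(n_probes)]
        meth = _meth(probes, samples, beta)

        def run(m, e, sample_order):
            r1 = mc.spearman_screen(e, m, sample_order[:30], 1)
            r2 = mc.spearman_screen(e, m, sample_order[30:], 2)
            return mc.select_top_cpgs(mc.combine_rank_sum(r1, r2), 100, min_cpg_total=1)

        base = run(meth, expr, samples)
        p_perm = rng.permutation(n_probes)
        s_perm = rng.permutation(n)
        meth_shuf = mc.MethylationMatrix(
            [probes[i] for i in p_perm],
            [samples[j] for j in s_perm],
            beta[np.ix_(p_perm, s_perm)],
        )
        expr_shuf = expr.subset_samples([samples[j] for j in s_perm])
        shuf = run(meth_shuf, expr_shuf, samples)
        assert base.genes["G"].pos == shuf.genes["G"].pos
        assert base.genes["G"].neg == shuf.genes["G"].neg
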