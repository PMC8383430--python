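"""Junction clustering, the DM-GLM likelihood and test, sashimi and MXE scores."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from scnsplice.counting import JunctionTable
from scnsplice.splicing import (
    cluster_junctions,
    dm_glm_test,
    dm_loglik,
    mxe_consistency,
    mxe_window_geometry,
    sashimi_summary,
)
from scnsplice.synthetic import CohortSpec, SwitchSpec, make_mxe_gene, simulate_cohort


def _table(rows, samples=("s1",)):
    """rows: {(chrom, donor, acceptor, strand): counts per sample}"""
    idx = pd.MultiIndex.from_tuples(sorted(rows), names=JunctionTable.INDEX_NAMES)
    df = pd.DataFrame([rows[k] for k in idx], index=idx, columns=list(samples))
    return JunctionTable(df)


def _union_find_components(keys):
    """Independent clustering oracle over the shared-coordinate graph."""
    parent = {k: k for k in keys}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    def union(a, b):
        parent[find(a)] = find(b)

    for i, k1 in enumerate(keys):
        for k2 in keys[i + 1 :]:
            if k1[0] == k2[0] and k1[3] == k2[3] and (
                k1[1] == k2[1] or k1[2] == k2[2]
            ):
                union(k1, k2)
    comps = {}
    for k in keys:
        comps.setdefault(find(k), set()).add(k)
    return sorted(frozenset(c) for c in comps.values())


class TestClusterJunctions:
    def test_shared_donor_one_cluster(self):
        jt = _table({("chr1", 150, 300, "+"): [20], ("chr1", 150, 500, "+"): [20]})
        clusters, _ = cluster_junctions(jt)
        assert len(clusters) == 1 and len(clusters[0].junctions) == 2

    def test_disconnected_singletons_dropped(self):
        jt = _table({("chr1", 150, 300, "+"): [40], ("chr1", 600, 900, "+"): [40]})
        clusters, dropped = cluster_junctions(jt)
        assert clusters == []
        assert {reason for _, reason in dropped} == {"singleton component"}

    def test_chain_forms_single_component(self):
        jt = _table(
            {
                ("chr1", 100, 200, "+"): [20],
                ("chr1", 150, 200, "+"): [20],
                ("chr1", 150, 400, "+"): [20],
                ("chr1", 350, 400, "+"): [20],
            }
        )
        clusters, _ = cluster_junctions(jt)
        assert len(clusters) == 1 and len(clusters[0].junctions) == 4

    def test_matches_union_find_oracle_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            keys = {
                (
                    "chr1",
                    int(rng.integers(0, 6) * 100),
                    int(600 + rng.integers(0, 6) * 100),
                    "+",
                )
                for _ in range(rng.integers(2, 10))
            }
            rows = {k: [int(rng.integers(20, 60))] for k in keys}
            jt = _table(rows)
            clusters, _ = cluster_junctions(jt, min_cluster_reads=0)
            got = sorted(frozenset(c.junctions) for c in clusters)
            oracle = [c for c in _union_find_components(sorted(keys)) if len(c) >= 2]
            assert got == sorted(oracle)

    def test_low_support_junction_pruned(self):
        jt = _table(
            {
                ("chr1", 150, 300, "+"): [5000],
                ("chr1", 150, 500, "+"): [5000],
                ("chr1", 300, 500, "+"): [1],  # 0.0001 of the cluster
            }
        )
        clusters, dropped = cluster_junctions(jt, min_junction_fraction=0.001)
        assert len(clusters) == 1 and len(clusters[0].junctions) == 2
        assert any("min_junction_fraction" in r for _, r in dropped)

    def test_min_cluster_reads(self):
        jt = _table({("chr1", 150, 300, "+"): [5], ("chr1", 150, 500, "+"): [5]})
        clusters, dropped = cluster_junctions(jt, min_cluster_reads=30)
        assert clusters == []
        assert any("min_cluster_reads" in r for _, r in dropped)

    def test_order_independent(self):
        rng = np.random.default_rng(9)
        keys = [
            ("chr1", 100, 300, "+"),
            ("chr1", 100, 500, "+"),
            ("chr1", 450, 500, "+"),
            ("chr1", 700, 900, "+"),
            ("chr1", 700, 950, "+"),
        ]
        rows = {k: [int(rng.integers(20, 50))] for k in keys}
        base, _ = cluster_junctions(_table(rows))
        for _ in range(5):
            perm = list(rows)
            rng.shuffle(perm)
            idx = pd.MultiIndex.from_tuples(perm, names=JunctionTable.INDEX_NAMES)
            jt = JunctionTable(pd.DataFrame([rows[k] for k in perm], index=idx, columns=["s1"]))
            again, _ = cluster_junctions(jt)
            assert [c.junctions for c in again] == [c.junctions for c in base]


class TestDmLoglik:
    def test_degenerate_single_junction_zero(self):
        y = np.array([[7.0]])
        assert dm_loglik(y, np.array([[1.0]]), alpha=3.0) == pytest.approx(0.0, abs=1e-12)

    def test_large_alpha_approaches_multinomial(self):
        y = np.array([[3.0, 1.0], [2.0, 2.0]])
        p = np.array([[0.6, 0.4], [0.6, 0.4]])
        multinomial = float(np.sum(y * np.log(p)))
        assert dm_loglik(y, p, alpha=1e6) == pytest.approx(multinomial, abs=1e-3)

    def test_beta_binomial_closed_form(self):
        # one sample, y=(1,0), p=(.5,.5), alpha=2 -> ln 0.5
        val = dm_loglik(np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]]), alpha=2.0)
        assert val == pytest.approx(math.log(0.5), abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dm_loglik(np.array([[1.0, 0.0]]), np.array([[0.7, 0.7]]), alpha=1.0)
        with pytest.raises(ValueError):
            dm_loglik(np.array([[1.0, 0.0]]), np.array([[0.5, 0.5]]), alpha=0.0)


def _simulate_cluster(rng, n0, n1, p0, p1, alpha, depth=60):
    rows, labels = [], []
    for i in range(n0 + n1):
        p = p0 if i < n0 else p1
        g = rng.dirichlet(alpha * np.asarray(p))
        rows.append(rng.multinomial(rng.poisson(depth), g))
        labels.append("pre" if i < n0 else "post")
    idx = [f"s{i}" for i in range(n0 + n1)]
    y = pd.DataFrame(rows, index=idx, columns=[f"j{k}" for k in range(len(p0))])
    return y, pd.Series(labels, index=idx)


def _betabinom_lrt(y, x):
    """Independent J=2 oracle: beta-binomial LRT via direct pmf optimization."""

    def negll(params, counts, totals):
        logit_p, log_a = params
        p = 1 / (1 + np.exp(-logit_p))
        a = np.exp(log_a)
        return -np.sum(stats.betabinom.logpmf(counts, totals, a * p, a * (1 - p)))

    counts = y.iloc[:, 0].to_numpy()
    totals = y.sum(axis=1).to_numpy()
    keep = totals > 0
    counts, totals, x = counts[keep], totals[keep], x[keep]

    def fit(c, t):
        best = None
        for p0 in (-1.0, 0.0, 1.0):
            res = optimize.minimize(
                negll, [p0, 2.0], args=(c, t), method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        return -best.fun

    # null: common p, common alpha; alt: group-specific p, shared alpha found
    # by profiling over a grid refined around the best point
    null_ll = fit(counts, totals)

    def alt_ll_given_alpha(log_a):
        tot = 0.0
        for grp in (0, 1):
            c, t = counts[x == grp], totals[x == grp]
            best = None
            for p0 in (-1.0, 0.0, 1.0):
                res = optimize.minimize(
                    lambda q: negll([q[0], log_a], c, t), [p0],
                    method="Nelder-Mead", options={"xatol": 1e-9, "fatol": 1e-11},
                )
                if best is None or res.fun < best.fun:
                    best = res
            tot -= best.fun
        return tot

    grid = np.linspace(-1, 6, 29)
    vals = [alt_ll_given_alpha(g) for g in grid]
    b = grid[int(np.argmax(vals))]
    fine = np.linspace(b - 0.3, b + 0.3, 31)
    alt_ll = max(alt_ll_given_alpha(g) for g in fine)
    return null_ll, alt_ll


class TestDmGlmTest:
    def test_identical_groups_null_truth(self):
        y = pd.DataFrame(
            [[30, 10, 5]] * 8, index=[f"s{i}" for i in range(8)], columns=list("abc")
        )
        lab = pd.Series(["pre"] * 4 + ["post"] * 4, index=y.index)
        res = dm_glm_test(y, lab)
        assert res.lrt_statistic < 1e-4
        assert res.p_value > 0.99
        assert abs(res.beta.sum()) < 1e-8

    def test_all_zero_junction_dropped_with_warning(self):
        y = pd.DataFrame(
            [[30, 0, 5], [28, 0, 7], [31, 0, 4], [30, 0, 6]],
            index=[f"s{i}" for i in range(4)],
            columns=list("abc"),
        )
        lab = pd.Series(["pre", "pre", "post", "post"], index=y.index)
        with pytest.warns(UserWarning, match="all-zero"):
            res = dm_glm_test(y, lab)
        assert res.dropped_junctions == ["b"] and res.df == 1

    def test_lrt_nonnegative_random_clusters(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            y, lab = _simulate_cluster(
                rng, 5, 5, [0.5, 0.5], [0.5, 0.5], alpha=10, depth=30
            )
            if (y.sum(axis=1)[lab == "pre"] > 0).sum() < 2:
                continue
            if (y.sum(axis=1)[lab == "post"] > 0).sum() < 2:
                continue
            if (y.sum(axis=0) == 0).any():
                continue
            res = dm_glm_test(y, lab)
            assert res.lrt_statistic >= -1e-6

    def test_agrees_with_betabinomial_oracle(self):
        """J=2 DM fit equals an independent beta-binomial LRT within 1e-3."""
        rng = np.random.default_rng(33)
        for _ in range(3):
            y, lab = _simulate_cluster(rng, 15, 15, [0.7, 0.3], [0.4, 0.6], alpha=15)
            res = dm_glm_test(y, lab)
            x = (lab == sorted(lab.unique())[1]).to_numpy(dtype=float)
            null_ll, alt_ll = _betabinom_lrt(y, x)
            # the DM likelihood omits the combinatorial coefficient that
            # betabinom.logpmf includes; it is constant across models
            coef = float(
                np.sum(
                    special.gammaln(y.sum(axis=1) + 1)
                    - special.gammaln(y.iloc[:, 0] + 1)
                    - special.gammaln(y.iloc[:, 1] + 1)
                )
            )
            assert res.null_loglik + coef == pytest.approx(null_ll, abs=1e-3)
            assert res.alt_loglik + coef == pytest.approx(alt_ll, abs=2e-3)

    def test_label_permutation_destroys_power(self):
        rng = np.random.default_rng(44)
        ps = []
        for _ in range(20):
            y, lab = _simulate_cluster(rng, 20, 20, [0.7, 0.3], [0.3, 0.7], alpha=20)
            shuffled = pd.Series(rng.permutation(lab.to_numpy()), index=lab.index)
            ps.append(dm_glm_test(y, shuffled).p_value)
        assert float(np.median(ps)) > 0.1

    def test_permutation_p_agrees_on_strong_switch(self):
        rng = np.random.default_rng(55)
        y, lab = _simulate_cluster(rng, 20, 20, [0.8, 0.2], [0.2, 0.8], alpha=30)
        res = dm_glm_test(y, lab, permutations=50, seed=1)
        assert res.p_value < 1e-6 and res.permutation_p <= 1 / 51 + 1e-12


class TestSashimiAndConsistency:
    def test_single_junction_proportion_one(self):
        jt = _table({("chr1", 150, 300, "+"): [10, 4]}, samples=("s1", "s2"))
        group = pd.Series({"s1": "pre", "s2": "post"})
        summary = sashimi_summary(jt, group, ("chr1", 0, 1000))
        assert summary.proportions["pre"].iloc[0] == 1.0

    def test_pooled_percentages(self):
        jt = _table(
            {
                ("chr1", 100, 200, "+"): [30],
                ("chr1", 100, 400, "+"): [60],
                ("chr1", 300, 400, "+"): [10],
            }
        )
        group = pd.Series({"s1": "pre"})
        summary = sashimi_summary(jt, group, ("chr1", 0, 1000))
        assert sorted(summary.proportions["pre"].tolist()) == [0.1, 0.3, 0.6]

    def test_empty_window_raises(self):
        jt = _table({("chr1", 150, 300, "+"): [10]})
        with pytest.raises(ValueError):
            sashimi_summary(jt, pd.Series({"s1": "pre"}), ("chr1", 5000, 6000))

    def test_prenatal_n_fraction_recovered(self):
        """Fetal-only cohort at f_N=0.8: N junction share ~ 0.8."""
        spec = CohortSpec(n_samples=40, age_range_pcd=(50.0, 120.0), seed=6, logit_noise_sd=0.0)
        genes = [make_mxe_gene("GG", "chr1")]
        switch = {"GG": SwitchSpec("GG", f_fetal=0.8, f_mature=0.8)}
        cohort = simulate_cohort(spec, genes, switch)
        g = genes[0]
        group = pd.Series("pre", index=cohort.meta.index)
        geom = mxe_window_geometry(g.bins, g.pair)
        lo, hi = geom["flank_up"][0], geom["flank_down"][1]
        summary = sashimi_summary(cohort.junctions, group, ("chr1", lo, hi))
        props = summary.proportions["pre"]
        n_keys = [
            k for k in props.index
            if k[1] == geom["flank_up"][1] and k[2] == geom["exon_n"][0]
            or k[1] == geom["exon_n"][1] and k[2] == geom["flank_down"][0]
        ]
        assert sum(props[k] for k in n_keys) == pytest.approx(0.8, abs=0.03)

    def test_only_inclusion_junctions_fully_consistent(self, mxe_gene):
        geom = mxe_window_geometry(mxe_gene.bins, mxe_gene.pair)
        jt = _table(
            {
                ("chr1", geom["flank_up"][1], geom["exon_a"][0], "+"): [50],
                ("chr1", geom["exon_n"][1], geom["flank_down"][0], "+"): [50],
            }
        )
        score = mxe_consistency(jt, geom)
        assert score.consistent_fraction == 1.0

    def test_cross_read_fraction(self, mxe_gene):
        geom = mxe_window_geometry(mxe_gene.bins, mxe_gene.pair)
        jt = _table(
            {
                ("chr1", geom["flank_up"][1], geom["exon_a"][0], "+"): [99],
                ("chr1", geom["exon_a"][1], geom["exon_n"][0], "+"): [1],
            }
        )
        score = mxe_consistency(jt, geom)
        assert score.consistent_fraction == pytest.approx(0.99)

    def test_windows_restricted_by_chromosome(self):
        """Genes on different chromosomes with identical coordinates do not
        leak junction reads into each other's consistency windows."""
        g1 = make_mxe_gene("GA", "chr1")
        g2 = make_mxe_gene("GB", "chr9")  # same coordinates, other chromosome
        geom1 = mxe_window_geometry(g1.bins, g1.pair, chrom="chr1")
        donor, acceptor = g1.junction_map["up_a"][0]
        jt = _table(
            {
                ("chr1", donor, acceptor, "+"): [10],
                ("chr9", donor, acceptor, "+"): [90],
            }
        )
        score = mxe_consistency(jt, geom1)
        assert score.total_reads == 10

    def test_double_skip_reported_separately(self):
        """~20% fetal double-skip: skip fraction recovered, consistency unaffected."""
        spec = CohortSpec(n_samples=50, age_range_pcd=(50.0, 150.0), seed=8, logit_noise_sd=0.0)
        genes = [make_mxe_gene("G8", "chr1", include_skip_transcript=True)]
        switch = {
            "G8": SwitchSpec(
                "G8", f_fetal=0.5, f_mature=0.5, skip_fetal=0.2, skip_mature=0.2
            )
        }
        cohort = simulate_cohort(spec, genes, switch)
        geom = mxe_window_geometry(genes[0].bins, genes[0].pair)
        score = mxe_consistency(cohort.junctions, geom)
        # junction-read weights are (a, a, n, n, k) for the five junction
        # types; with f_skip=0.2 and realized f_n = 0.5*(1-0.2) = 0.4,
        # a = 0.4 as well, so the skip share is 0.2 / 1.8
        expected_skip = 0.2 / (2 * 0.4 + 2 * 0.4 + 0.2)
        assert score.skip_fraction == pytest.approx(expected_skip, abs=0.02)
        assert score.consistent_fraction == 1.0
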