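import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from wingcomp import (
    build_comparison_plans,
    bm_adequacy_diagnostic,
    correlation_through_origin,
    felsenstein_contrasts,
    p_from_r,
    read_newick,
    read_traits,
    run_study,
    synthetic,
)
from wingcomp.contrasts import (
    ContrastError,
    ContrastSet,
    UndefinedCorrelationError,
    contrast_structure,
    eyespot_totals,
)
from wingcomp.phylo_io import resolve_polytomies


def bm_covariance(tree):
    """Independent oracle: BM tip covariance = shared root-to-MRCA path."""
    dt = tree.dendropy_tree
    depth = {}
    for nd in dt.preorder_node_iter():
        depth[nd] = 0.0 if nd.parent_node is None else (
            depth[nd.parent_node] + nd.edge.length
        )
    leaves = list(dt.leaf_node_iter())
    ancestors = {}
    for lf in leaves:
        chain = []
        nd = lf
        while nd is not None:
            chain.append(nd)
            nd = nd.parent_node
        ancestors[lf] = chain
    n = len(leaves)
    V = np.zeros((n, n))
    for i in range(n):
        seti = set(ancestors[leaves[i]])
        for j in range(i, n):
            mrca = next(nd for nd in ancestors[leaves[j]] if nd in seti)
            V[i, j] = V[j, i] = depth[mrca]
    labels = [lf.taxon.label for lf in leaves]
    return labels, V


class TestFelsensteinContrasts:
    def test_hand_worked_three_tip_example(self, three_tip_tree):
        cs = felsenstein_contrasts(three_tip_tree, {"A": 4.0, "B": 2.0, "C": 1.0})
        assert cs.contrasts == pytest.approx([2 / np.sqrt(2), 2 / np.sqrt(3.5)])
        assert cs.node_values[0] == pytest.approx(3.0)  # cherry ancestor
        assert cs.adjusted_lengths[0] == pytest.approx(1.5)  # v' = 1 + 1*1/2
        assert cs.n_contrasts == 2

    def test_identical_values_give_zero_contrasts(self, fixed_tree_23):
        vals = {lb: 5.0 for lb in fixed_tree_23.tip_labels}
        cs = felsenstein_contrasts(fixed_tree_23, vals)
        assert np.all(cs.contrasts == 0)

    def test_linearity_in_trait(self, fixed_tree_23, rng):
        vals = dict(zip(fixed_tree_23.tip_labels, rng.normal(size=23)))
        scaled = {k: 3.7 * v for k, v in vals.items()}
        a = felsenstein_contrasts(fixed_tree_23, vals).contrasts
        b = felsenstein_contrasts(fixed_tree_23, scaled).contrasts
        assert b == pytest.approx(3.7 * a)

    def test_contrast_count_is_tips_minus_one(self):
        for seed, n in [(0, 5), (1, 12), (2, 23), (3, 40)]:
            t = synthetic.simulate_yule_tree(n, seed=seed)
            vals = dict(zip(t.tip_labels, np.arange(n, dtype=float)))
            assert felsenstein_contrasts(t, vals).n_contrasts == n - 1

    def test_non_bifurcating_tree_directs_to_resolver(self):
        t = read_newick("(A:1,B:1,C:1);")
        with pytest.raises(ContrastError, match="resolve_polytomies"):
            felsenstein_contrasts(t, {"A": 1.0, "B": 2.0, "C": 3.0})

    def test_missing_tip_value_rejected(self, three_tip_tree):
        with pytest.raises(ContrastError, match="missing"):
            felsenstein_contrasts(three_tip_tree, {"A": 1.0, "B": 2.0, "C": np.nan})

    def test_zero_denominator_inflated_or_raises(self):
        t = read_newick("((A:0,B:0):1,C:1);")  # zero-length sister pair
        vals = {"A": 1.0, "B": 2.0, "C": 4.0}
        cs = felsenstein_contrasts(t, vals)  # default: auto inflation
        assert np.all(np.isfinite(cs.contrasts))
        with pytest.raises(ContrastError, match="zero contrast denominator"):
            felsenstein_contrasts(t, vals, zero_length_epsilon=None)

    def test_matches_gls_whitening_oracle(self, rng):
        # sum of squared standardized contrasts equals the GLS residual
        # sum of squares from whitening with the BM covariance
        for seed in range(20):
            n = int(rng.integers(3, 7))
            t = synthetic.simulate_yule_tree(n, seed=100 + seed)
            labels, V = bm_covariance(t)
            x = rng.normal(size=n)
            vals = dict(zip(labels, x))
            cs = felsenstein_contrasts(t, vals)
            Vinv = np.linalg.inv(V)
            one = np.ones(n)
            mu = (one @ Vinv @ x) / (one @ Vinv @ one)
            rss = (x - mu * one) @ Vinv @ (x - mu * one)
            ssc = float(cs.contrasts @ cs.contrasts)
            assert ssc == pytest.approx(rss, rel=1e-11)

    def test_child_order_invariance(self, rng):
        t = synthetic.simulate_yule_tree(10, seed=3)
        vals = dict(zip(t.tip_labels, rng.normal(size=10)))
        vals2 = dict(zip(t.tip_labels, rng.normal(size=10)))
        r0 = correlation_through_origin(
            felsenstein_contrasts(t, vals), felsenstein_contrasts(t, vals2)
        )
        flipped = t.copy()
        for nd in flipped.dendropy_tree.preorder_internal_node_iter():
            kids = nd.child_nodes()
            for ch in kids:
                nd.remove_child(ch)
            for ch in reversed(kids):
                nd.add_child(ch)
        r1 = correlation_through_origin(
            felsenstein_contrasts(flipped, vals), felsenstein_contrasts(flipped, vals2)
        )
        assert abs(r1.r) == pytest.approx(abs(r0.r), rel=1e-12)
        assert r1.p == pytest.approx(r0.p, rel=1e-12)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_cross_check_against_ape_pic(self, tmp_path, rng):
        # independent reference implementation of the same recursion
        t = synthetic.simulate_yule_tree(8, seed=42)
        x = rng.normal(size=8)
        y = rng.normal(size=8) + 0.5 * x
        labels = list(t.tip_labels)
        (tmp_path / "tree.nwk").write_text(t.to_newick())
        lines = ["label,x,y"] + [
            f"{lb},{xi:.17g},{yi:.17g}" for lb, xi, yi in zip(labels, x, y)
        ]
        (tmp_path / "traits.csv").write_text("\n".join(lines) + "\n")
        rcode = f"""
        suppressMessages(library(ape))
        tr <- read.tree("{tmp_path}/tree.nwk")
        d <- read.csv("{tmp_path}/traits.csv", row.names=1)
        cx <- pic(setNames(d$x, rownames(d)), tr)
        cy <- pic(setNames(d$y, rownames(d)), tr)
        r <- sum(cx*cy)/sqrt(sum(cx^2)*sum(cy^2))
        cat(sprintf("%.15g %.15g %.15g", sum(cx^2), sum(cy^2), r))
        """
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        ss_x_ref, ss_y_ref, r_ref = map(float, out.stdout.split())
        csx = felsenstein_contrasts(t, dict(zip(labels, x)))
        csy = felsenstein_contrasts(t, dict(zip(labels, y)))
        assert float(csx.contrasts @ csx.contrasts) == pytest.approx(
            ss_x_ref, rel=1e-10
        )
        assert float(csy.contrasts @ csy.contrasts) == pytest.approx(
            ss_y_ref, rel=1e-10
        )
        assert correlation_through_origin(csx, csy).r == pytest.approx(
            r_ref, rel=1e-10
        )


def make_contrast_set(values, sds=None, trait="t"):
    values = np.asarray(values, dtype=float)
    n = len(values)
    return ContrastSet(
        trait=trait,
        tips=tuple(f"sp{i}" for i in range(n + 1)),
        node_ids=tuple(f"n{i}" for i in range(n)),
        contrasts=values,
        node_values=np.zeros(n),
        contrast_sds=np.asarray(sds if sds is not None else np.ones(n)),
        adjusted_lengths=np.ones(n),
    )


class TestCorrelation:
    def test_proportional_contrasts_r_one(self):
        a = make_contrast_set([1.0, 2.0, 3.0])
        b = make_contrast_set([2.0, 4.0, 6.0])
        res = correlation_through_origin(a, b)
        assert res.r == pytest.approx(1.0)
        assert res.p == 0.0

    def test_orthogonal_through_origin(self):
        a = make_contrast_set([1.0, -1.0, 0.0])
        b = make_contrast_set([1.0, 1.0, 0.0])
        res = correlation_through_origin(a, b)
        assert res.r == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_no_mean_centring(self):
        # all-positive contrasts with zero product-moment correlation
        # still correlate strongly through the origin
        a = make_contrast_set([1.0, 1.0, 1.0, 1.0])
        b = make_contrast_set([1.0, 2.0, 1.0, 2.0])
        res = correlation_through_origin(a, b)
        assert res.r > 0.9

    def test_joint_sign_flip_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        r0 = correlation_through_origin(make_contrast_set(x), make_contrast_set(y))
        flip = np.ones(10)
        flip[[1, 4, 7]] = -1
        r1 = correlation_through_origin(
            make_contrast_set(x * flip), make_contrast_set(y * flip)
        )
        assert r1.r == r0.r  # bit-identical

    def test_all_zero_contrasts_rejected(self):
        a = make_contrast_set([0.0, 0.0, 0.0])
        b = make_contrast_set([1.0, 2.0, 3.0])
        with pytest.raises(UndefinedCorrelationError):
            correlation_through_origin(a, b)

    def test_mismatched_trees_rejected(self):
        a = make_contrast_set([1.0, 2.0, 3.0])
        b = ContrastSet(
            trait="u",
            tips=("x0", "x1", "x2", "x3"),
            node_ids=("m0", "m1", "m2"),
            contrasts=np.ones(3),
            node_values=np.zeros(3),
            contrast_sds=np.ones(3),
            adjusted_lengths=np.ones(3),
        )
        with pytest.raises(ValueError, match="different trees"):
            correlation_through_origin(a, b)


class TestPFromR:
    @pytest.mark.parametrize(
        "r,n,expected,decimals",
        [
            (0.66, 22, 0.0006, 4),
            (0.54, 22, 0.0078, 4),
            (0.57, 22, 0.0045, 4),
            (0.46, 22, 0.0272, 4),
        ],
    )
    def test_published_style_values(self, r, n, expected, decimals):
        assert p_from_r(r, n) == pytest.approx(expected, abs=10 ** -decimals)

    def test_null_value(self):
        assert p_from_r(0.0, 22) == pytest.approx(1.0)

    def test_sign_symmetric(self):
        assert p_from_r(-0.57, 22) == p_from_r(0.57, 22)

    def test_degenerate_r_returns_zero_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert p_from_r(1.0, 22) == 0.0

    def test_monotone_in_abs_r(self):
        ps = [p_from_r(r, 22) for r in np.linspace(0.05, 0.95, 10)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_t_identity(self):
        r, n = 0.43, 22
        t = r * np.sqrt((n - 1) / (1 - r**2))
        assert p_from_r(r, n) == pytest.approx(2 * stats.t.sf(t, n - 1))


class TestBmAdequacy:
    def test_constructed_violation_detected(self):
        rng = np.random.default_rng(8)
        sds = rng.uniform(0.5, 3.0, size=60)
        contrasts = sds * rng.choice([-1, 1], size=60)  # |C| proportional to SD
        stat, p = bm_adequacy_diagnostic(make_contrast_set(contrasts, sds))
        assert stat > 0.99
        assert p < 1e-10

    def test_constant_abs_contrasts_zero_statistic(self):
        sds = np.array([1.0, 2.0, 3.0, 4.0])
        stat, p = bm_adequacy_diagnostic(make_contrast_set([1, -1, 1, -1], sds))
        assert stat == 0.0

    def test_calibration_under_bm(self, fixed_tree_23):
        # BM-simulated traits should trip the diagnostic at roughly the
        # nominal rate
        struct = contrast_structure(fixed_tree_23)
        labels, V = bm_covariance(fixed_tree_23)
        order = [labels.index(lb) for lb in struct.tips]
        chol = np.linalg.cholesky(V[np.ix_(order, order)])
        rng = np.random.default_rng(99)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            x = chol @ rng.standard_normal(23)
            cs = ContrastSet(
                trait="t",
                tips=struct.tips,
                node_ids=struct.node_ids,
                contrasts=struct.matrix @ x,
                node_values=struct.node_matrix @ x,
                contrast_sds=struct.contrast_sds,
                adjusted_lengths=struct.adjusted_lengths,
            )
            _, p = bm_adequacy_diagnostic(cs)
            rejections += p < 0.05
        # 95% binomial band around 0.05 for 400 draws
        assert 0.02 <= rejections / n_rep <= 0.085

    def test_too_few_contrasts(self):
        with pytest.raises(ValueError, match="at least 4"):
            bm_adequacy_diagnostic(make_contrast_set([1.0, 2.0, 3.0]))


class TestComparisonPlans:
    def test_counts(self):
        plans = build_comparison_plans()
        within = [p for p in plans if p.scope == "within_surface_pairs"]
        homologous = [p for p in plans if p.scope == "cross_surface_homologous"]
        totals = [p for p in plans if p.scope == "cross_surface_totals"]
        assert len(within) == 4
        assert all(len(p.pairs) == 28 for p in within)
        assert sum(len(p.pairs) for p in within) == 112
        assert len(homologous) == 2
        assert all(len(p.pairs) == 8 for p in homologous)
        assert len(totals) == 2
        assert all(len(p.pairs) == 1 for p in totals)

    def test_sector_set_size_enforced(self):
        from wingcomp.config import SectorConfig

        with pytest.raises(ValueError, match="8 labels"):
            build_comparison_plans(SectorConfig(fore=("1", "2", "3")))

    def test_totals_derivation(self):
        header = ",".join(
            ["species"] + [f"fore.dorsal.s{i}" for i in range(-1, 7)]
        )
        tm = read_traits(f"{header}\nsp1,0,2,0,1,0,0,0,3\nsp2,0,0,0,0,0,0,0,0\n")
        totals = eyespot_totals(tm)
        assert totals.loc["sp1", "fore.dorsal.total"] == 3
        assert totals.loc["sp2", "fore.dorsal.total"] == 0


class TestRunStudy:
    def test_identical_columns_flagged(self, fixed_tree_23):
        import pandas as pd
        from wingcomp.phylo_io import TraitMatrix
        from wingcomp.contrasts import ComparisonPlan

        rng = np.random.default_rng(1)
        x = rng.integers(0, 6, size=23).astype(float)
        df = pd.DataFrame(
            {"fore.dorsal.s1": x, "fore.dorsal.s2": x.copy()},
            index=list(fixed_tree_23.tip_labels),
        )
        tm = TraitMatrix(df)
        plan = ComparisonPlan(
            "within_surface_pairs",
            "fore",
            ("dorsal",),
            (("fore.dorsal.s1", "fore.dorsal.s2"),),
        )
        res = run_study(fixed_tree_23, tm, plans=[plan])
        row = res.table.iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p == 0.0
        assert row.significant

    def test_missing_values_prune_and_adjust_df(self, fixed_tree_23):
        import pandas as pd
        from wingcomp.phylo_io import TraitMatrix
        from wingcomp.contrasts import ComparisonPlan

        rng = np.random.default_rng(2)
        tips = list(fixed_tree_23.tip_labels)
        df = pd.DataFrame(
            {
                "fore.dorsal.s1": rng.integers(0, 7, 23).astype(float),
                "fore.dorsal.s2": rng.integers(0, 7, 23).astype(float),
            },
            index=tips,
        )
        df.loc[tips[0], "fore.dorsal.s1"] = np.nan
        df.loc[tips[1], "fore.dorsal.s2"] = np.nan
        tm = TraitMatrix(df)
        plan = ComparisonPlan(
            "within_surface_pairs",
            "fore",
            ("dorsal",),
            (("fore.dorsal.s1", "fore.dorsal.s2"),),
        )
        res = run_study(fixed_tree_23, tm, plans=[plan])
        assert res.table.iloc[0].n_contrasts == 20  # 21 shared species
        assert res.table.iloc[0].df == 19

    def test_species_mismatch_listed(self, fixed_tree_23, study_dataset):
        _, traits = study_dataset
        import pandas as pd
        from wingcomp.phylo_io import TraitMatrix

        df = traits.data.drop(index=["sp01"])
        with pytest.raises(ValueError, match="sp01"):
            run_study(fixed_tree_23, TraitMatrix(df))

    def test_report_runs(self, study_dataset):
        tree, traits = study_dataset
        res = run_study(tree, traits)
        text = res.format_report()
        assert "wing" in text and "surface" in text
        n_rows = len(res.table) + len(res.skipped)
        assert n_rows == 130  # 4*28 within + 2*8 homologous + 2 totals

    def test_bh_correction_is_more_conservative(self, study_dataset):
        tree, traits = study_dataset
        raw = run_study(tree, traits, bh=False)
        adj = run_study(tree, traits, bh=True)
        assert adj.table.significant.sum() <= raw.table.significant.sum()
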