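"""Co-expression network: adjacency, TOM, module detection, trait statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from culmnet.containers import ExpressionMatrix, ValidationError
from culmnet.network import (
    GREY,
    ModuleAssignment,
    NetworkConfig,
    adjacency,
    detect_modules,
    gene_significance,
    module_eigengene,
    module_significance,
    module_trait_relation,
    pick_soft_threshold,
    scale_free_fit,
    tom_similarity,
)


def expr_from(values, unit="log2CPM1", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"s{j:03d}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), unit)


class TestAdjacency:
    def test_anticorrelated_pair_has_unit_weight(self):
        x = np.linspace(0, 1, 10)
        expr = expr_from(np.vstack([x, -x + 3]))
        for beta in (1.0, 4.0, 7.0):
            a = adjacency(expr, beta=beta)
            assert np.isclose(a.iloc[0, 1], 1.0)

    def test_beta_one_is_absolute_correlation(self, rng):
        expr = expr_from(rng.normal(size=(6, 20)))
        a = adjacency(expr, beta=1.0)
        r = np.corrcoef(expr.values.to_numpy())
        expected = np.abs(r)
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(a.to_numpy(), expected)

    def test_matches_elementwise_brute_force(self, rng):
        expr = expr_from(rng.normal(size=(15, 12)))
        a = adjacency(expr, beta=4.0).to_numpy()
        x = expr.values.to_numpy()
        for i in range(15):
            for j in range(15):
                expected = 0.0 if i == j else abs(stats.pearsonr(x[i], x[j])[0]) ** 4
                assert abs(a[i, j] - expected) < 1e-12

    def test_symmetric_bounded(self, rng):
        a = adjacency(expr_from(rng.normal(size=(20, 15))), beta=4.0).to_numpy()
        assert np.allclose(a, a.T)
        assert a.min() >= 0 and a.max() <= 1

    def test_zero_variance_gene_named(self, rng):
        vals = rng.normal(size=(4, 10))
        vals[2] = 3.14
        with pytest.raises(ValidationError, match="g002"):
            adjacency(expr_from(vals))


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop unsigned TOM reference."""
    n = a.shape[0]
    k = a.sum(axis=1)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            out[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTOM:
    def test_isolated_pair_has_zero_overlap(self):
        a = np.zeros((4, 4))
        a[2, 3] = a[3, 2] = 0.8  # genes 0,1 share nothing with anyone
        t = tom_similarity(a)
        assert t[0, 1] == 0.0

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_unit_graph_has_unit_overlap(self, n):
        a = np.ones((n, n)) - np.eye(n)
        t = tom_similarity(a)
        assert np.allclose(t, 1.0)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(5):
            r = rng.random((10, 10))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 0.0)
            t = tom_similarity(a)
            assert np.max(np.abs(t - tom_oracle(a))) < 1e-12

    def test_invalid_adjacency_rejected(self, rng):
        with pytest.raises(ValidationError):
            tom_similarity(rng.random((5, 5)))  # asymmetric, nonzero diagonal


def scale_free_oracle(k, n_bins=10):
    """Independent reimplementation of the binning + log-log regression."""
    k = np.asarray([v for v in k if v > 0], dtype=float)
    edges = [k.min() + (k.max() - k.min()) * b / n_bins for b in range(n_bins + 1)]
    assignments = []
    for v in k:
        b = n_bins - 1
        for bb in range(n_bins - 1):
            if v < edges[bb + 1]:
                b = bb
                break
        assignments.append(b)
    xs, ys = [], []
    for b in range(n_bins):
        vals = [v for v, a in zip(k, assignments) if a == b]
        if vals:
            xs.append(np.log10(np.mean(vals)))
            ys.append(np.log10(len(vals) / len(k)))
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = np.array(ys) - (slope * np.array(xs) + intercept)
    r2 = 1 - resid @ resid / np.sum((ys - np.mean(ys)) ** 2)
    return -np.sign(slope) * r2


class TestSoftThreshold:
    def test_default_power_and_candidates_include_four(self):
        cfg = NetworkConfig()
        assert cfg.power == 4
        assert 4 in cfg.candidate_powers

    def test_identical_genes_reported_degenerate(self, rng):
        base = rng.normal(size=20)
        noiseless = np.vstack([base * s for s in (1.0, 2.0, -1.5, 0.5, 3.0)])
        beta, table = pick_soft_threshold(expr_from(noiseless))
        assert table["degenerate"].all()

    def test_r2_matches_independent_oracle(self):
        from culmnet.simulate import ModuleSpec, SimulationConfig, simulate_dataset
        from culmnet.preprocess import normalize_log

        cfg = SimulationConfig(
            n_genotypes=8, n_genes=150, n_internodes=3, n_replicates=2,
            true_ranks=(2, 2, 2), noise_sd=0.1,
            module_spec=[ModuleSpec(size=40, inter_gene_cor=0.8)],
            seed=9,
        )
        _, _, counts, _, _ = simulate_dataset(cfg)
        lg = normalize_log(counts, mode="CPM")
        _, table = pick_soft_threshold(lg)
        x = lg.values.to_numpy()
        absr = np.abs(np.corrcoef(x))
        np.fill_diagonal(absr, 0.0)
        for _, row in table.iterrows():
            if row["degenerate"]:
                continue
            k = (absr ** row["power"]).sum(axis=1)
            assert abs(row["signed_r2"] - scale_free_oracle(k)) < 1e-10

    def test_scale_free_fit_flags_constant_connectivity(self):
        r2, slope, degenerate = scale_free_fit(np.full(50, 3.0))
        assert degenerate and np.isnan(r2)


def block_expr(rng, block_sizes, n_noise, n_samples=40):
    """Planted perfectly-correlated blocks plus independent noise genes."""
    rows = []
    for size in block_sizes:
        base = rng.normal(size=n_samples)
        scales = rng.uniform(0.5, 2.0, size=size)
        rows.append(np.outer(scales, base))
    if n_noise:
        rows.append(rng.normal(size=(n_noise, n_samples)))
    return expr_from(np.vstack(rows))


class TestDetectModules:
    def test_default_min_module_size(self):
        assert NetworkConfig().min_module_size == 500

    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(13)
        expr = block_expr(rng, [30, 25], n_noise=40)
        adj = adjacency(expr, beta=4.0)
        tom = tom_similarity(adj)
        asn = detect_modules(tom, NetworkConfig(min_module_size=20), adj=adj)
        mods = asn.modules()
        assert len(mods) == 2
        # blocks occupy the first 30 and next 25 genes, in size order
        assert set(asn.genes_in(mods[0])) == set(expr.gene_ids[:30])
        assert set(asn.genes_in(mods[1])) == set(expr.gene_ids[30:55])
        assert (asn.labels[expr.gene_ids[55:]] == GREY).all()

    def test_independent_noise_only_all_grey(self):
        rng = np.random.default_rng(14)
        expr = block_expr(rng, [], n_noise=80)
        adj = adjacency(expr, beta=4.0)
        tom = tom_similarity(adj)
        asn = detect_modules(tom, NetworkConfig(min_module_size=20), adj=adj)
        assert (asn.labels == GREY).all()

    def test_fewer_genes_than_min_size_warns_all_grey(self, rng):
        expr = block_expr(rng, [5], n_noise=5)
        adj = adjacency(expr, beta=4.0)
        tom = tom_similarity(adj)
        with pytest.warns(UserWarning, match="all grey"):
            asn = detect_modules(tom, NetworkConfig(min_module_size=100), adj=adj)
        assert (asn.labels == GREY).all()

    def test_non_grey_modules_meet_min_size(self):
        rng = np.random.default_rng(15)
        expr = block_expr(rng, [30, 25, 22], n_noise=60)
        adj = adjacency(expr, beta=4.0)
        tom = tom_similarity(adj)
        asn = detect_modules(tom, NetworkConfig(min_module_size=20), adj=adj)
        for mod in asn.modules():
            assert len(asn.genes_in(mod)) >= 20


class TestEigengene:
    def test_identical_genes_give_common_profile(self, rng):
        base = rng.normal(size=30)
        expr = expr_from(np.vstack([2 * base + 1, 0.5 * base - 3, base]))
        asn = ModuleAssignment(
            labels=pd.Series("turquoise", index=expr.gene_ids), min_module_size=2
        )
        eig = module_eigengene(expr, asn)
        me = eig.loc["turquoise"].to_numpy()
        z = (base - base.mean()) / base.std()
        assert np.allclose(np.abs(me), np.abs(z / np.linalg.norm(z)), atol=1e-10)
        assert np.corrcoef(me, base)[0, 1] > 0.999

    def test_sign_convention_nonnegative_with_module_mean(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            expr = expr_from(r.normal(size=(12, 25)))
            asn = ModuleAssignment(
                labels=pd.Series("blue", index=expr.gene_ids), min_module_size=2
            )
            me = module_eigengene(expr, asn).loc["blue"]
            assert np.corrcoef(me, expr.values.mean(axis=0))[0, 1] >= 0

    def test_matches_svd_oracle(self, rng):
        expr = expr_from(rng.normal(size=(30, 20)))
        asn = ModuleAssignment(
            labels=pd.Series("red", index=expr.gene_ids), min_module_size=2
        )
        me = module_eigengene(expr, asn).loc["red"].to_numpy()
        x = expr.values.to_numpy()
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        _, _, vt = np.linalg.svd(z)
        assert np.allclose(np.abs(me), np.abs(vt[0]), atol=1e-10)

    def test_grey_excluded(self, rng):
        expr = expr_from(rng.normal(size=(10, 15)))
        labels = pd.Series(["blue"] * 5 + [GREY] * 5, index=expr.gene_ids)
        eig = module_eigengene(expr, ModuleAssignment(labels=labels, min_module_size=2))
        assert list(eig.index) == ["blue"]


class TestModuleTraitRelation:
    def _eigengenes(self, rng, n=50):
        me = rng.normal(size=(2, n))
        me /= np.linalg.norm(me, axis=1, keepdims=True)
        samples = [f"s{j}" for j in range(n)]
        return pd.DataFrame(me, index=["blue", "brown"], columns=samples)

    def test_identical_trait_gives_unit_correlation(self, rng):
        eig = self._eigengenes(rng)
        traits = pd.DataFrame({"t": eig.loc["blue"]})
        out = module_trait_relation(eig, traits).set_index("module")
        assert np.isclose(out.loc["blue", "r"], 1.0)
        assert out.loc["blue", "p"] <= np.finfo(float).tiny * 10

    def test_orthogonalised_trait_has_zero_correlation(self, rng):
        eig = self._eigengenes(rng)
        x = eig.loc["blue"].to_numpy()
        y = rng.normal(size=len(x))
        xc = x - x.mean()
        y = y - y.mean()
        y = y - (y @ xc) / (xc @ xc) * xc  # residualised against the eigengene
        traits = pd.DataFrame({"t": y}, index=eig.columns)
        out = module_trait_relation(eig, traits).set_index("module")
        assert abs(out.loc["blue", "r"]) < 1e-10

    def test_p_value_matches_incomplete_beta_closed_form(self, rng):
        n, r_target = 27, 0.5
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = rng.normal(size=n)
        z = z - z.mean()
        z = z - (z @ x) / (x @ x) * x
        z /= z.std()
        y = r_target * x + np.sqrt(1 - r_target**2) * z  # exact sample r = 0.5
        samples = [f"s{j}" for j in range(n)]
        eig = pd.DataFrame([x / np.linalg.norm(x)], index=["blue"], columns=samples)
        out = module_trait_relation(eig, pd.DataFrame({"t": y}, index=samples))
        df = n - 2
        t = r_target * np.sqrt(df / (1 - r_target**2))
        expected = special.betainc(df / 2, 0.5, df / (df + t * t))
        assert np.isclose(out["p"].iloc[0], expected, rtol=1e-10)
        assert np.isclose(out["r"].iloc[0], 0.5, atol=1e-12)

    def test_too_few_samples_rejected(self, rng):
        eig = self._eigengenes(rng, n=3)
        traits = pd.DataFrame({"t": [1.0, 2.0, 3.0]}, index=eig.columns)
        with pytest.raises(ValidationError):
            module_trait_relation(eig, traits)


class TestGeneSignificance:
    def test_trait_equal_to_gene_profile_scores_one(self, rng):
        expr = expr_from(rng.normal(size=(10, 30)))
        trait = expr.values.iloc[4]
        gs = gene_significance(expr, trait, trait_name="t")
        assert np.isclose(gs.loc["g004", "GS"], 1.0)

    def test_matches_pearsonr_loop_oracle(self, rng):
        expr = expr_from(rng.normal(size=(20, 25)))
        trait = pd.Series(rng.normal(size=25), index=expr.sample_ids)
        gs = gene_significance(expr, trait)
        for g in expr.gene_ids:
            r, p = stats.pearsonr(expr.values.loc[g], trait)
            assert np.isclose(gs.loc[g, "r"], r, atol=1e-12)
            assert np.isclose(gs.loc[g, "p"], p, rtol=1e-8)

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(17)
        expr = expr_from(rng.normal(size=(1000, 40)))
        trait = pd.Series(rng.permutation(rng.normal(size=40)), index=expr.sample_ids)
        gs = gene_significance(expr, trait)
        frac = (gs["p"] < 0.05).mean()
        assert abs(frac - 0.05) <= 0.02

    def test_constant_trait_rejected(self, rng):
        expr = expr_from(rng.normal(size=(5, 20)))
        with pytest.raises(ValidationError):
            gene_significance(expr, pd.Series(1.0, index=expr.sample_ids))


class TestModuleSignificance:
    def test_uniform_gs_module(self):
        gs = pd.DataFrame(
            {"trait": "t", "r": [0.4, -0.4, 0.4], "GS": [0.4, 0.4, 0.4], "p": [0.01] * 3},
            index=["a", "b", "c"],
        )
        asn = ModuleAssignment(
            labels=pd.Series("black", index=["a", "b", "c"]), min_module_size=2
        )
        ms = module_significance(gs, asn)
        assert np.isclose(ms.set_index("module").loc["black", "module_significance"], 0.4)

    def test_matches_group_mean_oracle(self, rng):
        genes = [f"g{i}" for i in range(30)]
        r = rng.uniform(-1, 1, size=30)
        gs = pd.DataFrame({"trait": "t", "r": r, "GS": np.abs(r), "p": 0.5}, index=genes)
        labels = pd.Series(["blue"] * 10 + ["brown"] * 10 + [GREY] * 10, index=genes)
        ms = module_significance(gs, ModuleAssignment(labels=labels, min_module_size=2))
        ms = ms.set_index("module")
        assert np.isclose(ms.loc["blue", "module_significance"], np.abs(r[:10]).mean())
        assert np.isclose(ms.loc["grey", "module_significance"], np.abs(r[20:]).mean())


def test_antagonistic_modules_recovered_across_seeds():
    """Opposite module-trait signs and disjoint candidate lists, 20 seeds."""
    from culmnet.preprocess import normalize_log
    from culmnet.selection import top_k_by_significance, trait_specific_candidates
    from culmnet.simulate import ModuleSpec, SimulationConfig, simulate_dataset

    sign_ok = 0
    disjoint_ok = 0
    n_runs = 20
    for seed in range(n_runs):
        cfg = SimulationConfig(
            n_genes=2000, true_ranks=(2, 3, 2), noise_sd=0.1,
            module_spec=[
                ModuleSpec(size=200, trait_effect=1.0, inter_gene_cor=0.9),
                ModuleSpec(size=200, trait_effect=-1.0, inter_gene_cor=0.9),
            ],
            seed=100 + seed,
        )
        _, truth, counts, meta, traits = simulate_dataset(cfg, trait_noise_sd=0.2)
        lg = normalize_log(counts, mode="CPM")
        adj = adjacency(lg, beta=4.0)
        tom = tom_similarity(adj)
        asn = detect_modules(tom, NetworkConfig(min_module_size=50), adj=adj)
        mem = pd.Series(truth.module_membership).reindex(lg.gene_ids)
        best = {}
        for mod in ("M1", "M2"):
            counts_lab = asn.labels[mem.index[mem == mod]].value_counts()
            lab = counts_lab.index[0]
            if lab != GREY:
                best[mod] = lab
        if len(best) < 2 or best["M1"] == best["M2"]:
            continue
        eig = module_eigengene(lg, asn)
        mtr = module_trait_relation(eig, traits).set_index("module")
        if mtr.loc[best["M1"], "r"] * mtr.loc[best["M2"], "r"] < 0:
            sign_ok += 1
        gs = gene_significance(lg, traits["trait"])
        top = top_k_by_significance(gs, k=100)
        c1 = trait_specific_candidates(top, asn, target=best["M1"], exclude=best["M2"])
        c2 = trait_specific_candidates(top, asn, target=best["M2"], exclude=best["M1"])
        if not (set(c1.genes) & set(c2.genes)):
            disjoint_ok += 1
    assert sign_ok >= 19, f"opposite signs in only {sign_ok}/{n_runs} runs"
    assert disjoint_ok >= 19, f"disjoint candidates in only {disjoint_ok}/{n_runs} runs"
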