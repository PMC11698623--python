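"""Network construction: adjacency, TOM, soft threshold, modules, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from sklearn.metrics import adjusted_rand_score

import modulemir.coexpression as cx
import modulemir.preprocessing as pp
from modulemir import SimConfig, simulate_dataset
from modulemir.coexpression import (
    CoexpressionError,
    UNASSIGNED,
    apply_kme_filters,
    detect_modules,
    merge_close_modules,
    module_eigengenes,
    pearson_matrix,
    pick_soft_threshold,
    signed_adjacency,
    tom_similarity,
)


def frame(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=names, columns=names)


def random_correlation(seed, n=12, m=20):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, m))
    return frame(np.corrcoef(x))


class TestPearson:
    def test_duplicate_and_negated_gene(self, small_expr):
        expr = small_expr.copy()
        expr.loc["dup"] = expr.loc["g0"]
        expr.loc["neg"] = -expr.loc["g0"]
        cor = pearson_matrix(expr)
        assert cor.loc["g0", "dup"] == pytest.approx(1.0)
        assert cor.loc["g0", "neg"] == pytest.approx(-1.0)

    def test_matches_hand_computed_values(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0], [4.0, 3.0, 2.0, 1.0]],
            index=["a", "b", "c"],
            columns=list("wxyz"),
        )
        cor = pearson_matrix(expr)
        # hand evaluation of the Pearson formula on centred vectors
        assert cor.loc["a", "b"] == pytest.approx(0.6, abs=1e-12)
        assert cor.loc["a", "c"] == pytest.approx(-1.0, abs=1e-12)
        assert cor.loc["b", "c"] == pytest.approx(-0.6, abs=1e-12)

    def test_zero_variance_gene_named(self, small_expr):
        expr = small_expr.copy()
        expr.loc["flat"] = 2.5
        with pytest.raises(CoexpressionError, match="flat"):
            pearson_matrix(expr)


class TestSignedAdjacency:
    @pytest.mark.parametrize("beta", [1, 6, 16])
    def test_extreme_correlations(self, beta):
        cor = frame([[1.0, 1.0, -1.0], [1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])
        adj = signed_adjacency(cor, beta)
        assert adj.loc["g0", "g1"] == pytest.approx(1.0)
        assert adj.loc["g0", "g2"] == pytest.approx(0.0)

    def test_zero_correlation_at_power_16(self):
        cor = frame(np.eye(2))
        adj = signed_adjacency(cor, 16)
        assert adj.iloc[0, 1] == pytest.approx(0.5**16, rel=1e-12)

    def test_beta_below_one_rejected(self):
        with pytest.raises(CoexpressionError, match="beta"):
            signed_adjacency(frame(np.eye(2)), 0.5)

    def test_high_power_approaches_perfect_correlation_indicator(self):
        cor = random_correlation(0)
        adj = signed_adjacency(cor, 64).to_numpy()
        exact = np.isclose(cor.to_numpy(), 1.0)
        assert np.all(adj[~exact] < 1e-3)
        assert np.allclose(adj[exact], 1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), beta=st.integers(1, 30))
    def test_bounds_and_symmetry_property(self, seed, beta):
        adj = signed_adjacency(random_correlation(seed), beta).to_numpy()
        assert np.all((adj >= 0) & (adj <= 1))
        assert np.allclose(adj, adj.T)
        assert np.allclose(np.diag(adj), 1.0)


class TestTOM:
    def test_zero_off_diagonal_gives_identity_pattern(self):
        tom = tom_similarity(frame(np.eye(4))).to_numpy()
        assert np.allclose(tom, np.eye(4))

    def test_complete_graph_gives_all_ones(self):
        tom = tom_similarity(frame(np.ones((5, 5)))).to_numpy()
        assert np.allclose(tom, 1.0)

    def test_three_node_worked_example(self):
        adj = frame([[1.0, 0.8, 0.4], [0.8, 1.0, 0.2], [0.4, 0.2, 1.0]])
        tom = tom_similarity(adj)
        # (0.4*0.2 + 0.8) / (min(1.2, 1.0) + 1 - 0.8) = 0.88/1.2
        assert tom.loc["g0", "g1"] == pytest.approx(0.88 / 1.2, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), beta=st.integers(1, 12))
    def test_bounds_and_symmetry_property(self, seed, beta):
        adj = signed_adjacency(random_correlation(seed), beta)
        tom = tom_similarity(adj).to_numpy()
        assert np.all((tom >= 0) & (tom <= 1 + 1e-12))
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)


def scan_soft_threshold_oracle(expr, powers, target=0.9, n_bins=10):
    """Independent re-derivation of the scale-free scan (plain loops)."""
    cor = np.corrcoef(expr.to_numpy())
    chosen = None
    for beta in powers:
        adj = ((1 + cor) / 2.0) ** beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=0)
        k = k[k > 0]
        edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
        xs, ys = [], []
        for b in range(n_bins):
            sel = (k >= edges[b]) & (k < edges[b + 1])
            if b == n_bins - 1:
                sel = (k >= edges[b]) & (k <= edges[b + 1])
            if sel.sum() == 0:
                continue
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.sum() / k.size))
        slope, intercept = np.polyfit(xs, ys, 1)
        y = np.array(ys)
        fit = 1 - ((y - (slope * np.array(xs) + intercept)) ** 2).sum() / (
            (y - y.mean()) ** 2
        ).sum()
        if -np.sign(slope) * fit > target:
            chosen = beta
            break
    return chosen


@pytest.fixture(scope="module")
def heterogeneous_expr():
    """Many modules of varied size and loading plus background noise.

    The connectivity spectrum of this design is heavy-tailed enough for the
    scale-free criterion to be reachable (seed frozen after scanning the
    construction with the independent oracle).
    """
    rng = np.random.default_rng(4)
    n_samples = 100
    sizes = np.unique((10 * (1 / rng.uniform(0.05, 1, 25)) ** 0.8).astype(int))
    sizes = [min(s, 200) for s in sizes]
    blocks = []
    for s in sizes:
        factor = rng.normal(size=n_samples)
        loading = rng.uniform(0.4, 0.9)
        blocks.append(
            loading * factor + np.sqrt(1 - loading**2) * rng.normal(size=(s, n_samples))
        )
    background = rng.normal(size=(sum(len(b) for b in blocks), n_samples))
    x = np.vstack(blocks + [background])
    return pd.DataFrame(
        x, index=[f"g{i}" for i in range(x.shape[0])],
        columns=[f"s{j}" for j in range(n_samples)],
    )


class TestSoftThreshold:
    def test_chosen_power_matches_independent_scan(self, heterogeneous_expr):
        powers = list(range(1, 21))
        report = pick_soft_threshold(heterogeneous_expr, powers)
        expected = scan_soft_threshold_oracle(heterogeneous_expr, powers)
        assert expected is not None
        assert report.chosen == expected

    def test_vacuous_target_selects_smallest_power(self, normalized_genes):
        report = pick_soft_threshold(normalized_genes, [3, 7, 12], target_r2=-1.0)
        assert report.chosen == 3

    def test_mean_connectivity_strictly_decreases(self, normalized_genes):
        report = pick_soft_threshold(
            normalized_genes, list(range(1, 11)), target_r2=-1.0
        )
        mk = report.table["mean_connectivity"].to_numpy()
        assert np.all(np.diff(mk) < 0)


def planted_tom(seed=0, sizes=(50, 50), background=0, cor=0.9):
    cfg = SimConfig(
        seed=seed, n_samples=80, n_genes=sum(sizes) + background,
        module_sizes=sizes, background_genes=background, module_cor=cor,
        noise_sd=0.3, trait_modules=((0, 1, 0.5),), regulators=((0, 0, 0.5, 0.5),),
    )
    ds = simulate_dataset(cfg)
    expr = pp.normalize_log2(ds.gene_counts)
    tom = tom_similarity(signed_adjacency(pearson_matrix(expr), 6))
    return tom, ds.truth.partition, expr


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        tom, truth, _ = planted_tom()
        part = detect_modules(tom, min_module_size=30)
        assert adjusted_rand_score(truth.loc[part.index], part) == pytest.approx(1.0)

    def test_oversized_minimum_unassigns_everything(self):
        tom, _, _ = planted_tom()
        part = detect_modules(tom, min_module_size=200)
        assert (part == UNASSIGNED).all()

    def test_gene_permutation_equivariance(self):
        tom, _, _ = planted_tom()
        rng = np.random.default_rng(1)
        order = rng.permutation(len(tom))
        perm = tom.iloc[order, order]
        a = detect_modules(tom, 30)
        b = detect_modules(perm, 30).loc[a.index]
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)

    def test_degenerate_tom_does_not_crash(self):
        flat = frame(np.full((10, 10), 0.5))
        np.fill_diagonal(flat.values, 1.0)
        part = detect_modules(flat, min_module_size=2)
        assert set(part.unique()) <= {UNASSIGNED, "mod1"}


class TestEigengenes:
    def test_identical_profiles_give_that_profile(self):
        rng = np.random.default_rng(0)
        profile = rng.normal(size=30)
        expr = pd.DataFrame(
            np.tile(profile, (4, 1)) + rng.normal(scale=1e-9, size=(4, 30)),
            index=list("abcd"),
        )
        part = pd.Series(["m"] * 4, index=expr.index)
        me = module_eigengenes(expr, part)
        r = np.corrcoef(me.loc["m"], profile)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_orientation_positive_against_mean_profile(self, normalized_genes, default_dataset):
        truth = default_dataset.truth.partition
        me = module_eigengenes(normalized_genes, truth.loc[normalized_genes.index])
        for module in me.index:
            genes = truth.index[truth == module]
            mean_profile = (
                normalized_genes.loc[genes]
                .sub(normalized_genes.loc[genes].mean(axis=1), axis=0)
                .mean(axis=0)
            )
            assert np.corrcoef(me.loc[module], mean_profile)[0, 1] > 0

    def test_recovers_planted_latent_factor(self):
        # at loading 0.9 the eigengene tracks the factor closely; the floor
        # reflects the library-size coupling the count layer introduces
        cfg = SimConfig(seed=9, n_samples=100, module_cor=0.9, noise_sd=0.44)
        ds = simulate_dataset(cfg)
        expr = pp.normalize_log2(ds.gene_counts)
        me = module_eigengenes(expr, ds.truth.partition)
        r = np.corrcoef(me.loc["M1"], ds.truth.factors.loc["M1"])[0, 1]
        assert r >= 0.9


class TestMergeAndKme:
    def test_same_factor_modules_merge(self):
        # two labels carved out of one latent factor -> eigengene cor > 0.75
        rng = np.random.default_rng(4)
        factor = rng.normal(size=100)
        x = 0.9 * factor + 0.3 * rng.normal(size=(100, 100))
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(100)],
                            columns=[f"s{j}" for j in range(100)])
        split = pd.Series(["A"] * 50 + ["B"] * 50, index=expr.index)
        merged = merge_close_modules(expr, split, cut_height=0.25)
        assert merged.nunique() == 1

    def test_zero_cut_height_keeps_partition(self, normalized_genes, default_dataset):
        truth = default_dataset.truth.partition.loc[normalized_genes.index]
        merged = merge_close_modules(normalized_genes, truth, cut_height=0.0)
        assert adjusted_rand_score(truth, merged) == pytest.approx(1.0)

    def test_independent_modules_not_merged(self, normalized_genes, default_dataset):
        truth = default_dataset.truth.partition.loc[normalized_genes.index]
        merged = merge_close_modules(normalized_genes, truth, cut_height=0.25)
        assert merged[merged != UNASSIGNED].nunique() == 5

    def test_low_kme_member_unassigned(self, normalized_genes, default_dataset):
        truth = default_dataset.truth.partition.loc[normalized_genes.index].copy()
        # plant a background gene into module M1: its kME is near zero
        background = truth.index[truth == UNASSIGNED][0]
        truth[background] = "M1"
        me = module_eigengenes(normalized_genes, truth)
        out = apply_kme_filters(normalized_genes, truth, me)
        assert out[background] == UNASSIGNED

    def test_coreless_module_dissolved(self, normalized_genes, default_dataset):
        truth = default_dataset.truth.partition.loc[normalized_genes.index].copy()
        # a module made of background genes has no kME-0.5 core
        background = truth.index[truth == UNASSIGNED][:30]
        truth[background] = "fake"
        me = module_eigengenes(normalized_genes, truth)
        out = apply_kme_filters(normalized_genes, truth, me)
        assert (out[background] == UNASSIGNED).all()

    def test_tight_module_untouched(self):
        tom, truth, expr = planted_tom()
        me = module_eigengenes(expr, truth)
        out = apply_kme_filters(expr, truth, me)
        assert adjusted_rand_score(truth, out) == pytest.approx(1.0)
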