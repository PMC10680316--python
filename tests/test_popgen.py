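"""F_ST, f3/f4, block jackknife, informativeness, PCA, and NJ trees."""
from __future__ import annotations

import math

import numpy as np
import pytest

from forensnp import UndefinedStatisticError, ValidationError
from forensnp.loci import FrequencyTable, Locus
from forensnp.popgen import (DistanceMatrix, Phylogeny, block_jackknife,
                             f4_stat, fst_matrix, hudson_fst_components,
                             hudson_fst_pair, informativeness_in, nj_tree,
                             outgroup_f3, pca_fit_project)
from forensnp.qc import compute_allele_frequencies
from forensnp.simulate import (SyntheticConfig, generate_population_genotypes,
                               sample_balding_nichols_freqs)

from _oracles import classic_delete_one_jackknife


def table(pop_freqs: dict[str, list[float]], n_samples: float | None = 100.0,
          chroms=None) -> FrequencyTable:
    """Diallelic FrequencyTable from per-population allele-0 frequencies."""
    pops = list(pop_freqs)
    L = len(next(iter(pop_freqs.values())))
    chroms = chroms or [str(j % 22 + 1) for j in range(L)]
    loci = [Locus(f"L{j}", chroms[j], j + 1, ("A", "C")) for j in range(L)]
    freqs = np.zeros((len(pops), L, 3))
    for p, pop in enumerate(pops):
        freqs[p, :, 0] = pop_freqs[pop]
        freqs[p, :, 1] = 1.0 - np.asarray(pop_freqs[pop])
    ns = None if n_samples is None else np.full((len(pops), L), n_samples)
    return FrequencyTable(pops, loci, freqs, ns)


class TestBlockJackknife:
    def test_constant_contributions_zero_se(self):
        num = np.full(40, 0.7)
        est, se = block_jackknife(num, np.arange(40) // 10)
        assert est == pytest.approx(0.7)
        assert se == pytest.approx(0.0, abs=1e-14)

    def test_single_block_rejected(self):
        with pytest.raises(ValidationError):
            block_jackknife(np.ones(10), np.zeros(10, dtype=int))

    def test_equal_blocks_reduce_to_classic_formula(self):
        rng = np.random.default_rng(0)
        num = rng.normal(size=60)
        blocks = np.arange(60) // 10
        est, se = block_jackknife(num, blocks)
        theta_j = np.array([
            num[blocks != b].mean() for b in range(6)])
        assert se == pytest.approx(classic_delete_one_jackknife(est, theta_j), rel=1e-10)

    def test_iid_normal_se_tracks_analytic(self):
        rng = np.random.default_rng(1)
        ratios = []
        for _ in range(200):
            x = rng.normal(size=500)
            _, se = block_jackknife(x, np.arange(500) // 10)
            ratios.append(se / (x.std(ddof=1) / math.sqrt(500)))
        assert abs(np.mean(ratios) - 1) < 0.3


class TestHudsonFst:
    def test_single_locus_infinite_n(self):
        num, den = hudson_fst_components(np.array([0.2]), np.array([0.8]),
                                         np.array([np.nan]), np.array([np.nan]))
        assert num[0] / den[0] == pytest.approx(0.36 / 0.68)

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, 400)
        noise1 = np.clip(p + rng.normal(0, 0.02, 400), 0.01, 0.99)
        noise2 = np.clip(p + rng.normal(0, 0.02, 400), 0.01, 0.99)
        ft = table({"A": noise1, "B": noise2}, n_samples=1000)
        f = hudson_fst_pair(ft, "A", "B")
        assert abs(f.value) < max(2 * f.se, 0.002)

    def test_swap_symmetric(self):
        rng = np.random.default_rng(3)
        ft = table({"A": rng.uniform(0.2, 0.8, 100), "B": rng.uniform(0.2, 0.8, 100)})
        assert hudson_fst_pair(ft, "A", "B").value == pytest.approx(
            hudson_fst_pair(ft, "B", "A").value)

    def test_fixed_everywhere_is_undefined(self):
        ft = table({"A": [1.0, 1.0], "B": [1.0, 1.0]}, n_samples=None)
        with pytest.raises(UndefinedStatisticError):
            hudson_fst_pair(ft, "A", "B")

    def test_matrix_properties_and_star_ordering(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 3000)

        def drift(f):
            conc = (1 - f) / f
            return np.array([rng.beta(x * conc, (1 - x) * conc) for x in p])

        ft = table({"A": drift(0.02), "B": drift(0.02), "C": drift(0.2)},
                   n_samples=None)
        dm = fst_matrix(ft)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
        df = dm.to_dataframe()
        assert df.loc["A", "B"] < df.loc["A", "C"]
        assert df.loc["A", "B"] < df.loc["B", "C"]

    def test_group_means(self):
        dm = DistanceMatrix(["K", "X", "Y"], np.array([[0, .1, .3], [.1, 0, .2], [.3, .2, 0]]))
        means = dm.group_means("K", {"X": "east", "Y": "west"})
        assert means == {"east": pytest.approx(0.1), "west": pytest.approx(0.3)}


class TestF3F4:
    def test_f3_symmetric_and_nonnegative_for_duplicates(self):
        rng = np.random.default_rng(5)
        ft = table({"O": rng.uniform(0.2, 0.8, 500),
                    "A": rng.uniform(0.2, 0.8, 500),
                    "B": rng.uniform(0.2, 0.8, 500)}, n_samples=200)
        ab = outgroup_f3(ft, "O", "A", "B")
        ba = outgroup_f3(ft, "O", "B", "A")
        assert ab.value == pytest.approx(ba.value, rel=1e-12)
        assert ab.z == pytest.approx(ab.value / ab.se)

    def test_f3_matches_direct_per_locus_computation(self):
        rng = np.random.default_rng(6)
        o = rng.uniform(0.2, 0.8, 300)
        a = rng.uniform(0.2, 0.8, 300)
        b = rng.uniform(0.2, 0.8, 300)
        n_o = 150.0
        ft = table({"O": o, "A": a, "B": b}, n_samples=75.0)  # 150 haploids
        res = outgroup_f3(ft, "O", "A", "B")
        direct = np.mean((o - a) * (o - b) - o * (1 - o) / (n_o - 1))
        assert res.value == pytest.approx(direct, rel=1e-12)

    def test_f3_detects_shared_drift(self):
        # A and B share an internal branch; C is independent: f3(O; A, B)
        # must exceed f3(O; A, C) decisively
        rng = np.random.default_rng(7)
        p = rng.uniform(0.2, 0.8, 4000)

        def bn(base, f):
            conc = (1 - f) / f
            return np.array([rng.beta(x * conc, (1 - x) * conc) for x in base])

        shared = bn(p, 0.05)
        ft = table({"O": p, "A": bn(shared, 0.02), "B": bn(shared, 0.02),
                    "C": bn(p, 0.07)}, n_samples=None)
        f_shared = outgroup_f3(ft, "O", "A", "B", corrected=False)
        f_control = outgroup_f3(ft, "O", "A", "C", corrected=False)
        diff_z = (f_shared.value - f_control.value) / math.hypot(f_shared.se, f_control.se)
        assert diff_z > 3

    def test_f4_duplicate_population_is_exactly_zero(self):
        rng = np.random.default_rng(8)
        ft = table({"O": rng.uniform(0.2, 0.8, 300),
                    "K": rng.uniform(0.2, 0.8, 300),
                    "X": rng.uniform(0.2, 0.8, 300)}, n_samples=100)
        res = f4_stat(ft, "O", "K", "X", "X")
        assert res.value == 0.0
        assert math.isnan(res.z)

    def test_f4_antisymmetric(self):
        rng = np.random.default_rng(9)
        ft = table({p: rng.uniform(0.2, 0.8, 300) for p in "OKXY"}, n_samples=100)
        xy = f4_stat(ft, "O", "K", "X", "Y")
        yx = f4_stat(ft, "O", "K", "Y", "X")
        assert xy.value == pytest.approx(-yx.value, rel=1e-12)

    def test_f4_detects_directional_admixture(self):
        # 30% of K's ancestry comes from X's lineage: f4(O, K; X, Y) < 0, Z > 2
        rng = np.random.default_rng(10)
        p = rng.uniform(0.2, 0.8, 4000)

        def bn(base, f):
            conc = (1 - f) / f
            return np.array([rng.beta(x * conc, (1 - x) * conc) for x in base])

        x = bn(p, 0.1)
        y = bn(p, 0.1)
        k = 0.7 * bn(p, 0.1) + 0.3 * x
        ft = table({"O": p, "K": k, "X": x, "Y": y}, n_samples=None)
        res = f4_stat(ft, "O", "K", "X", "Y")
        assert res.value < 0
        assert res.z < -2


class TestInformativeness:
    def test_identical_groups_zero(self):
        ft = table({"A": [0.3, 0.5], "B": [0.3, 0.5]})
        res = informativeness_in(ft, {"A": "g1", "B": "g2"})
        assert np.allclose(res.values.values, 0.0, atol=1e-12)
        assert res.selected == []

    def test_fixed_difference_is_ln2(self):
        ft = table({"A": [1.0], "B": [0.0]})
        res = informativeness_in(ft, {"A": "g1", "B": "g2"})
        assert res.values.iloc[0] == pytest.approx(math.log(2))
        assert res.selected == ["L0"]

    def test_bounded_by_ln_k_and_nonnegative(self):
        rng = np.random.default_rng(11)
        ft = table({p: rng.uniform(0.01, 0.99, 200) for p in ("A", "B", "C")})
        res = informativeness_in(ft, {p: p for p in ("A", "B", "C")})
        assert (res.values.values >= -1e-12).all()
        assert (res.values.values <= math.log(3) + 1e-12).all()

    def test_median_increases_with_differentiation(self):
        medians = []
        for f in (0.02, 0.1, 0.3):
            cfg = SyntheticConfig(n_loci=500, populations=("A", "B"), F=f,
                                  seed=12, tri_allelic_fraction=0.0)
            ft = sample_balding_nichols_freqs(cfg)
            res = informativeness_in(ft, {"A": "g1", "B": "g2"})
            medians.append(res.values.median())
        assert medians[0] < medians[1] < medians[2]

    def test_unavailable_locus_skipped(self):
        ft = table({"A": [0.3, 0.5], "B": [0.4, 0.5]})
        ft.freqs[1, 0, :] = np.nan
        res = informativeness_in(ft, {"A": "g1", "B": "g2"})
        assert res.skipped == ["L0"]
        assert list(res.values.index) == ["L1"]


@pytest.mark.filterwarnings("ignore:dropping")
class TestPca:
    def test_projected_fit_member_matches_fitted_coordinates(self, two_pop_genotypes):
        gm, _ = two_pop_genotypes
        fit = gm.samples[:60]
        fitted = pca_fit_project(gm, fit, [])
        projected = pca_fit_project(gm, fit, [fit[0]])
        np.testing.assert_allclose(projected.coords.loc[fit[0]],
                                   fitted.coords.loc[fit[0]], atol=1e-8)

    def test_pc1_separates_balding_nichols_populations(self, two_pop_genotypes):
        gm, pops = two_pop_genotypes
        res = pca_fit_project(gm, gm.samples, [])
        pc1 = res.coords["PC1"]
        a = pc1[[s for s in gm.samples if pops[s] == "P1"]]
        b = pc1[[s for s in gm.samples if pops[s] == "P2"]]
        assert a.max() < b.min() or b.max() < a.min()

    def test_eigenvalues_match_independent_svd(self, two_pop_genotypes):
        gm, _ = two_pop_genotypes
        res = pca_fit_project(gm, gm.samples, [], n_components=5)
        # rebuild the standardized matrix independently and compare spectra
        dos = np.full((gm.n_samples, gm.n_loci), np.nan)
        for j, loc in enumerate(gm.loci):
            col = gm.column(j)
            counts = np.bincount(col[col[:, 0] != -1].ravel(), minlength=loc.n_alleles)
            major = int(np.argmax(counts)) if loc.n_alleles == 3 else 0
            ok = col[:, 0] != -1
            dos[ok, j] = (col[ok] != major).sum(axis=1)
        keep = np.nanvar(dos, axis=0) > 1e-12
        X = dos[:, keep]
        p_hat = (1 + np.nansum(X, axis=0)) / (2 + 2 * (~np.isnan(X)).sum(axis=0))
        Z = np.nan_to_num((X - 2 * p_hat) / np.sqrt(p_hat * (1 - p_hat)))
        s = np.linalg.svd(Z, compute_uv=False)
        np.testing.assert_allclose(res.eigenvalues,
                                   (s[:5] ** 2) / (gm.n_samples - 1), rtol=1e-8)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()


class TestNjTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float))
        tree = nj_tree(dm).to_skbio()
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(1.0),
                           "C": pytest.approx(3.0)}

    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,C:3,D:4) gives an additive distance matrix
        d = {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7}
        labels = ["A", "B", "C", "D"]
        m = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = labels.index(x), labels.index(y)
            m[i, j] = m[j, i] = v
        tree = nj_tree(DistanceMatrix(labels, m)).to_skbio()
        # verify additivity: patristic distances reproduce the input exactly
        for (x, y), v in d.items():
            got = tree.find(x).distance(tree.find(y))
            assert got == pytest.approx(v, abs=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(13)
        labels = ["P1", "P2", "P3", "P4", "P5"]
        m = rng.uniform(0.05, 0.4, size=(5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        t1 = nj_tree(DistanceMatrix(labels, m)).to_skbio()
        perm = [3, 0, 4, 1, 2]
        t2 = nj_tree(DistanceMatrix([labels[i] for i in perm],
                                    m[np.ix_(perm, perm)])).to_skbio()
        for x in labels:
            for y in labels:
                if x < y:
                    assert t1.find(x).distance(t1.find(y)) == pytest.approx(
                        t2.find(x).distance(t2.find(y)), abs=1e-9)

    def test_agrees_with_skbio_nj(self):
        # independent implementation check on a clean additive matrix
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(14)
        labels = ["A", "B", "C", "D", "E"]
        # build additive distances from a random tree via random splits
        base = rng.uniform(0.1, 1.0, size=(5, 5))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0)
        ours = nj_tree(DistanceMatrix(labels, m)).to_skbio()
        theirs = skbio_nj(SkbioDM(m, ids=labels))
        for x in labels:
            for y in labels:
                if x < y:
                    assert ours.find(x).distance(ours.find(y)) == pytest.approx(
                        theirs.find(x).distance(theirs.find(y)), abs=1e-6)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], dtype=float))
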