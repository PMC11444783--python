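import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kinskew.locus_stats import allele_frequencies
from kinskew.relatedness import (between_group_relatedness,
                                 breeder_permutation_test, class_relatedness,
                                 mantel_test, qg_pairs, qg_relatedness)
from kinskew.simdata import SimConfig, simulate_population

from conftest import hwe_matrix, make_matrix


def _roles_frame(pop):
    meta = pop.metadata()
    return meta.rename(columns={"id": "id"})


def _pedigree_pairs(seed, n_pairs, L=13, A=6, conc=0.46):
    """Parent-offspring and unrelated pairs with known truth."""
    rng = np.random.default_rng(seed)
    freqs = rng.dirichlet(np.full(A, conc), size=L)

    def draw(n):
        g = np.zeros((n, L, 2), dtype=np.int64)
        for l in range(L):
            g[:, l, :] = rng.choice(A, size=(n, 2), p=freqs[l]) + 1
        return np.sort(g, axis=2)

    parents, mates, unrel = draw(n_pairs), draw(n_pairs), draw(n_pairs)
    pick_p = rng.integers(2, size=(n_pairs, L))
    pick_m = rng.integers(2, size=(n_pairs, L))
    kids = np.sort(np.stack([
        np.take_along_axis(parents, pick_p[:, :, None], 2)[:, :, 0],
        np.take_along_axis(mates, pick_m[:, :, None], 2)[:, :, 0]], axis=2),
        axis=2)
    from kinskew.genotypes import GenotypeMatrix
    blocks = np.concatenate([parents, kids, unrel])
    ids = [f"i{k}" for k in range(blocks.shape[0])]
    m = GenotypeMatrix(ids, [f"L{l}" for l in range(L)], blocks)
    po = [(f"i{k}", f"i{k + n_pairs}") for k in range(n_pairs)]
    uu = [(f"i{k}", f"i{k + 2 * n_pairs}") for k in range(n_pairs)]
    return m, po, uu


class TestQgRelatedness:
    def test_clone_limit(self):
        m = make_matrix({"x": [(1, 1)] * 5, "y": [(1, 1)] * 5,
                         "filler": [(2, 2)] * 5})
        freqs = allele_frequencies(m)
        # force p = 0.5 everywhere for the closed-form check
        freqs.table[:, 1] = 0.5
        freqs.table[:, 2] = 0.5
        rel = qg_relatedness(m, freqs)
        assert rel.pair("x", "y") == pytest.approx(1.0)

    def test_parent_offspring_mean_half(self):
        m, po, _ = _pedigree_pairs(seed=0, n_pairs=2000)
        r = qg_pairs(m, allele_frequencies(m), po)
        assert np.mean(r) == pytest.approx(0.5, abs=0.02)

    def test_unrelated_mean_zero(self):
        m, _, uu = _pedigree_pairs(seed=0, n_pairs=2000)
        r = qg_pairs(m, allele_frequencies(m), uu)
        assert np.mean(r) == pytest.approx(0.0, abs=0.02)

    def test_matrix_matches_naive_loop(self):
        m, _, _ = _pedigree_pairs(seed=1, n_pairs=4)
        m = m.subset(m.ids[:10])
        freqs = allele_frequencies(m)
        rel = qg_relatedness(m, freqs)
        pf = freqs.table
        for x in range(10):
            for y in range(10):
                if x == y:
                    continue
                sums = []
                for (i, j) in ((x, y), (y, x)):
                    num = den = 0.0
                    for l in range(m.n_loci):
                        x1, x2 = (int(v) for v in m.alleles[i, l])
                        y1, y2 = (int(v) for v in m.alleles[j, l])
                        s = int(x1 == y1) + int(x1 == y2) \
                            + int(x2 == y1) + int(x2 == y2)
                        num += 0.5 * s - pf[l, x1] - pf[l, x2]
                        den += 1 + int(x1 == x2) - pf[l, x1] - pf[l, x2]
                    sums.append(num / den)
                assert rel.r[x, y] == pytest.approx(np.mean(sums), abs=1e-9)

    def test_symmetric(self):
        m, _, _ = _pedigree_pairs(seed=2, n_pairs=10)
        rel = qg_relatedness(m, allele_frequencies(m))
        assert np.allclose(rel.r, rel.r.T, equal_nan=True)

    def test_mean_over_sample_near_zero(self):
        pop = simulate_population(SimConfig(seed=4, n_seasons=1))
        m = pop.true_genotypes.subset(pop.true_genotypes.ids[:94])
        rel = qg_relatedness(m, allele_frequencies(m))
        vals = rel.r[~np.isnan(rel.r)]
        assert abs(vals.mean()) <= 0.02

    def test_no_shared_loci_excluded(self):
        m = make_matrix({"x": [(1, 1), (0, 0)], "y": [(0, 0), (1, 1)],
                         "z": [(1, 2), (1, 2)]})
        rel = qg_relatedness(m, allele_frequencies(m))
        assert np.isnan(rel.pair("x", "y"))
        assert rel.excluded[0, 1]


class TestClassRelatedness:
    def test_single_pair_class_is_exact(self):
        m, _, _ = _pedigree_pairs(seed=3, n_pairs=2)
        rel = qg_relatedness(m, allele_frequencies(m))
        meta = pd.DataFrame({
            "id": [m.ids[0], m.ids[1]],
            "sex": ["F", "F"],
            "group": ["g", "g"],
            "role": ["subordinate", "subordinate"],
        })
        table = class_relatedness(rel, meta)
        row = table[table["class"] == "sub_f_sub_f"].iloc[0]
        assert row["n_pairs"] == 1
        assert row["mean_r"] == pytest.approx(rel.pair(m.ids[0], m.ids[1]))

    def test_full_sib_cohorts_raise_sub_f_class(self):
        pop = simulate_population(SimConfig(seed=6, group_size_mean=4,
                                            n_seasons=5))
        m = pop.true_genotypes
        rel = qg_relatedness(m, allele_frequencies(m))
        table = class_relatedness(rel, _roles_frame(pop), pop.litters)
        sub_f = table.set_index("class").loc["sub_f_sub_f", "mean_r"]
        dom_pair = table.set_index("class").loc["dominant_pair", "mean_r"]
        assert sub_f > dom_pair + 0.1

    def test_full_skew_within_litter_half(self):
        pop = simulate_population(SimConfig(
            seed=7, dominant_maternity_share=1.0, dominant_paternity_share=1.0,
            n_seasons=2))
        m = pop.true_genotypes
        # founder-based reference frequencies: the full-sib expectation of 0.5
        # holds against an unrelated reference; sample frequencies inflated by
        # the sibs themselves bias the estimator downward
        founders = [i.id for i in pop.individuals if i.birth_season < 0]
        rel = qg_relatedness(m, allele_frequencies(m.subset(founders)))
        table = class_relatedness(rel, _roles_frame(pop), pop.litters)
        wl = table.set_index("class").loc["within_litter"]
        assert wl["n_pairs"] > 30
        assert wl["mean_r"] == pytest.approx(0.5, abs=0.06)

    def test_empty_class_is_nan(self):
        m, _, _ = _pedigree_pairs(seed=3, n_pairs=2)
        rel = qg_relatedness(m, allele_frequencies(m))
        meta = pd.DataFrame({"id": m.ids[:2], "sex": ["M", "F"],
                             "group": ["g", "g"],
                             "role": ["dominant", "dominant"]})
        table = class_relatedness(rel, meta).set_index("class")
        assert np.isnan(table.loc["pup_pup", "mean_r"])
        assert table.loc["pup_pup", "n_pairs"] == 0


class TestBreederPermutation:
    def test_power_against_kin_structured_groups(self):
        pop = simulate_population(SimConfig(seed=10, group_size_mean=4,
                                            n_seasons=5))
        m = pop.true_genotypes
        rel = qg_relatedness(m, allele_frequencies(m))
        res = breeder_permutation_test(rel, _roles_frame(pop), n=1000, seed=0)
        assert res.p_value <= 0.01

    def test_identical_genotypes_p_one(self):
        # clones at every locus under non-degenerate reference frequencies:
        # every pairwise r is identical, so every null value equals observed
        rows = {f"i{k}": [(1, 1)] * 5 for k in range(6)}
        m = make_matrix(rows)
        freqs = allele_frequencies(m)
        freqs.table[:, 1] = 0.5
        freqs.table = np.column_stack([freqs.table, np.full(5, 0.5)])
        rel = qg_relatedness(m, freqs)
        meta = pd.DataFrame({
            "id": list(rows), "sex": ["M", "F", "M", "F", "M", "F"],
            "group": ["g"] * 6,
            "role": ["dominant", "dominant"] + ["subordinate"] * 4,
        })
        res = breeder_permutation_test(rel, meta, n=200, seed=0)
        assert res.p_value == 1.0

    def test_extreme_p_floor(self, small_population):
        pop = small_population
        m = pop.true_genotypes
        rel = qg_relatedness(m, allele_frequencies(m))
        res = breeder_permutation_test(rel, _roles_frame(pop), n=1000, seed=1)
        assert res.p_value >= 1 / 1001
        assert len(res.null) == 1000

    def test_determinism(self, small_population):
        pop = small_population
        rel = qg_relatedness(pop.true_genotypes,
                             allele_frequencies(pop.true_genotypes))
        a = breeder_permutation_test(rel, _roles_frame(pop), n=300, seed=9)
        b = breeder_permutation_test(rel, _roles_frame(pop), n=300, seed=9)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null, b.null)

    def test_no_eligible_partner_errors(self):
        rows = {"dm": [(1, 2)] * 5, "df": [(1, 2)] * 5}
        m = make_matrix(rows)
        rel = qg_relatedness(m, allele_frequencies(m))
        meta = pd.DataFrame({"id": ["dm", "df"], "sex": ["M", "F"],
                             "group": ["g", "h"],  # different groups
                             "role": ["dominant", "dominant"]})
        with pytest.raises(ValueError):
            breeder_permutation_test(rel, meta, n=10, seed=0)


class TestBetweenGroup:
    def test_hand_oracle_three_groups(self):
        m, _, _ = _pedigree_pairs(seed=5, n_pairs=3)
        m = m.subset(m.ids[:6])
        groups = {i: f"g{k // 2}" for k, i in enumerate(m.ids)}
        rel = qg_relatedness(m, allele_frequencies(m))
        table = between_group_relatedness(rel, groups)
        # brute-force dyad average for (g0, g1)
        vals = [rel.pair(x, y) for x in m.ids[:2] for y in m.ids[2:4]]
        assert table.loc["g0", "g1"] == pytest.approx(np.mean(vals))
        assert np.allclose(table.values, table.values.T, equal_nan=True)

    def test_identical_genotypes_constant(self):
        rows = {f"i{k}": [(1, 1)] * 4 for k in range(6)}
        m = make_matrix(rows)
        groups = {i: f"g{k // 2}" for k, i in enumerate(m.ids)}
        freqs = allele_frequencies(m)
        freqs.table[:, 1] = 0.5
        freqs.table = np.column_stack([freqs.table, np.full(4, 0.5)])
        rel = qg_relatedness(m, freqs)
        table = between_group_relatedness(rel, groups)
        off = table.values[~np.eye(3, dtype=bool)]
        assert np.allclose(off, off[0])


class TestMantel:
    def _sym(self, rng, k=7):
        m = rng.random((k, k))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_self_correlation(self):
        m1 = self._sym(np.random.default_rng(0))
        res = mantel_test(m1, m1, n_perm=999, seed=0)
        assert res.r == pytest.approx(1.0)
        # only a resampled identity permutation can match r = 1, so p sits at
        # the floor up to the few identity draws among 999 free permutations
        assert res.p_value <= 5 / 1000

    def test_constant_matrix_errors(self):
        m1 = self._sym(np.random.default_rng(0))
        m2 = np.ones_like(m1)
        with pytest.raises(ValueError, match="zero variance"):
            mantel_test(m1, m2)

    def test_too_small(self):
        with pytest.raises(ValueError):
            mantel_test(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_null_calibration(self):
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(200):
            res = mantel_test(self._sym(rng), self._sym(rng),
                              n_perm=199, seed=int(rng.integers(2**31)))
            pvals.append(res.p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_one_tailed_option(self):
        m1 = self._sym(np.random.default_rng(5))
        res = mantel_test(m1, m1, n_perm=99, seed=0, alternative="greater")
        assert res.p_value == pytest.approx(1 / 100)
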