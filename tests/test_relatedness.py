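"""Dyadic likelihood machinery, ML relatedness/classification, inbreeding."""

import math

import numpy as np
import pytest

from conftest import hwe_genotype_probs
from scatcap.datasets import load_cuis_relatedness
from scatcap.relatedness import (
    ANCHORS,
    _GRID,
    classify_relationship,
    dyad_loglik,
    estimate_F_ml,
    estimate_r_ml,
    pair_ibd_probs,
    r_from_k,
    relatedness_matrix,
    summarize_relatedness,
)
from scatcap.simulate import SimulationConfig, simulate_dyad


def enum_ibd_probs(g1, g2, p):
    """Exact enumeration oracle for P(g1, g2 | 0/1/2 shared IBD alleles)."""
    ks = list(p)
    u = lambda x, y: (min(x, y), max(x, y))
    P0 = sum(
        p[a] * p[b] * p[c] * p[d]
        for a in ks for b in ks for c in ks for d in ks
        if u(a, b) == g1 and u(c, d) == g2
    )
    P1 = sum(
        p[s] * p[x] * p[y]
        for s in ks for x in ks for y in ks
        if u(s, x) == g1 and u(s, y) == g2
    )
    P2 = sum(
        p[s] * p[t] for s in ks for t in ks if u(s, t) == g1 and u(s, t) == g2
    )
    return P0, P1, P2


P4 = {1: 0.2, 2: 0.3, 3: 0.4, 4: 0.1}
GENOS = [(1, 1), (1, 2), (2, 2), (3, 4), (1, 3), (2, 3)]


class TestDyadLikelihood:
    @pytest.mark.parametrize("g1", GENOS)
    @pytest.mark.parametrize("g2", GENOS)
    def test_ibd_tables_match_enumeration(self, g1, g2):
        exact = enum_ibd_probs(g1, g2, P4)
        table = pair_ibd_probs(g1, g2, P4)
        for e, t in zip(exact, table):
            assert t == pytest.approx(e, abs=1e-12)

    def test_unrelated_is_product_of_hwe_probs(self):
        gp = hwe_genotype_probs(P4)
        freqs = {"L1": P4, "L2": P4}
        g1 = {"L1": (1, 2), "L2": (1, 1)}
        g2 = {"L1": (3, 4), "L2": (2, 3)}
        expected = math.log(gp[(1, 2)] * gp[(3, 4)]) + math.log(gp[(1, 1)] * gp[(2, 3)])
        assert dyad_loglik(g1, g2, ANCHORS["U"], freqs) == pytest.approx(expected)

    def test_full_ibd_identical_heterozygote(self):
        # k = (0,0,1), both AB: per-locus likelihood is P(AB) = 2 p_a p_b
        freqs = {"L1": P4}
        ll = dyad_loglik({"L1": (1, 2)}, {"L1": (1, 2)}, (0.0, 0.0, 1.0), freqs)
        assert ll == pytest.approx(math.log(2 * 0.2 * 0.3))

    def test_missing_loci_skipped(self):
        freqs = {"L1": P4, "L2": P4}
        full = dyad_loglik({"L1": (1, 2)}, {"L1": (1, 2)}, ANCHORS["U"], freqs)
        with_gap = dyad_loglik(
            {"L1": (1, 2), "L2": None}, {"L1": (1, 2), "L2": (1, 1)}, ANCHORS["U"], freqs
        )
        assert with_gap == pytest.approx(full)


class TestEstimateR:
    def test_identical_rare_allele_genotypes_near_one(self):
        freqs = {f"L{i}": {1: 0.05, 2: 0.95} for i in range(20)}
        g = {f"L{i}": (1, 1) for i in range(20)}
        est = estimate_r_ml(g, g, freqs)
        assert est.r >= 0.9

    def test_optimum_dominates_whole_simplex_grid(self, fixture_freqs):
        rng = np.random.default_rng(2)
        for cat in ("U", "PO", "FS"):
            g1, g2 = simulate_dyad(cat, fixture_freqs, rng)
            est = estimate_r_ml(g1, g2, fixture_freqs)
            from scatcap.relatedness import _locus_prob_matrix

            P = _locus_prob_matrix(g1, g2, fixture_freqs)
            grid_ll = np.log(np.maximum(_GRID @ P.T, 1e-300)).sum(axis=1)
            assert est.loglik >= grid_ll.max() - 1e-9

    def test_symmetric_in_dyad_order(self, fixture_freqs):
        rng = np.random.default_rng(3)
        g1, g2 = simulate_dyad("FS", fixture_freqs, rng)
        a = estimate_r_ml(g1, g2, fixture_freqs)
        b = estimate_r_ml(g2, g1, fixture_freqs)
        assert a.r == pytest.approx(b.r, abs=1e-9)

    def test_invariant_to_allele_relabeling(self):
        freqs1 = {"L%d" % i: {1: 0.3, 2: 0.7} for i in range(10)}
        freqs2 = {"L%d" % i: {11: 0.3, 22: 0.7} for i in range(10)}
        g1a = {"L%d" % i: (1, 2) for i in range(10)}
        g1b = {"L%d" % i: (11, 22) for i in range(10)}
        g2a = {"L%d" % i: (1, 1) for i in range(10)}
        g2b = {"L%d" % i: (11, 11) for i in range(10)}
        assert estimate_r_ml(g1a, g2a, freqs1).r == pytest.approx(
            estimate_r_ml(g1b, g2b, freqs2).r, abs=1e-9
        )


class TestClassification:
    def test_no_shared_allele_locus_excludes_po(self):
        freqs = {"L1": P4, "L2": P4}
        g1 = {"L1": (1, 2), "L2": (1, 1)}
        g2 = {"L1": (3, 4), "L2": (1, 1)}  # L1 shares nothing
        cat, ll = classify_relationship(g1, g2, freqs)
        assert ll["PO"] == -math.inf
        assert cat != "PO"

    def test_identical_common_genotypes_favor_fs(self):
        freqs = {f"L{i}": {1: 0.5, 2: 0.5} for i in range(12)}
        g = {f"L{i}": (1, 2) for i in range(12)}
        cat, ll = classify_relationship(g, g, freqs)
        assert cat == "FS"
        assert ll["FS"] >= max(ll["U"], ll["HS"], ll["PO"])

    def test_tie_prefers_less_related(self):
        # AA vs AB at p = q = 0.5 gives an exact three-way tie
        # (U = HS = PO = 0.125); the least related anchor must win
        freqs = {"L1": {1: 0.5, 2: 0.5}}
        cat, ll = classify_relationship({"L1": (1, 1)}, {"L1": (1, 2)}, freqs)
        assert ll["U"] == pytest.approx(ll["PO"], abs=1e-12)
        assert cat == "U"


class TestInbreeding:
    def test_all_heterozygous_gives_zero(self):
        freqs = {f"L{i}": {1: 0.5, 2: 0.5} for i in range(10)}
        g = {f"L{i}": (1, 2) for i in range(10)}
        est = estimate_F_ml(g, freqs, n_boot=50, seed=1)
        assert est.f == 0.0
        assert est.ci[0] == 0.0

    def test_all_homozygous_gives_one(self):
        freqs = {f"L{i}": {1: 0.5, 2: 0.5} for i in range(20)}
        g = {f"L{i}": (1, 1) for i in range(20)}
        est = estimate_F_ml(g, freqs, n_boot=0)
        assert est.f == 1.0

    def test_optimum_dominates_f_grid(self, fixture_freqs):
        rng = np.random.default_rng(4)
        from scatcap.simulate import simulate_selfed
        g = simulate_selfed(fixture_freqs, 1, rng)[0]
        est = estimate_F_ml(g, fixture_freqs, n_boot=0)
        from scatcap.relatedness import _f_loglik_rows
        rows = _f_loglik_rows(g, fixture_freqs)
        ll = rows.sum(axis=0)
        f_idx = int(round(est.f * 1000))
        assert ll[f_idx] >= ll.max() - 1e-9

    def test_needs_three_loci(self):
        freqs = {"L1": {1: 0.5, 2: 0.5}, "L2": {1: 0.5, 2: 0.5}}
        g = {"L1": (1, 1), "L2": (1, 2)}
        with pytest.raises(Exception):
            estimate_F_ml(g, freqs, n_boot=0)


class TestSummaries:
    def test_published_matrix_worked_example(self):
        df = load_cuis_relatedness()
        s = summarize_relatedness(df["r_ml"].to_numpy())
        assert s.n_pairs == 36
        assert s.mean == pytest.approx(0.155, abs=5e-4)
        assert s.n_low == 27
        assert s.n_ge_high == 8
        s_tri = summarize_relatedness(df["r_triadic"].to_numpy())
        assert s_tri.n_gt_high == 2

    def test_all_zero_matrix(self):
        s = summarize_relatedness(np.zeros(10))
        assert s.mean == 0.0 and s.sd == 0.0 and s.n_ge_high == 0

    def test_matrix_pipeline_smoke(self, fixture_freqs):
        rng = np.random.default_rng(9)
        from scatcap.dtypes import GenotypeTable
        from scatcap.simulate import _draw_hwe_genotype

        loci = list(fixture_freqs)
        samples = [f"i{k}" for k in range(4)]
        calls = {
            (s, l): _draw_hwe_genotype(fixture_freqs[l], rng)
            for s in samples
            for l in loci
        }
        table = GenotypeTable(samples, loci, calls)
        mat = relatedness_matrix(table, fixture_freqs)
        assert np.allclose(mat.r, mat.r.T, equal_nan=True)
        summ = summarize_relatedness(mat)
        assert summ.n_pairs == 6
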