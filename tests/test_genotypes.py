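"""Genotype I/O, relatedness, relatedness filtering, Rousset's a-hat, D_PS."""

import itertools

import numpy as np
import pytest

import landgen as lg
from landgen.genotypes import (MISSING, GenotypeParseError,
                               GenotypeValidationError, _pair_locus_coeffs)

from conftest import random_genotypes


# -- reading and round-trips ---------------------------------------------

class TestReadWrite:
    def test_round_trip_preserves_alleles(self, rng, tmp_path):
        table = random_genotypes(rng, n=8, missing_frac=0.15)
        path = tmp_path / "geno.csv"
        lg.write_genotypes(table, path)
        back = lg.read_genotypes(path)
        assert back.ids == table.ids
        assert back.loci == table.loci
        # allele pairs are unordered
        assert np.array_equal(np.sort(back.alleles, axis=2),
                              np.sort(table.alleles, axis=2))

    def test_small_table_shape(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("individual_id,L1,L2\na,1/2,3/3\nb,2/2,3/4\nc,1/1,4/4\n")
        t = lg.read_genotypes(path)
        assert t.n == 3 and t.n_loci == 2

    def test_zero_slash_zero_is_missing_not_allele_zero(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("individual_id,L1,L2\na,0/0,1/2\nb,1/2,2/2\n")
        t = lg.read_genotypes(path)
        assert (t.alleles[0, 0] == MISSING).all()
        assert 0 not in t.allele_frequencies()[0]

    def test_two_column_dialect(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("individual_id,L1_1,L1_2\na,1,2\nb,2,2\n")
        t = lg.read_genotypes(path)
        assert t.loci == ["L1"] and t.alleles[0, 0].tolist() == [1, 2]

    def test_malformed_token_names_row_and_column(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("individual_id,L1\na,1/x\n")
        with pytest.raises(GenotypeParseError, match="row 0.*'L1'"):
            lg.read_genotypes(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "g.csv"
        path.write_text("individual_id,L1\na,1/2\na,2/2\n")
        with pytest.raises(GenotypeValidationError, match="duplicate"):
            lg.read_genotypes(path)

    def test_summary_mean_individuals_per_locality(self, rng):
        t = random_genotypes(rng, n=12)
        t.localities = [f"s{k % 4}" for k in range(12)]
        s = t.summary()
        assert s["n_localities"] == 4
        assert s["mean_individuals_per_locality"] == pytest.approx(3.0)


# -- ML relatedness -------------------------------------------------------

class TestRelatedness:
    def test_likelihood_coefficients_sum_to_one(self):
        freqs = {1: 0.5, 2: 0.3, 3: 0.2}
        gts = [(a, b) for a in freqs for b in freqs if a <= b]
        for k in [(1, 0, 0), (0, 1, 0), (0, 0, 1), (0.25, 0.5, 0.25)]:
            tot = sum(np.dot(k, _pair_locus_coeffs(g1, g2, freqs))
                      for g1, g2 in itertools.product(gts, gts))
            assert tot == pytest.approx(1.0, abs=1e-12)

    def test_clones_estimated_near_one(self, rng):
        base = random_genotypes(rng, n=20, n_loci=20, n_alleles=8)
        alleles = base.alleles.copy()
        alleles[1] = alleles[0]  # plant a clone pair
        t = lg.GenotypeTable(base.ids, alleles, base.loci)
        r = lg.estimate_relatedness(t, pairs=[("i00", "i01")])
        assert r.values[0, 1] >= 0.99

    def test_mendelian_simulation_oracle(self, rng):
        """Parent-offspring dyads average ~0.5, unrelated dyads ~0, using
        Mendelian dropping at 20 loci with 8 equifrequent alleles."""
        n_loci, n_all, n_pairs = 20, 8, 40

        def draw():
            return rng.integers(1, n_all + 1, size=(n_loci, 2))

        parents = [draw() for _ in range(n_pairs)]
        kids = []
        for p in parents:
            c = np.empty_like(p)
            for l in range(n_loci):
                c[l, 0] = p[l, rng.integers(2)]
                c[l, 1] = rng.integers(1, n_all + 1)
            kids.append(c)
        ids = ([f"p{k}" for k in range(n_pairs)]
               + [f"c{k}" for k in range(n_pairs)])
        t = lg.GenotypeTable(ids, np.array(parents + kids),
                             [f"L{j}" for j in range(n_loci)])
        po = lg.estimate_relatedness(t, pairs=[(f"p{k}", f"c{k}")
                                               for k in range(n_pairs)])
        po_vals = [po.values[k, n_pairs + k] for k in range(n_pairs)]
        un = lg.estimate_relatedness(t, pairs=[(f"p{k}", f"p{k + 1}")
                                               for k in range(n_pairs - 1)])
        un_vals = [un.values[k, k + 1] for k in range(n_pairs - 1)]
        se = np.std(po_vals) / np.sqrt(len(po_vals))
        assert abs(np.mean(po_vals) - 0.5) < max(3 * se, 0.05)
        assert np.mean(un_vals) < 0.1

    def test_values_in_unit_interval(self, rng):
        t = random_genotypes(rng, n=6, n_loci=8)
        r = lg.estimate_relatedness(t)
        off = r.values[np.triu_indices(6, k=1)]
        assert np.all((off >= 0) & (off <= 1))

    def test_monomorphic_data_rejected(self):
        alleles = np.ones((4, 5, 2), dtype=int)
        t = lg.GenotypeTable(list("abcd"), alleles, [f"L{j}" for j in range(5)])
        with pytest.raises(GenotypeValidationError, match="monomorphic"):
            lg.estimate_relatedness(t)


# -- relatedness filtering ------------------------------------------------

class TestFilterRelated:
    def _matrix(self, ids, entries):
        n = len(ids)
        vals = np.zeros((n, n))
        for (i, j), v in entries.items():
            vals[i, j] = vals[j, i] = v
        return lg.PairwiseMatrix(ids, vals, "relatedness_r")

    def test_no_dyad_above_threshold_is_noop(self, rng):
        t = random_genotypes(rng, n=4)
        r = self._matrix(t.ids, {(0, 1): 0.3, (2, 3): 0.5})  # 0.5 retained
        assert lg.filter_related(t, r, 0.5).ids == t.ids

    def test_single_related_pair_forces_one_removal(self, rng):
        t = random_genotypes(rng, n=3)
        r = self._matrix(t.ids, {(0, 1): 0.6})
        kept = lg.filter_related(t, r, 0.5)
        assert len(kept.ids) == 2 and t.ids[2] in kept.ids

    @pytest.mark.parametrize("trial", range(10))
    def test_output_never_contains_above_threshold_dyad(self, trial):
        rng = np.random.default_rng(100 + trial)
        t = random_genotypes(rng, n=8)
        vals = np.round(rng.random((8, 8)), 2)
        vals = (vals + vals.T) / 2
        r = lg.PairwiseMatrix(t.ids, vals, "relatedness_r")
        thr = float(rng.random())
        kept = lg.filter_related(t, r, thr)
        sub = r.subset(kept.ids).values
        off = sub[np.triu_indices(len(kept.ids), k=1)]
        assert not np.any(off > thr)


# -- Rousset's a-hat ------------------------------------------------------

def brute_force_ar(table):
    """Independent oracle: enumerate the allele draws directly."""
    typed = table.typed_mask()
    n, L = table.n, table.n_loci
    qw = []
    for l in range(L):
        w = [1.0 if table.alleles[i, l, 0] == table.alleles[i, l, 1] else 0.0
             for i in range(n) if typed[i, l]]
        qw.append(np.mean(w))
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            num = den = 0.0
            for l in range(L):
                if not (typed[i, l] and typed[j, l]):
                    continue
                q = np.mean([table.alleles[i, l, a] == table.alleles[j, l, b]
                             for a in range(2) for b in range(2)])
                num += qw[l] - q
                den += 1.0 - qw[l]
            out[i, j] = num / den if den else np.nan
    return out


class TestRoussetAr:
    def test_hand_enumerated_toy(self, toy_genotypes):
        ar = lg.rousset_ar(toy_genotypes)
        assert ar.values[0, 1] == pytest.approx(2.0)   # AA vs BB
        assert ar.values[0, 2] == pytest.approx(0.5)   # AA vs AB

    def test_agrees_with_brute_force_enumeration(self):
        for trial in range(8):
            rng = np.random.default_rng(200 + trial)
            t = random_genotypes(rng, n=rng.integers(3, 7),
                                 n_loci=rng.integers(1, 4), n_alleles=3,
                                 missing_frac=0.1 if trial % 2 else 0.0)
            try:
                ar = lg.rousset_ar(t)
            except GenotypeValidationError:
                continue
            expect = brute_force_ar(t)
            ok = np.isfinite(expect)
            assert np.allclose(ar.values[ok], expect[ok], atol=1e-12)

    def test_invariant_to_allele_relabeling(self, toy_genotypes):
        relabeled = lg.GenotypeTable(
            toy_genotypes.ids, 10 * toy_genotypes.alleles, toy_genotypes.loci)
        a = lg.rousset_ar(toy_genotypes).values
        b = lg.rousset_ar(relabeled).values
        assert np.allclose(a[np.isfinite(a)], b[np.isfinite(b)])

    def test_all_identical_homozygotes_rejected(self):
        alleles = np.ones((4, 3, 2), dtype=int)
        t = lg.GenotypeTable(list("abcd"), alleles, ["L1", "L2", "L3"])
        with pytest.raises(GenotypeValidationError, match="undefined"):
            lg.rousset_ar(t)


# -- D_PS -----------------------------------------------------------------

class TestDps:
    def test_identical_genotypes_share_everything(self, rng):
        t = random_genotypes(rng, n=3)
        t.alleles[1] = t.alleles[0]
        d = lg.dps(t)
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_alleles_share_nothing(self):
        alleles = np.array([[[1, 2]], [[3, 4]], [[1, 3]]])
        t = lg.GenotypeTable(list("abc"), alleles, ["L1"])
        assert lg.dps(t).values[0, 1] == pytest.approx(0.0)

    def test_heterozygote_vs_homozygote_shares_half(self):
        alleles = np.array([[[1, 2]], [[1, 1]], [[2, 2]]])
        t = lg.GenotypeTable(list("abc"), alleles, ["L1"])
        assert lg.dps(t).values[0, 1] == pytest.approx(0.5)

    def test_bounded_in_unit_interval(self, rng):
        t = random_genotypes(rng, n=8, missing_frac=0.2)
        vals = lg.dps(t).values
        ok = np.isfinite(vals)
        assert np.all((vals[ok] >= 0) & (vals[ok] <= 1))
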