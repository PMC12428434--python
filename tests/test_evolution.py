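"""K2P distances, neighbor joining, newick output, and NG86 Ka/Ks."""

import itertools
import math
import random

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mitocr import evolution as ev
from mitocr import synthetic_data as sd
from mitocr.seq_stats import CODON_TO_AA, SENSE_CODONS, STOP_CODONS


# ---------------------------------------------------------------------------
# K2P

class TestK2P:
    def test_identical_sequences(self):
        r = ev.k2p_distance("ACGT" * 10, "ACGT" * 10)
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)

    def test_closed_form_transitions_only(self):
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        r = ev.k2p_distance(a, b)
        assert r.P == 0.1 and r.Q == 0.0
        assert math.isclose(r.d, -0.5 * math.log(0.8), abs_tol=1e-12)

    def test_closed_form_mixed(self):
        # P = 0.25, Q = 0.25 against an independent formula evaluation
        a = "A" * 100
        b = "G" * 25 + "C" * 25 + "A" * 50
        r = ev.k2p_distance(a, b)
        expected = -0.5 * math.log((1 - 2 * 0.25 - 0.25)
                                   * math.sqrt(1 - 2 * 0.25))
        assert math.isclose(r.d, expected, abs_tol=1e-12)

    def test_pairwise_deletion(self):
        r = ev.k2p_distance("ACGN", "ACGT")
        assert r.n_sites == 3 and r.d == 0.0

    def test_saturation_flagged(self):
        r = ev.k2p_distance("A" * 10, "G" * 10)
        assert r.d is None and "saturat" in r.undefined_reason

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError):
            ev.k2p_distance("NNN", "ACG")
        with pytest.raises(ValueError):
            ev.k2p_distance("AC", "ACG")

    def test_simulation_recovery(self):
        # simulate an explicit two-rate substitution process at distance d
        # and check the estimate against the truth
        rng = np.random.default_rng(5)
        d_true = 0.2
        alpha, beta = d_true / 2, d_true / 4  # alpha + 2*beta = d
        bases = "ACGT"
        ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
        n = 10_000
        anc = rng.choice(list(bases), size=n)
        der = []
        for x in anc:
            cur = x
            for _ in range(rng.poisson(d_true)):
                if rng.random() < alpha / d_true:
                    cur = ts[cur]
                else:
                    tv = [b for b in bases if b != cur and b != ts[cur]]
                    cur = tv[int(rng.integers(2))]
            der.append(cur)
        r = ev.k2p_distance("".join(anc), "".join(der))
        assert abs(r.d - d_true) < 0.02  # ~3 standard errors at 10 kb


# ---------------------------------------------------------------------------
# NJ + newick

def _tree_from_newick(nwk, namespace):
    t = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=namespace)
    t.deroot()
    t.is_rooted = False
    t.update_bipartitions()
    return t


def _random_dendropy_tree(rng, n):
    ns = dendropy.TaxonNamespace([f"t{k}" for k in range(n)])
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=ns, rng=rng)
    for e in t.preorder_edge_iter():
        e.length = rng.uniform(0.05, 1.0)
    return t


def _distance_frame(t):
    pdm = t.phylogenetic_distance_matrix()
    taxa = list(t.taxon_namespace)
    labels = [x.label for x in taxa]
    return pd.DataFrame([[pdm.distance(a, b) for b in taxa] for a in taxa],
                        index=labels, columns=labels)


class TestNJ:
    def test_three_taxon_closed_form(self):
        D = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]],
                         index=list("ABC"), columns=list("ABC"), dtype=float)
        tree = ev.nj_tree(D)
        lengths = {c.label: bl for c, bl in tree.root.children}
        assert math.isclose(lengths["A"], (3 + 4 - 5) / 2)
        assert math.isclose(lengths["B"], (3 + 5 - 4) / 2)
        assert math.isclose(lengths["C"], (4 + 5 - 3) / 2)

    def test_four_taxon_additive_recovery(self):
        # distances from ((A:1,B:2):3,(C:4,D:5))
        D = pd.DataFrame(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        assert ev.write_newick(ev.nj_tree(D)) == "(C:4,D:5,(A:1,B:2):3);"

    def test_additive_recovery_random_trees(self):
        rng = random.Random(7)
        for _ in range(50):
            t = _random_dendropy_tree(rng, rng.randint(5, 8))
            tree = ev.nj_tree(_distance_frame(t))
            t2 = _tree_from_newick(ev.write_newick(tree), t.taxon_namespace)
            t.deroot()
            t.is_rooted = False
            t.update_bipartitions()
            assert dendropy.calculate.treecompare.symmetric_difference(
                t, t2) == 0

    def test_taxon_order_invariance(self):
        rng = random.Random(3)
        t = _random_dendropy_tree(rng, 6)
        D = _distance_frame(t)
        perm = list(D.index)[::-1]
        t1 = _tree_from_newick(ev.write_newick(ev.nj_tree(D)),
                               t.taxon_namespace)
        t2 = _tree_from_newick(
            ev.write_newick(ev.nj_tree(D.loc[perm, perm])),
            t.taxon_namespace)
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_two_taxa_convenience(self):
        D = pd.DataFrame([[0, 4], [4, 0]], index=["A", "B"],
                         columns=["A", "B"], dtype=float)
        assert ev.write_newick(ev.nj_tree(D)) == "(A:2,B:2);"

    def test_matrix_validation(self):
        bad = pd.DataFrame([[0, 1], [2, 0]], index=list("AB"),
                           columns=list("AB"), dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            ev.nj_tree(bad)
        nan = pd.DataFrame([[0, float("nan")], [float("nan"), 0]],
                           index=list("AB"), columns=list("AB"))
        with pytest.raises(ValueError, match="undefined"):
            ev.nj_tree(nan)

    def test_negative_branch_flag_and_clamp(self):
        D = pd.DataFrame(
            [[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 1], [6, 6, 1, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        # perturb to force a slightly negative terminal branch
        D.loc["A", "B"] = D.loc["B", "A"] = 7.5
        tree = ev.nj_tree(D)
        clamped = ev.nj_tree(D, clamp=True)
        if tree.has_negative_branches:
            assert not clamped.has_negative_branches

    def test_newick_round_trip_and_quoting(self):
        D = pd.DataFrame([[0, 2, 3], [2, 0, 3], [3, 3, 0]],
                         index=["sp one", "sp:two", "c"],
                         columns=["sp one", "sp:two", "c"], dtype=float)
        nwk = ev.write_newick(ev.nj_tree(D))
        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == [
            "c", "sp one", "sp:two"]

    def test_against_independent_nj_implementation(self):
        import io

        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = random.Random(11)
        t = _random_dendropy_tree(rng, 7)
        D = _distance_frame(t)
        ours = _tree_from_newick(ev.write_newick(ev.nj_tree(D)),
                                 t.taxon_namespace)
        sk = skbio_nj(DistanceMatrix(D.values, ids=list(D.index)))
        buf = io.StringIO()
        sk.write(buf)
        theirs = _tree_from_newick(buf.getvalue(), t.taxon_namespace)
        assert dendropy.calculate.treecompare.symmetric_difference(
            ours, theirs) == 0


# ---------------------------------------------------------------------------
# NG86

def _brute_force_pathways(c1, c2):
    """Independent pathway enumerator for a codon pair."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, syn, non, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            syn += CODON_TO_AA[cur] == CODON_TO_AA[nxt]
            non += CODON_TO_AA[cur] != CODON_TO_AA[nxt]
            cur = nxt
        if ok:
            paths.append((syn, non))
    if not paths:
        for order in itertools.permutations(diff):
            cur, syn, non = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                syn += CODON_TO_AA[cur] == CODON_TO_AA[nxt]
                non += CODON_TO_AA[cur] != CODON_TO_AA[nxt]
                cur = nxt
            paths.append((syn, non))
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


class TestNG86:
    def test_identical_cds(self):
        r = ev.ng86_kaks("ATGGCA", "ATGGCA")
        assert (r.Ka, r.Ks) == (0.0, 0.0)
        assert r.ratio is None
        assert ev.ng86_kaks("ATGGCA", "ATGGCA", zero_over_zero=0.0).ratio == 0.0

    def test_fourfold_third_position_is_synonymous(self):
        r = ev.ng86_kaks("GTT", "GTC")  # Val -> Val
        assert (r.Sd, r.Nd) == (1.0, 0.0)

    def test_sites_sum_invariant_random_pairs(self):
        rng = np.random.default_rng(2)
        sense = list(SENSE_CODONS)
        for _ in range(30):
            n = int(rng.integers(2, 60))
            a = "".join(rng.choice(sense, size=n))
            b = "".join(rng.choice(sense, size=n))
            r = ev.ng86_kaks(a, b)
            assert math.isclose(r.S_sites + r.N_sites, 3 * r.n_codons,
                                abs_tol=1e-9)

    def test_multi_difference_codons_match_pathway_oracle(self):
        rng = np.random.default_rng(4)
        sense = list(SENSE_CODONS)
        for _ in range(200):
            c1, c2 = rng.choice(sense, size=2)
            r = ev.ng86_kaks(c1, c2)
            sd_, nd_ = _brute_force_pathways(c1, c2)
            assert math.isclose(r.Sd, sd_, abs_tol=1e-12)
            assert math.isclose(r.Nd, nd_, abs_tol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from(SENSE_CODONS), min_size=2, max_size=30),
           st.lists(st.sampled_from(SENSE_CODONS), min_size=2, max_size=30))
    def test_swap_symmetry(self, ca, cb):
        n = min(len(ca), len(cb))
        a, b = "".join(ca[:n]), "".join(cb[:n])
        r1, r2 = ev.ng86_kaks(a, b), ev.ng86_kaks(b, a)
        assert math.isclose(r1.S_sites, r2.S_sites, abs_tol=1e-9)
        assert math.isclose(r1.Sd, r2.Sd, abs_tol=1e-9)
        assert math.isclose(r1.Nd, r2.Nd, abs_tol=1e-9)

    def test_stop_and_ambiguous_codons_excluded(self):
        r = ev.ng86_kaks("ATGTAAGNA", "ATGTAAGCA")
        assert r.n_codons == 1
        assert r.n_excluded_codons == 2

    def test_saturated_proportion_flagged(self):
        # force pN >= 0.75 via a contrived highly divergent pair
        a = "ATG" * 40
        b = "TGG" * 40
        r = ev.ng86_kaks(a, b)
        if r.pN >= 0.75:
            assert r.Ka is None and r.undefined_reason is not None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.ng86_kaks("ATGGCA", "ATG")


class TestKaKsRecovery:
    def test_planted_omega_recovered(self):
        b = sd.evolve_cds(seed=3, n_codons=5000, omega=0.2)
        r = ev.ng86_kaks(b.records["ancestor"], b.records["descendant"])
        assert 0.1 <= r.ratio <= 0.3  # within +/-50% of the plant

    def test_omega_ordering_preserved(self):
        est = {}
        for om in (0.05, 0.2):
            b = sd.evolve_cds(seed=9, n_codons=4000, omega=om)
            r = ev.ng86_kaks(b.records["ancestor"], b.records["descendant"])
            est[om] = r.ratio
        assert est[0.05] < est[0.2]

    def test_neutral_evolution_near_one(self):
        b = sd.evolve_cds(seed=4, n_codons=4000, omega=1.0, kappa=1.0,
                          target_ks=0.15)
        r = ev.ng86_kaks(b.records["ancestor"], b.records["descendant"])
        assert 0.75 <= r.ratio <= 1.25


class TestProfile:
    def _gene_sets(self, seed=0, omega=0.1):
        rng = np.random.default_rng(seed)
        sets = {"focal": {}, "bg1": {}, "bg2": {}}
        for gi, gene in enumerate(("g1", "g2")):
            b = sd.evolve_cds(seed=seed * 10 + gi, n_codons=400, omega=omega,
                              target_ks=0.2)
            sets["focal"][gene] = b.records["ancestor"]
            sets["bg1"][gene] = b.records["descendant"]
            b2 = sd.evolve_cds(seed=seed * 10 + gi + 5, n_codons=400,
                               omega=omega, target_ks=0.2)
            sets["bg2"][gene] = b2.records["descendant"]
        return sets

    def test_identical_focal_and_background(self):
        cds = sd.evolve_cds(seed=1, n_codons=200, omega=0.2).records["ancestor"]
        df = ev.kaks_profile({"a": {"g": cds}, "b": {"g": cds}}, focal="a")
        assert set(df["gene"]) == {"g", "concatenated"}
        assert (df["Ka"] == 0).all()

    def test_concatenated_row_pools_counts(self):
        sets = self._gene_sets()
        df = ev.kaks_profile(sets, focal="focal")
        row = df[(df.gene == "concatenated") & (df.species == "bg1")].iloc[0]
        # oracle: Ka/Ks of the concatenated alignment itself
        a = sets["focal"]["g1"] + sets["focal"]["g2"]
        b = sets["bg1"]["g1"] + sets["bg1"]["g2"]
        pooled = ev.ng86_kaks(a, b)
        assert math.isclose(row["Ka"], pooled.Ka, abs_tol=1e-9)
        assert math.isclose(row["Ks"], pooled.Ks, abs_tol=1e-9)
        # and it is NOT the mean of per-gene ratios in general
        per_gene = df[(df.gene != "concatenated") & (df.species == "bg1")]
        assert not math.isclose(row["ratio"], per_gene["ratio"].mean(),
                                abs_tol=1e-12)

    def test_missing_gene_yields_null_with_warning(self):
        sets = self._gene_sets()
        del sets["bg1"]["g2"]
        with pytest.warns(UserWarning, match="missing"):
            df = ev.kaks_profile(sets, focal="focal")
        cell = df[(df.gene == "g2") & (df.species == "bg1")]
        assert cell["Ka"].isna().all()

    def test_focal_must_exist(self):
        with pytest.raises(KeyError):
            ev.kaks_profile({"a": {}}, focal="zzz")
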