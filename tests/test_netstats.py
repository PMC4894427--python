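import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metadiv as md
from metadiv.exceptions import MetadivError
from metadiv.io import AbundanceMatrix, ReactionNetwork, SampleTable
from metadiv.netstats import (connectivity, coupling_test,
                              direction_concordance, pair_correlations,
                              split_and_compare, _pair_table_matrices)

from oracles import (exhaustive_relabel_coupling_p, exhaustive_split_p)


class TestConnectivity:
    def test_degree_counts_distinct_reactions(self):
        net = ReactionNetwork(
            compound_reaction={("C1", "R1"), ("C1", "R2"), ("C2", "R2")},
            reaction_enzyme=set(), compound_pathway=set())
        deg = connectivity(net)
        assert deg["C1"] == 2
        assert deg["C2"] == 1

    def test_unannotated_metabolite_excluded(self):
        net = ReactionNetwork(compound_reaction={("C1", "R1")},
                              reaction_enzyme=set(),
                              compound_pathway=set())
        deg = connectivity(net, ["C1", "C_absent"])
        assert list(deg.index) == ["C1"]

    def test_synthetic_network_matches_planted_tail(self):
        cfg = md.SimConfig(n_metabolites=300, n_reactions=200, seed=1)
        net = md.make_network(cfg)
        deg = connectivity(net)
        assert (deg > 20).sum() >= 1


class TestSplitAndCompare:
    def test_boundary_degree_goes_to_low_group(self):
        degrees = pd.Series([1, 5, 20, 25],
                            index=["a", "b", "c", "d"])
        lr = pd.Series([1.0, 2.0, 3.0, 4.0],
                       index=["a", "b", "c", "d"])
        res = split_and_compare(degrees, lr, cutoff=20, B=50, rng=0)
        assert res.n_low == 3 and res.n_high == 1

    def test_identical_values_give_zero_stat_and_p_one(self):
        degrees = pd.Series([1, 2, 30, 40], index=list("abcd"))
        lr = pd.Series([2.0, 2.0, 2.0, 2.0], index=list("abcd"))
        res = split_and_compare(degrees, lr, B=100, rng=0)
        assert res.statistic == 0.0
        assert res.permutation_p == 1.0

    def test_empty_group_is_error(self):
        degrees = pd.Series([1, 2], index=["a", "b"])
        lr = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(MetadivError, match="20"):
            split_and_compare(degrees, lr, cutoff=20, B=10, rng=0)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(8)
        lr_vals = rng.exponential(3, 6)
        degrees = pd.Series([1, 2, 3, 30, 40, 50],
                            index=[f"m{i}" for i in range(6)])
        lr = pd.Series(lr_vals, index=degrees.index)
        B = 4000
        res = split_and_compare(degrees, lr, cutoff=20, B=B, rng=1)
        exact = exhaustive_split_p(lr_vals, n_low=3,
                                   statistic=res.statistic)
        # add-one convention and Monte-Carlo error
        assert abs(res.permutation_p - exact) < 0.02 + 1.0 / (B + 1)


def _abundance_from_individual_means(means, n_rep=2):
    """means: DataFrame metabolites x individuals (6 per species)."""
    rows = []
    cols = []
    for ind in means.columns:
        for r in range(1, n_rep + 1):
            cols.append(f"{ind}_r{r}")
    data = np.repeat(means.to_numpy(), n_rep, axis=1)
    sp_of = {"H": "human", "C": "chimpanzee", "R": "rhesus"}
    meta = pd.DataFrame({
        "species": [sp_of[c[0]] for c in cols],
        "individual": [c.rsplit("_", 1)[0] for c in cols],
        "replicate": [int(c[-1]) for c in cols],
        "batch": ["b" + c[-1] for c in cols],
        "sex": "unknown",
    }, index=pd.Index(cols, name="measurement_id"))
    return (AbundanceMatrix(pd.DataFrame(data, index=means.index,
                                         columns=cols)),
            SampleTable(meta))


class TestPairCorrelations:
    def _toy_net(self, ids, same=()):
        cr = {(m, "R_shared") for m in same}
        for k, m in enumerate(ids):
            cr.add((m, f"R{k}"))
        return ReactionNetwork(compound_reaction=cr,
                               reaction_enzyme=set(),
                               compound_pathway=set())

    def test_identical_profiles_give_r_one(self):
        inds = [f"{t}{i}" for t in "HCR" for i in range(3)]
        rng = np.random.default_rng(0)
        prof = rng.normal(0, 1, 9)
        means = pd.DataFrame([prof, prof,
                              rng.normal(0, 1, 9)],
                             index=["m1", "m2", "m3"], columns=inds)
        matrix, samples = _abundance_from_individual_means(means)
        net = self._toy_net(["m1", "m2", "m3"], same=("m1", "m2"))
        pt = pair_correlations(matrix, samples, net)
        row = pt[(pt["m1"] == "m1") & (pt["m2"] == "m2")].iloc[0]
        for sp in md.SPECIES:
            assert row[f"r_{sp}"] == pytest.approx(1.0)
        assert row["same_reaction"]

    def test_exact_anticollinearity_gives_minus_one(self):
        inds = [f"{t}{i}" for t in "HCR" for i in range(3)]
        m1 = np.tile([1.0, 2.0, 3.0], 3)
        m2 = np.tile([6.0, 4.0, 2.0], 3)
        means = pd.DataFrame([m1, m2, np.tile([0.0, 1.0, 5.0], 3)],
                             index=["m1", "m2", "m3"], columns=inds)
        matrix, samples = _abundance_from_individual_means(means)
        pt = pair_correlations(matrix, samples,
                               self._toy_net(["m1", "m2", "m3"]))
        row = pt[(pt["m1"] == "m1") & (pt["m2"] == "m2")].iloc[0]
        for sp in md.SPECIES:
            assert row[f"r_{sp}"] == pytest.approx(-1.0)

    def test_planted_coupling_recovered_in_all_species(self,
                                                       default_sim):
        pt = pair_correlations(default_sim.abundance,
                               default_sim.samples,
                               default_sim.network)
        for sp in md.SPECIES:
            same = pt.loc[pt["same_reaction"], f"r_{sp}"].median()
            diff = pt.loc[~pt["same_reaction"], f"r_{sp}"].median()
            assert same > diff

    def test_zero_variance_metabolite_dropped_with_count(self):
        inds = [f"{t}{i}" for t in "HCR" for i in range(3)]
        rng = np.random.default_rng(1)
        means = pd.DataFrame([np.ones(9), rng.normal(0, 1, 9),
                              rng.normal(0, 1, 9)],
                             index=["flat", "m2", "m3"], columns=inds)
        matrix, samples = _abundance_from_individual_means(means)
        pt = pair_correlations(matrix, samples,
                               self._toy_net(["flat", "m2", "m3"]))
        assert pt.attrs["n_dropped_zero_variance"] == 1
        assert "flat" not in set(pt["m1"]) | set(pt["m2"])


class TestCouplingTest:
    def _pair_table(self, r_by_pair, same_pairs):
        rows = []
        ids = sorted({m for p in r_by_pair for m in p})
        for (a, b), r in r_by_pair.items():
            rows.append({"m1": a, "m2": b,
                         "same_reaction": (a, b) in same_pairs
                         or (b, a) in same_pairs,
                         "r_human": r, "r_chimpanzee": r,
                         "r_rhesus": r})
        return pd.DataFrame(rows)

    def test_equal_correlations_give_p_one(self):
        pairs = {(f"m{a}", f"m{b}"): 0.4
                 for a in range(4) for b in range(a + 1, 4)}
        pt = self._pair_table(pairs, same_pairs={("m0", "m1")})
        res = coupling_test(pt, "human", B=200, rng=0)
        assert res.median_same == res.median_diff
        assert res.permutation_p == 1.0

    def test_constant_group_has_degenerate_ci(self):
        pairs = {(f"m{a}", f"m{b}"): 0.0
                 for a in range(4) for b in range(a + 1, 4)}
        pairs[("m0", "m1")] = 0.7
        pt = self._pair_table(pairs, same_pairs={("m0", "m1")})
        res = coupling_test(pt, "human", B=200, rng=0)
        assert res.ci_same == (0.7, 0.7)

    def test_permutation_matches_exhaustive_relabeling(self):
        rng = np.random.default_rng(5)
        ids = [f"m{i}" for i in range(4)]
        pairs = {}
        for a in range(4):
            for b in range(a + 1, 4):
                pairs[(ids[a], ids[b])] = float(rng.uniform(-1, 1))
        pt = self._pair_table(pairs,
                              same_pairs={("m0", "m1"), ("m2", "m3")})
        B = 4000
        res = coupling_test(pt, "human", B=B, rng=3)
        R, S = _pair_table_matrices(pt, "r_human")
        exact = exhaustive_relabel_coupling_p(
            R, S, res.median_same - res.median_diff)
        assert abs(res.permutation_p - exact) < 0.02 + 1.0 / (B + 1)

    def test_b_below_one_is_error(self):
        pt = self._pair_table({("a", "b"): 0.1, ("a", "c"): 0.2,
                               ("b", "c"): 0.3},
                              same_pairs={("a", "b")})
        with pytest.raises(MetadivError):
            coupling_test(pt, "human", B=0)


class _FrameDC:
    def __init__(self, frame):
        self.frame = frame


def _dc_for_pairs(direction, q, ids, pair="HC"):
    rows = [{"metabolite_id": m, "pair": pair, "LR": 1.0, "p": q[m],
             "q": q[m], "direction": direction[m]} for m in ids]
    return _FrameDC(pd.DataFrame(rows))


class TestDirectionConcordance:
    def _pt(self, pairs):
        return pd.DataFrame([{"m1": a, "m2": b, "same_reaction": sr,
                              "r_human": 0.0, "r_chimpanzee": 0.0,
                              "r_rhesus": 0.0}
                             for a, b, sr in pairs])

    def test_same_signs_concordant(self):
        ids = ["a", "b"]
        dc = _dc_for_pairs({"a": 1, "b": 1}, {"a": 0.01, "b": 0.01}, ids)
        res = direction_concordance(self._pt([("a", "b", True)]), dc,
                                    B=50, rng=0)
        assert res.prop_same_reaction == 1.0

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        # 2x2 table [[3,1],[1,3]]: one-sided P = (C43*C41*... ) = 17/70
        ids = [f"s{i}" for i in range(8)] + [f"d{i}" for i in range(8)]
        direction = {}
        q = {m: 0.01 for m in ids}
        pairs = []
        # same-reaction: 3 concordant, 1 discordant
        same_members = [("s0", "s1", 1, 1), ("s2", "s3", 1, 1),
                        ("s4", "s5", -1, -1), ("s6", "s7", 1, -1)]
        diff_members = [("d0", "d1", 1, 1), ("d2", "d3", 1, -1),
                        ("d4", "d5", -1, 1), ("d6", "d7", 1, -1)]
        for a, b, da, db in same_members:
            direction[a], direction[b] = da, db
            pairs.append((a, b, True))
        for a, b, da, db in diff_members:
            direction[a], direction[b] = da, db
            pairs.append((a, b, False))
        dc = _dc_for_pairs(direction, q, ids)
        res = direction_concordance(self._pt(pairs), dc, B=100, rng=0)
        assert res.table == [[3, 1], [1, 3]]
        assert res.fisher_p == pytest.approx(17 / 70, rel=1e-10)

    def test_all_discordant_gives_zero_proportions(self):
        ids = ["a", "b", "c", "d"]
        direction = {"a": 1, "b": -1, "c": 1, "d": -1}
        q = {m: 0.01 for m in ids}
        dc = _dc_for_pairs(direction, q, ids)
        pt = self._pt([("a", "b", True), ("c", "d", False)])
        res = direction_concordance(pt, dc, B=50, rng=0)
        assert res.prop_same_reaction == 0.0
        assert res.prop_different == 0.0

    def test_at_least_one_dc_mode_keeps_more_pairs(self):
        ids = ["a", "b", "c", "d"]
        direction = {m: 1 for m in ids}
        q = {"a": 0.01, "b": 0.5, "c": 0.5, "d": 0.5}
        dc = _dc_for_pairs(direction, q, ids)
        pt = self._pt([("a", "b", True), ("c", "d", False)])
        strict = direction_concordance(pt, dc, mode="both_dc",
                                       B=50, rng=0)
        loose = direction_concordance(pt, dc, mode="at_least_one_dc",
                                      B=50, rng=0)
        assert strict.n_same + strict.n_diff == 0
        assert loose.n_same == 1 and loose.n_diff == 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(MetadivError):
            direction_concordance(self._pt([]), _FrameDC(
                pd.DataFrame(columns=["metabolite_id", "pair", "q",
                                      "direction"])), mode="nope")


class TestPermutationConventions:
    def test_p_in_add_one_range_and_reproducible(self, default_sim):
        pt = pair_correlations(default_sim.abundance,
                               default_sim.samples, default_sim.network)
        r1 = coupling_test(pt, "human", B=99, rng=42)
        r2 = coupling_test(pt, "human", B=99, rng=42)
        assert r1.permutation_p == r2.permutation_p
        assert 1 / 100 <= r1.permutation_p <= 1.0
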