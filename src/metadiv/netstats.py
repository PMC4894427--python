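"""Reaction-network statistics for differential concentration.

Three analyses tie metabolite divergence to network context:

* connectivity: metabolites in many reactions (degree > cutoff, default
  20) versus few, compared on their LRT statistics with a one-sided
  permutation test (low-connectivity metabolites are expected to
  diverge more);
* coupling: within-species Pearson correlation (across individual
  means, replicates collapsed) of same-reaction metabolite pairs versus
  different-reaction pairs, with percentile-bootstrap CIs on the group
  medians and a permutation null that relabels metabolite identities on
  the network — preserving both the network topology and the empirical
  correlation structure;
* direction concordance: among differentially concentrated pairs, the
  proportion changing in the same direction across species, same- versus
  different-reaction, with a one-sided Fisher exact test.

"Different-reaction" pairs are restricted to metabolites that are
network-annotated but share no reaction, so the contrast is not
confounded by annotation status. Permutation p-values use the add-one
convention ``(1 + #{perm >= obs}) / (B + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MetadivError
from .io import AbundanceMatrix, ReactionNetwork, SampleTable, SPECIES

__all__ = ["connectivity", "split_and_compare", "pair_correlations",
           "coupling_test", "direction_concordance",
           "ConnectivityResult", "CouplingResult", "ConcordanceResult"]


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------

def connectivity(network: ReactionNetwork,
                 metabolite_ids=None) -> pd.Series:
    """Distinct-reaction degree per metabolite.

    Metabolites absent from the network are excluded (degree undefined).
    """
    if metabolite_ids is None:
        ids = sorted({c for c, _ in network.compound_reaction})
    else:
        ids = [m for m in metabolite_ids if network.degree(m) > 0]
    return pd.Series([network.degree(m) for m in ids],
                     index=pd.Index(ids, name="metabolite_id"),
                     name="degree")


@dataclass
class ConnectivityResult:
    cutoff: int
    n_low: int
    n_high: int
    median_low: float
    median_high: float
    statistic: float           # median(low) - median(high)
    permutation_p: float
    B: int


def split_and_compare(degrees: pd.Series, lr_values: pd.Series,
                      cutoff: int = 20, B: int = 1000,
                      rng=None) -> ConnectivityResult:
    """Low- vs high-connectivity comparison of LRT statistics.

    Low means degree <= cutoff (the boundary falls in the low group).
    One-sided permutation test of median(low) - median(high) > 0 by B
    random reassignments of group labels preserving group sizes.
    """
    rng = np.random.default_rng(rng)
    common = degrees.index.intersection(lr_values.index)
    deg = degrees.loc[common]
    lr = lr_values.loc[common].to_numpy(dtype=float)
    low_mask = (deg <= cutoff).to_numpy()
    n_low, n_high = int(low_mask.sum()), int((~low_mask).sum())
    if n_low == 0 or n_high == 0:
        raise MetadivError(
            f"connectivity cutoff {cutoff} leaves an empty group")
    med_low = float(np.median(lr[low_mask]))
    med_high = float(np.median(lr[~low_mask]))
    obs = med_low - med_high
    count = 0
    for _ in range(B):
        perm = rng.permutation(lr)
        if (np.median(perm[:n_low]) - np.median(perm[n_low:])) >= obs:
            count += 1
    return ConnectivityResult(
        cutoff=cutoff, n_low=n_low, n_high=n_high,
        median_low=med_low, median_high=med_high, statistic=float(obs),
        permutation_p=(1 + count) / (B + 1), B=B)


# ---------------------------------------------------------------------------
# pairwise within-species correlations
# ---------------------------------------------------------------------------

def _individual_means(matrix: AbundanceMatrix, samples: SampleTable):
    """Collapse replicates: metabolites x individuals, plus species map."""
    meta = samples.data.loc[matrix.measurement_ids]
    means = matrix.data.T.groupby(meta["individual"]).mean().T
    sp = meta.drop_duplicates("individual").set_index("individual")[
        "species"]
    return means, sp.loc[means.columns]


def pair_correlations(matrix: AbundanceMatrix, samples: SampleTable,
                      network: ReactionNetwork,
                      method: str = "pearson") -> pd.DataFrame:
    """Within-species correlation for every annotated metabolite pair.

    Replicates are averaged per individual first; the correlation is then
    computed across the individuals of each species separately. Columns:
    m1, m2, same_reaction, r_human, r_chimpanzee, r_rhesus. Metabolites
    with zero variance within some species are dropped (count attached as
    ``frame.attrs['n_dropped_zero_variance']``).
    """
    means, sp = _individual_means(matrix, samples)
    annotated = sorted(set(matrix.metabolite_ids)
                       & {c for c, _ in network.compound_reaction})
    sub = means.loc[annotated]

    keep = pd.Series(True, index=sub.index)
    for species in SPECIES:
        cols = sp.index[sp == species]
        if len(cols) >= 2:
            keep &= sub[cols].std(axis=1) > 0
    dropped = int((~keep).sum())
    sub = sub.loc[keep]
    ids = list(sub.index)
    n = len(ids)

    corr = {}
    for species in SPECIES:
        cols = sp.index[sp == species]
        if len(cols) < 3:
            raise MetadivError(f"need >=3 individuals in {species}")
        block = sub[cols]
        if method == "spearman":
            block = block.rank(axis=1)
        corr[species] = np.corrcoef(block.to_numpy())

    same = np.zeros((n, n), dtype=bool)
    for a in range(n):
        ra = network.reactions_of(ids[a])
        for b in range(a + 1, n):
            if ra & network.reactions_of(ids[b]):
                same[a, b] = same[b, a] = True

    iu = np.triu_indices(n, k=1)
    frame = pd.DataFrame({
        "m1": [ids[a] for a in iu[0]],
        "m2": [ids[b] for b in iu[1]],
        "same_reaction": same[iu],
        "r_human": corr["human"][iu],
        "r_chimpanzee": corr["chimpanzee"][iu],
        "r_rhesus": corr["rhesus"][iu],
    })
    frame.attrs["n_dropped_zero_variance"] = dropped
    return frame


@dataclass
class CouplingResult:
    species: str
    median_same: float
    median_diff: float
    ci_same: tuple
    ci_diff: tuple
    permutation_p: float
    n_same: int
    n_diff: int
    B: int

    def summary(self) -> str:
        return (f"{self.species}: median r same-reaction "
                f"{self.median_same:.3f} "
                f"[{self.ci_same[0]:.3f}, {self.ci_same[1]:.3f}] "
                f"(n={self.n_same}) vs different "
                f"{self.median_diff:.3f} "
                f"[{self.ci_diff[0]:.3f}, {self.ci_diff[1]:.3f}] "
                f"(n={self.n_diff}); permutation p={self.permutation_p:.4g}"
                f" (B={self.B})")


def _pair_table_matrices(pair_table: pd.DataFrame, rcol: str):
    ids = sorted(set(pair_table["m1"]) | set(pair_table["m2"]))
    idx = {m: k for k, m in enumerate(ids)}
    n = len(ids)
    R = np.full((n, n), np.nan)
    S = np.zeros((n, n), dtype=bool)
    for m1, m2, sr, r in zip(pair_table["m1"], pair_table["m2"],
                             pair_table["same_reaction"],
                             pair_table[rcol]):
        a, b = idx[m1], idx[m2]
        R[a, b] = R[b, a] = r
        S[a, b] = S[b, a] = sr
    return R, S


def _bootstrap_median_ci(values, B, rng, level=0.95):
    values = np.asarray(values, dtype=float)
    meds = np.empty(B)
    n = len(values)
    for b in range(B):
        meds[b] = np.median(values[rng.integers(0, n, n)])
    lo, hi = np.quantile(meds, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def coupling_test(pair_table: pd.DataFrame, species: str,
                  B: int = 1000, rng=None) -> CouplingResult:
    """Same- vs different-reaction correlation coupling for one species.

    Bootstrap (percentile, B resamples) CIs for each group's median r;
    the permutation null relabels metabolite identities on the network —
    rows/columns of the same-reaction mask are permuted against the fixed
    correlation matrix — and the one-sided p-value is the add-one
    fraction of permuted median differences at least as large as
    observed.
    """
    if B < 1:
        raise MetadivError("B must be >= 1")
    rng = np.random.default_rng(rng)
    rcol = f"r_{species}"
    if rcol not in pair_table.columns:
        raise MetadivError(f"unknown species {species!r}")
    same_r = pair_table.loc[pair_table["same_reaction"], rcol].to_numpy()
    diff_r = pair_table.loc[~pair_table["same_reaction"], rcol].to_numpy()
    if len(same_r) == 0 or len(diff_r) == 0:
        raise MetadivError("need both same- and different-reaction pairs")

    med_same = float(np.median(same_r))
    med_diff = float(np.median(diff_r))
    obs = med_same - med_diff
    ci_same = _bootstrap_median_ci(same_r, B, rng)
    ci_diff = _bootstrap_median_ci(diff_r, B, rng)

    R, S = _pair_table_matrices(pair_table, rcol)
    n = R.shape[0]
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(B):
        perm = rng.permutation(n)
        Sp = S[np.ix_(perm, perm)][iu]
        r_all = R[iu]
        stat = np.median(r_all[Sp]) - np.median(r_all[~Sp])
        if stat >= obs - 1e-15:
            count += 1
    return CouplingResult(
        species=species, median_same=med_same, median_diff=med_diff,
        ci_same=ci_same, ci_diff=ci_diff,
        permutation_p=(1 + count) / (B + 1),
        n_same=len(same_r), n_diff=len(diff_r), B=B)


# ---------------------------------------------------------------------------
# cross-species direction concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    pair: str
    mode: str
    prop_same_reaction: float
    prop_different: float
    n_same: int
    n_diff: int
    fisher_p: float
    table: list                 # 2x2 [[same_conc, same_disc], [diff...]]
    ci_same: tuple
    ci_diff: tuple

    def summary(self) -> str:
        return (f"direction concordance ({self.pair}, {self.mode}): "
                f"same-reaction {self.prop_same_reaction:.3f} "
                f"(n={self.n_same}) vs different "
                f"{self.prop_different:.3f} (n={self.n_diff}); "
                f"one-sided Fisher p={self.fisher_p:.4g}")


def _bootstrap_prop_ci(flags, B, rng, level=0.95):
    flags = np.asarray(flags, dtype=float)
    n = len(flags)
    if n == 0:
        return (float("nan"), float("nan"))
    props = np.array([flags[rng.integers(0, n, n)].mean()
                      for _ in range(B)])
    lo, hi = np.quantile(props, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def direction_concordance(pair_table: pd.DataFrame, dc_results,
                          pair: str = "HC", mode: str = "both_dc",
                          q_cutoff: float = 0.05, B: int = 1000,
                          rng=None) -> ConcordanceResult:
    """Same-direction change of metabolite pairs, same vs different reaction.

    Pairs are kept when both members (``both_dc``) or at least one member
    (``at_least_one_dc``) are differentially concentrated at
    ``q < q_cutoff`` for the species pair. A pair is concordant when both
    members' direction signs are equal and nonzero. The 2x2 table
    (same/different reaction x concordant/discordant) is tested with a
    one-sided Fisher exact test (same-reaction more concordant);
    bootstrap CIs accompany the proportions.
    """
    if mode not in ("both_dc", "at_least_one_dc"):
        raise MetadivError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(rng)
    sub = dc_results.frame[dc_results.frame["pair"] == pair]
    q = dict(zip(sub["metabolite_id"], sub["q"]))
    direction = dict(zip(sub["metabolite_id"], sub["direction"]))

    rows = []
    for m1, m2, sr in zip(pair_table["m1"], pair_table["m2"],
                          pair_table["same_reaction"]):
        if m1 not in q or m2 not in q:
            continue
        dc1, dc2 = q[m1] < q_cutoff, q[m2] < q_cutoff
        keep = (dc1 and dc2) if mode == "both_dc" else (dc1 or dc2)
        if not keep:
            continue
        d1, d2 = direction[m1], direction[m2]
        concordant = d1 != 0 and d2 != 0 and d1 == d2
        rows.append((sr, concordant))

    same = [c for sr, c in rows if sr]
    diff = [c for sr, c in rows if not sr]
    table = [[int(sum(same)), len(same) - int(sum(same))],
             [int(sum(diff)), len(diff) - int(sum(diff))]]
    if len(same) and len(diff):
        _, fisher_p = stats.fisher_exact(table, alternative="greater")
    else:
        fisher_p = float("nan")
    return ConcordanceResult(
        pair=pair, mode=mode,
        prop_same_reaction=(np.mean(same) if same else float("nan")),
        prop_different=(np.mean(diff) if diff else float("nan")),
        n_same=len(same), n_diff=len(diff), fisher_p=float(fisher_p),
        table=table,
        ci_same=_bootstrap_prop_ci(same, B, rng),
        ci_diff=_bootstrap_prop_ci(diff, B, rng))
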