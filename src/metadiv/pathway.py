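"""Pathway-level aggregation of per-metabolite evidence.

Per pathway and species pair, the raw (unadjusted) LRT p-values of the
measured member metabolites are combined with Fisher's method:
``X^2 = -2 sum ln p_i`` referred to chi-square with 2k degrees of
freedom. Raw p-values are used because Fisher's method assumes uniform
nulls; q-values would not be. Metabolites appearing in several pathways
contribute to each — no overlap correction is attempted, and correlation
among same-reaction members (which violates Fisher independence) is a
reported caveat, not corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MetadivError
from .io import ReactionNetwork, SPECIES_PAIRS

__all__ = ["fisher_combined", "score_pathways", "PathwayScores"]

_P_CLAMP = 1e-300


def fisher_combined(pvalues):
    """Fisher's combined probability: returns ``(X2, p_combined)``.

    Zero p-values are clamped to 1e-300 with a warning; an empty input
    is an error.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise MetadivError("fisher_combined needs at least one p-value")
    if np.any(p < 0) or np.any(p > 1):
        raise MetadivError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clamped to 1e-300", stacklevel=2)
        p = np.maximum(p, _P_CLAMP)
    stat, p_comb = stats.combine_pvalues(p, method="fisher")
    return float(stat), float(p_comb)


@dataclass
class PathwayScores:
    frame: pd.DataFrame        # one row per scored pathway
    skipped: list              # pathways below min_members

    def summary(self, top=10) -> str:
        lines = [f"Pathway scores ({len(self.frame)} scored, "
                 f"{len(self.skipped)} skipped)"]
        for _, row in self.frame.head(top).iterrows():
            flag = " *human-specific*" if row["human_specific_flag"] else ""
            lines.append(f"  {row['pathway_id']}: "
                         f"p_HC={row['p_HC']:.3g} p_HR={row['p_HR']:.3g} "
                         f"p_CR={row['p_CR']:.3g} "
                         f"(n={row['n_members_measured']}){flag}")
        return "\n".join(lines)


def score_pathways(dc_results, network: ReactionNetwork,
                   min_members: int = 2,
                   compound_of_metabolite=None) -> PathwayScores:
    """Combine member metabolites' raw p-values per pathway and pair.

    A pathway is flagged human-specific when its BH-adjusted combined p
    is below 0.05 for both human pairs and above 0.1 for the
    chimpanzee-rhesus pair — the metabolite-level rule mirrored at
    pathway level. Pathways are ranked by the smaller of the two
    human-pair combined p-values.
    """
    frame = dc_results.frame if hasattr(dc_results, "frame") else dc_results
    pmap = {}
    for pair in SPECIES_PAIRS:
        sub = frame[frame["pair"] == pair]
        pmap[pair] = dict(zip(sub["metabolite_id"], sub["p"]))
    measured = set(pmap["HC"])
    to_compound = compound_of_metabolite or {}

    rows, skipped = [], []
    for pw in sorted(network.pathways):
        member_compounds = network.pathway_members(pw)
        members = sorted(m for m in measured
                         if to_compound.get(m, m) in member_compounds)
        if len(members) < max(min_members, 1):
            skipped.append(pw)
            continue
        row = {"pathway_id": pw, "n_members_measured": len(members)}
        for pair in SPECIES_PAIRS:
            x2, pc = fisher_combined([pmap[pair][m] for m in members])
            row[f"X2_{pair}"] = x2
            row[f"p_{pair}"] = pc
        rows.append(row)

    if not rows:
        return PathwayScores(frame=pd.DataFrame(
            columns=["pathway_id", "n_members_measured",
                     "human_specific_flag"]), skipped=skipped)
    df = pd.DataFrame(rows)
    from .dc import bh_fdr
    for pair in SPECIES_PAIRS:
        df[f"q_{pair}"] = bh_fdr(df[f"p_{pair}"].to_numpy())
    df["human_specific_flag"] = ((df["q_HC"] < 0.05) & (df["q_HR"] < 0.05)
                                 & (df["q_CR"] > 0.1))
    df["rank_p"] = df[["p_HC", "p_HR"]].min(axis=1)
    df = df.sort_values("rank_p", kind="mergesort").reset_index(drop=True)
    return PathwayScores(frame=df, skipped=skipped)
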