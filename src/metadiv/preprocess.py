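"""Normalization and technical-artifact removal.

The quality-control workflow mirrors common practice for replicated
GC-MS intensity tables: quantile normalization across measurement
columns, outlier-replicate exclusion by inter-replicate correlation and
principal-component scores, and regression of principal components that
track batch (run-order) structure rather than species.

PCA convention: measurements are observations and metabolites are
variables; the matrix is row-centered (per metabolite), not scaled, and
components are ordered by explained variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError
from .io import AbundanceMatrix, SampleTable

logger = logging.getLogger(__name__)

__all__ = ["QCReport", "quantile_normalize", "detect_outliers",
           "regress_out_components", "regress_out_directions",
           "select_artifact_components", "preprocess_pipeline"]


@dataclass
class QCReport:
    excluded_measurement_ids: list
    replicate_correlation: pd.Series      # mean Pearson r with co-replicates
    pc_scores: pd.DataFrame               # measurements x components
    variance_explained: np.ndarray
    corr_flagged: list = field(default_factory=list)
    pc_flagged: list = field(default_factory=list)
    removed_components: list = field(default_factory=list)
    batch_assoc_p: dict = field(default_factory=dict)


def quantile_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Force every measurement column onto the same empirical distribution.

    The reference distribution is the across-column mean of order
    statistics; ties within a column receive the mean of the reference
    values at the tied ranks (via average ranks and interpolation).
    """
    X = matrix.values
    n_met, n_meas = X.shape
    if n_meas < 2:
        warnings.warn("single-column input: quantile normalization is a "
                      "no-op", stacklevel=2)
        return matrix
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    positions = np.arange(1, n_met + 1, dtype=float)
    for j in range(n_meas):
        ranks = stats.rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, reference)
    return AbundanceMatrix(pd.DataFrame(out, index=matrix.data.index,
                                        columns=matrix.data.columns))


def _pca_scores(X):
    """Measurement-space PCA of the row-centered matrix.

    Returns (scores: measurements x k, variance_explained, U, S, Vt) with
    ``X_centered = U @ diag(S) @ Vt`` and scores = (S * Vt.T).
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Vt.T * S
    total = (S ** 2).sum()
    varexp = (S ** 2) / total if total > 0 else np.zeros_like(S)
    return scores, varexp, U, S, Vt


def detect_outliers(matrix: AbundanceMatrix, samples: SampleTable,
                    corr_threshold: float = 0.8,
                    pc_mad_k: float = 6.0) -> QCReport:
    """Flag outlier replicates by inter-correlation and PC scores.

    A measurement is flagged if (a) its mean Pearson correlation with the
    other replicates of the same individual falls below ``corr_threshold``,
    or (b) its PC1 or PC2 score lies more than ``pc_mad_k``
    median-absolute-deviations from that component's median.

    Criterion (a) is applied iteratively per individual: the replicate
    with the lowest sub-threshold mean correlation is removed and the
    correlations recomputed among the remainder, so one corrupt replicate
    cannot drag its siblings below threshold. The PCA for criterion (b)
    is run on the species-centered matrix (per-metabolite species means
    removed), so that genuine between-species structure — typically the
    leading components — is not mistaken for a technical artifact.
    """
    ids = matrix.measurement_ids
    X = matrix.values
    df = samples.data.loc[ids]

    mean_corr = pd.Series(np.nan, index=pd.Index(ids, name="measurement_id"))
    corr_flagged = []
    col = {m: k for k, m in enumerate(ids)}
    for ind, grp in df.groupby("individual"):
        members = list(grp.index)
        if len(members) < 2:
            logger.info("individual %s has <2 replicates; correlation "
                        "criterion skipped", ind)
            continue
        active = list(members)
        while len(active) >= 2:
            sub = X[:, [col[m] for m in active]]
            R = np.corrcoef(sub, rowvar=False)
            mc = {m: float(np.mean(np.delete(R[a], a)))
                  for a, m in enumerate(active)}
            for m, v in mc.items():
                mean_corr[m] = v
            worst = min(mc, key=mc.get)
            if mc[worst] < corr_threshold:
                corr_flagged.append(worst)
                active.remove(worst)
            else:
                break

    # species-centered matrix for artifact-directed PCA
    Xc = X.copy()
    species = df["species"].to_numpy()
    for sp in np.unique(species):
        mask = species == sp
        Xc[:, mask] -= Xc[:, mask].mean(axis=1, keepdims=True)
    scores, varexp, *_ = _pca_scores(Xc)
    k_use = min(2, scores.shape[1])
    pc_flagged = []
    for k in range(k_use):
        s = scores[:, k]
        med = np.median(s)
        mad = np.median(np.abs(s - med))
        if mad == 0:
            continue
        for a, m in enumerate(ids):
            if abs(s[a] - med) > pc_mad_k * mad and m not in pc_flagged:
                pc_flagged.append(m)

    excluded = sorted(set(corr_flagged) | set(pc_flagged))
    return QCReport(
        excluded_measurement_ids=excluded,
        replicate_correlation=mean_corr,
        pc_scores=pd.DataFrame(scores, index=ids,
                               columns=[f"PC{k + 1}" for k in
                                        range(scores.shape[1])]),
        variance_explained=varexp,
        corr_flagged=sorted(corr_flagged),
        pc_flagged=sorted(pc_flagged),
    )


def regress_out_components(matrix: AbundanceMatrix,
                           component_indices) -> AbundanceMatrix:
    """Reconstruct the matrix without the named principal components.

    Each metabolite's row-centered profile is projected off the selected
    measurement-space component score directions; row means are restored.
    Indices are 0-based and must be below the rank of the centered matrix.
    """
    component_indices = sorted(set(int(k) for k in component_indices))
    if not component_indices:
        return matrix
    X = matrix.values
    row_means = X.mean(axis=1, keepdims=True)
    Xc = X - row_means
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if any(k >= rank for k in component_indices):
        raise DegenerateDataError(
            f"component index out of range for rank-{rank} matrix")
    S = S.copy()
    S[component_indices] = 0.0
    out = (U * S) @ Vt + row_means
    return AbundanceMatrix(pd.DataFrame(out, index=matrix.data.index,
                                        columns=matrix.data.columns))


def _anova_p(scores_1d, labels):
    groups = [scores_1d[labels == g] for g in np.unique(labels)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        return 1.0
    with np.errstate(invalid="ignore"):
        stat, p = stats.f_oneway(*groups)
    return 1.0 if np.isnan(p) else float(p)


def _species_centered(X, species):
    Xc = X.copy()
    for sp in np.unique(species):
        mask = species == sp
        Xc[:, mask] -= Xc[:, mask].mean(axis=1, keepdims=True)
    return Xc


def select_artifact_components(matrix: AbundanceMatrix,
                               samples: SampleTable,
                               alpha: float = 0.05,
                               n_components: int = 5,
                               center_species: bool = True,
                               return_directions: bool = False):
    """Components (among the top ``n_components``) that track batch.

    A component is selected when its scores associate with batch by a
    one-way ANOVA F-test (p < alpha) while showing no species association
    (p >= alpha) — the signature of a non-biological artifact.

    By default the PCA is run on the species-centered matrix: when batch
    and species variance are of similar size, PCA of the raw matrix
    rotates the two directions into mixed components that fail both
    filters; removing species means first keeps the biological axis out
    of the candidate components by construction. Returns
    (indices, {index: (batch_p, species_p)}) and, when
    ``return_directions`` is set, the matching measurement-space unit
    vectors.
    """
    ids = matrix.measurement_ids
    df = samples.data.loc[ids]
    if "batch" not in df.columns or df["batch"].isna().all():
        warnings.warn("no batch labels; no artifact components selected",
                      stacklevel=2)
        return ([], {}, np.empty((0, len(ids)))) if return_directions \
            else ([], {})
    species = df["species"].to_numpy()
    X = matrix.values
    Xa = _species_centered(X, species) if center_species else X
    scores, varexp, U, S, Vt = _pca_scores(Xa)
    batch = df["batch"].to_numpy()
    chosen, pvals = [], {}
    for k in range(min(n_components, scores.shape[1])):
        p_batch = _anova_p(scores[:, k], batch)
        p_species = _anova_p(scores[:, k], species)
        pvals[k] = (p_batch, p_species)
        if p_batch < alpha and p_species >= alpha:
            chosen.append(k)
    if return_directions:
        return chosen, pvals, Vt[chosen]
    return chosen, pvals


def regress_out_directions(matrix: AbundanceMatrix,
                           directions) -> AbundanceMatrix:
    """Project every metabolite's centered profile off the given
    measurement-space directions (rows of ``directions``, orthonormalized
    internally); row means restored."""
    W = np.atleast_2d(np.asarray(directions, dtype=float))
    if W.shape[0] == 0:
        return matrix
    # orthogonalize against the constant vector so row means survive
    W = W - W.mean(axis=1, keepdims=True)
    Q, _ = np.linalg.qr(W.T)
    X = matrix.values
    row_means = X.mean(axis=1, keepdims=True)
    Xc = X - row_means
    out = Xc - (Xc @ Q) @ Q.T + row_means
    return AbundanceMatrix(pd.DataFrame(out, index=matrix.data.index,
                                        columns=matrix.data.columns))


def preprocess_pipeline(matrix: AbundanceMatrix, samples: SampleTable,
                        log2_input: bool = False,
                        corr_threshold: float = 0.8,
                        pc_mad_k: float = 6.0,
                        alpha: float = 0.05):
    """normalize -> exclude outliers -> re-normalize -> regress artifacts.

    Returns ``(clean AbundanceMatrix, matching SampleTable, QCReport)``.
    Quantile normalization is re-run after exclusion so the reference
    distribution is not contaminated by the outliers.
    """
    if log2_input:
        matrix = AbundanceMatrix(np.log2(matrix.data))
    norm = quantile_normalize(matrix)
    qc = detect_outliers(norm, samples, corr_threshold=corr_threshold,
                         pc_mad_k=pc_mad_k)
    kept = matrix.drop_measurements(qc.excluded_measurement_ids)
    norm2 = quantile_normalize(kept)
    sub_samples = samples.subset(norm2.measurement_ids)
    comps, pvals, directions = select_artifact_components(
        norm2, sub_samples, alpha=alpha, return_directions=True)
    qc.removed_components = comps
    qc.batch_assoc_p = {k: v[0] for k, v in pvals.items()}
    if comps:
        norm2 = regress_out_directions(norm2, directions)
    return norm2, sub_samples, qc
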