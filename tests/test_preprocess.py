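import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metadiv as md
from metadiv.io import AbundanceMatrix, SampleTable
from metadiv.exceptions import DegenerateDataError
from metadiv.preprocess import (detect_outliers, preprocess_pipeline,
                                quantile_normalize,
                                regress_out_components,
                                regress_out_directions,
                                select_artifact_components)


def _matrix(values, met=None, meas=None):
    values = np.asarray(values, dtype=float)
    met = met or [f"m{i}" for i in range(values.shape[0])]
    meas = meas or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceMatrix(pd.DataFrame(values, index=met, columns=meas))


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        out = quantile_normalize(_matrix([[1, 2], [3, 4]]))
        np.testing.assert_allclose(out.values,
                                   [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_fixed_point(self):
        m = _matrix([[1, 1, 1], [5, 5, 5], [2, 2, 2]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_tie_gets_mean_of_reference_ranks(self):
        # column 0 has a tie at ranks 1-2; reference is the row-sorted
        # across-column mean: [1.5, 2.5, 5.5]
        out = quantile_normalize(_matrix([[2, 1], [2, 3], [5, 6]]))
        np.testing.assert_allclose(out.values[:, 0], [2.0, 2.0, 5.5])
        np.testing.assert_allclose(out.values[:, 1], [1.5, 2.5, 5.5])

    def test_columns_share_empirical_distribution(self, default_sim):
        out = quantile_normalize(default_sim.abundance)
        X = out.values
        ref = np.sort(X[:, 0])
        for j in range(1, X.shape[1]):
            assert stats.ks_2samp(ref, X[:, j]).statistic < 1e-12

    def test_single_column_warns_and_returns_input(self):
        m = _matrix([[1.0], [2.0]])
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)


class TestDetectOutliers:
    def test_low_correlation_replicate_flagged(self):
        # 3 replicates per individual so the corrupt one is identifiable
        rng = np.random.default_rng(0)
        rows = []
        for sp, tag in zip(md.SPECIES, "HCR"):
            for i in range(2):
                for r in (1, 2, 3):
                    rows.append({"measurement_id": f"{tag}{i}_r{r}",
                                 "species": sp, "individual": f"{tag}{i}",
                                 "replicate": r, "batch": f"b{r}",
                                 "sex": "unknown"})
        meta = pd.DataFrame(rows).set_index("measurement_id")
        profile = rng.normal(10, 2, 50)
        X = np.column_stack([profile + rng.normal(0, 0.05, 50)
                             for _ in range(len(meta))])
        X[:, 4] = rng.normal(10, 2, 50)  # decorrelate H1_r2
        m = AbundanceMatrix(pd.DataFrame(
            X, index=[f"m{i}" for i in range(50)],
            columns=list(meta.index)))
        qc = detect_outliers(m, SampleTable(meta), corr_threshold=0.8)
        assert qc.corr_flagged == [meta.index[4]]

    def test_perfect_replicates_nothing_flagged(self, balanced_samples):
        rng = np.random.default_rng(1)
        base = rng.normal(10, 2, (50, 9))
        X = np.repeat(base, 2, axis=1)  # replicates identical
        m = AbundanceMatrix(pd.DataFrame(
            X, index=[f"m{i}" for i in range(50)],
            columns=list(balanced_samples.index)))
        qc = detect_outliers(m, SampleTable(balanced_samples))
        assert qc.excluded_measurement_ids == []

    def test_planted_outliers_recovered_exactly(self, default_sim):
        qn = quantile_normalize(default_sim.abundance)
        qc = detect_outliers(qn, default_sim.samples)
        assert set(qc.excluded_measurement_ids) == \
            set(default_sim.truth.outlier_measurements)

    def test_variance_explained_is_sorted_and_sums_to_one(self,
                                                          default_sim):
        qc = detect_outliers(quantile_normalize(default_sim.abundance),
                             default_sim.samples)
        v = qc.variance_explained
        assert np.all(np.diff(v) <= 1e-12)
        assert v.sum() == pytest.approx(1.0)


class TestRegressOutComponents:
    def test_rank_one_matrix_reduces_to_row_means(self):
        u = np.array([1.0, 2.0, 3.0])
        w = np.array([1.0, -1.0, 0.5, 2.0])
        m = _matrix(np.outer(u, w))
        out = regress_out_components(m, [0])
        expected = np.tile(m.values.mean(axis=1, keepdims=True), (1, 4))
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    def test_remove_nothing_is_identity(self, default_sim):
        out = regress_out_components(default_sim.abundance, [])
        np.testing.assert_allclose(out.values,
                                   default_sim.abundance.values)

    def test_idempotent_for_fixed_components(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(0, 1, (30, 12)))
        once = regress_out_components(m, [0, 1])
        # the removed subspace carries no variance now; removing the new
        # leading components again changes nothing about the removed ones
        X1 = once.values - once.values.mean(axis=1, keepdims=True)
        _, S, _ = np.linalg.svd(m.values
                                - m.values.mean(axis=1, keepdims=True),
                                full_matrices=False)
        _, S1, _ = np.linalg.svd(X1, full_matrices=False)
        np.testing.assert_allclose(S1[:len(S) - 3], S[2:-1], rtol=1e-8)

    def test_requesting_rank_or_more_errors(self):
        m = _matrix(np.outer([1.0, 2.0], [1.0, 2.0, 3.0]))
        with pytest.raises(DegenerateDataError):
            regress_out_components(m, [0, 1])


class TestSelectArtifactComponents:
    def test_null_scores_rarely_selected(self):
        hits = 0
        for seed in range(10):
            d = md.simulate(md.null_config(n_metabolites=60, seed=seed))
            comps, _ = select_artifact_components(
                quantile_normalize(d.abundance), d.samples)
            hits += bool(comps)
        assert hits <= 1  # >=90% of null seeds select nothing

    def test_planted_batch_component_selected(self, default_sim):
        comps, pvals = select_artifact_components(
            quantile_normalize(default_sim.abundance),
            default_sim.samples)
        assert len(comps) >= 1
        for k in comps:
            p_batch, p_species = pvals[k]
            assert p_batch < 0.05 and p_species >= 0.05

    def test_species_associated_component_not_selected(self,
                                                       default_sim):
        # raw (non-species-centered) PCA: the top species component must
        # never pass the artifact filter
        comps, pvals = select_artifact_components(
            quantile_normalize(default_sim.abundance),
            default_sim.samples, center_species=False)
        for k, (p_batch, p_species) in pvals.items():
            if p_species < 0.05:
                assert k not in comps

    def test_no_batch_labels_selects_nothing(self, default_sim):
        df = default_sim.samples.data.copy()
        df["batch"] = np.nan
        with pytest.warns(UserWarning, match="batch"):
            comps, _ = select_artifact_components(
                default_sim.abundance, SampleTable(df))
        assert comps == []


class TestPipelineOrder:
    def test_batch_f_drops_after_artifact_removal(self, default_sim):
        clean, samples, qc = preprocess_pipeline(default_sim.abundance,
                                                 default_sim.samples)
        assert qc.removed_components
        kept = default_sim.abundance.drop_measurements(
            qc.excluded_measurement_ids)
        before = quantile_normalize(kept)
        batch = samples.data.loc[clean.measurement_ids,
                                 "batch"].to_numpy()

        def batch_f(X):
            return np.array([stats.f_oneway(
                *[row[batch == b] for b in np.unique(batch)]).statistic
                for row in X])

        frac = np.mean(batch_f(clean.values) < batch_f(before.values))
        assert frac >= 0.95

    def test_dimensions_only_lose_dropped_measurements(self,
                                                       default_sim):
        clean, samples, qc = preprocess_pipeline(default_sim.abundance,
                                                 default_sim.samples)
        n_dropped = len(qc.excluded_measurement_ids)
        assert clean.shape == (default_sim.abundance.shape[0],
                               default_sim.abundance.shape[1] - n_dropped)
        assert clean.measurement_ids == samples.measurement_ids

    def test_regress_out_directions_preserves_row_means(self,
                                                        default_sim):
        rng = np.random.default_rng(0)
        w = rng.normal(0, 1, default_sim.abundance.shape[1])
        w /= np.linalg.norm(w)
        out = regress_out_directions(default_sim.abundance, w)
        np.testing.assert_allclose(
            out.values.mean(axis=1),
            default_sim.abundance.values.mean(axis=1), atol=1e-9)
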