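import logging

import numpy as np
import pandas as pd
import pytest

from pdl1time.icis_phenotyping import (
    DENSITY_FEATURES,
    FeatureMatrix,
    PDL1_FEATURES,
    Phenotype,
    aggregate_densities,
    compute_icis,
    label_phenotypes,
    transform_features,
    wpgma_cluster,
)
from pdl1time.io_model import MarkerDensityRecord
from pdl1time.pdl1_scoring import ConsensusScores


def _rec(pid, core, density, marker="CD8", region="invasion_front", qc=True):
    return MarkerDensityRecord(patient_id=pid, core_id=core, region=region,
                               marker=marker, density=density, qc_pass=qc)


class TestAggregateDensities:
    @pytest.mark.parametrize("densities,expected", [
        ([100.0, 300.0], 200.0),
        ([150.0], 150.0),
        ([0.0, 0.0, 10.0, 1000.0], 5.0),
    ])
    def test_median_over_cores(self, densities, expected):
        records = [
            _rec("P1", f"c{i}", d) for i, d in enumerate(densities)
        ]
        table = aggregate_densities(records)
        assert table.loc["P1", "CD8_invasion_front"] == expected

    def test_qc_failing_cores_ignored(self):
        records = [_rec("P1", "c1", 100.0), _rec("P1", "c2", 900.0, qc=False)]
        assert aggregate_densities(records).loc["P1", "CD8_invasion_front"] == 100.0


class TestTransformFeatures:
    def test_two_point_population_zscore(self):
        # densities {1, 3} -> log2 {1, 2} -> Z {-1, +1}
        table = pd.DataFrame({"CD8_invasion_front": [1.0, 3.0]},
                             index=["P1", "P2"])
        m = transform_features(table)
        np.testing.assert_allclose(
            m.to_frame()["CD8_invasion_front"].to_numpy(), [-1.0, 1.0]
        )

    def test_constant_feature_becomes_zero_column(self):
        table = pd.DataFrame({"CD8_invasion_front": [5.0, 5.0, 5.0]},
                             index=list("abc"))
        m = transform_features(table)
        assert (m.values == 0).all()

    def test_zero_density_maps_to_zero_before_z(self):
        # log2(0 + 1) = 0; with {0, 1} the log2 values are {0, 1}
        table = pd.DataFrame({"CD8_invasion_front": [0.0, 1.0]},
                             index=["P1", "P2"])
        m = transform_features(table)
        np.testing.assert_allclose(sorted(m.values.ravel()), [-1.0, 1.0])

    def test_columns_standardized_to_machine_precision(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            rng.uniform(0, 500, size=(30, len(DENSITY_FEATURES))),
            index=[f"P{i}" for i in range(30)], columns=DENSITY_FEATURES,
        )
        consensus = [
            ConsensusScores(f"P{i}", *rng.uniform(0, 100, size=4))
            for i in range(30)
        ]
        m = transform_features(table, consensus)
        assert np.abs(m.values.mean(axis=0)).max() < 1e-9
        assert np.abs(m.values.std(axis=0) - 1).max() < 1e-9

    def test_missing_cells_imputed_with_cohort_median(self):
        table = pd.DataFrame(
            {"CD8_invasion_front": [1.0, 3.0, np.nan]}, index=list("abc")
        )
        m = transform_features(table)
        # imputed log2 value equals the column median -> Z = 0 for patient c
        assert m.to_frame().loc["c", "CD8_invasion_front"] == pytest.approx(0.0)


class TestComputeIcis:
    def test_two_patient_single_feature(self):
        m = FeatureMatrix(["P1", "P2"], ["CD8_invasion_front"],
                          np.array([[-1.0], [1.0]]))
        icis = compute_icis(m)
        assert icis["P1"] == -1.0 and icis["P2"] == 1.0

    def test_uniform_plus_one_sd_gives_icis_one(self):
        m = FeatureMatrix(["P1"], DENSITY_FEATURES,
                          np.ones((1, len(DENSITY_FEATURES))))
        assert compute_icis(m)["P1"] == pytest.approx(1.0)

    def test_invariant_to_feature_ordering(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(5, len(DENSITY_FEATURES)))
        m = FeatureMatrix([f"P{i}" for i in range(5)],
                          list(DENSITY_FEATURES), values)
        perm = rng.permutation(len(DENSITY_FEATURES))
        m_shuffled = FeatureMatrix(
            m.patient_ids, [DENSITY_FEATURES[j] for j in perm], values[:, perm]
        )
        pd.testing.assert_series_equal(compute_icis(m), compute_icis(m_shuffled))

    def test_pdl1_features_excluded_from_icis(self):
        names = ["CD8_invasion_front"] + PDL1_FEATURES
        values = np.array([[1.0, 9.0, 9.0, 9.0, 9.0]])
        m = FeatureMatrix(["P1"], names, values)
        assert compute_icis(m)["P1"] == 1.0


def _matrix_1d(points):
    return FeatureMatrix([f"P{i}" for i in range(len(points))], ["f"],
                         np.asarray(points, dtype=float).reshape(-1, 1))


class TestWpgmaCluster:
    def test_hand_computed_one_dimensional_example(self):
        # merge (0, 1) at d=1; WPGMA distance of {0,1} to 10 = (10+9)/2 = 9.5
        clusters = wpgma_cluster(_matrix_1d([0.0, 1.0, 10.0]), k=2)
        assert clusters[0] == clusters[1] != clusters[2]

    def test_two_tight_pairs_separate(self):
        m = FeatureMatrix(list("abcd"), ["x", "y"], np.array(
            [[0.0, 0.0], [0.1, 0.0], [50.0, 50.0], [50.1, 50.0]]
        ))
        clusters = wpgma_cluster(m, k=2)
        assert clusters[0] == clusters[1] != clusters[2] == clusters[3]

    def test_duplicate_rows_always_co_cluster(self):
        m = FeatureMatrix(list("abcde"), ["x"], np.array(
            [[3.0], [3.0], [0.0], [9.0], [20.0]]
        ))
        clusters = wpgma_cluster(m, k=3)
        assert clusters[0] == clusters[1]

    def test_too_few_patients_raises(self):
        with pytest.raises(ValueError):
            wpgma_cluster(_matrix_1d([0.0, 1.0]), k=4)

    def test_matches_bruteforce_agglomerative_oracle(self):
        """scipy WPGMA equals an independent exhaustive-merge oracle."""
        rng = np.random.default_rng(12345)
        for _ in range(50):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(2, 4))
            x = rng.normal(size=(n, 3))
            m = FeatureMatrix([f"P{i}" for i in range(n)],
                              ["a", "b", "c"], x)
            ours = _partition(wpgma_cluster(m, k=k))
            assert ours == _wpgma_bruteforce(x, k)


def _partition(labels):
    groups = {}
    for i, c in enumerate(labels):
        groups.setdefault(c, set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


def _wpgma_bruteforce(x, k):
    """Exhaustive pairwise WPGMA merging, re-implemented independently."""
    clusters = [{i} for i in range(len(x))]
    dist = {}
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            dist[(i, j)] = float(np.linalg.norm(x[i] - x[j]))

    def d(a, b):
        return dist[(min(a, b), max(a, b))]

    active = list(range(len(x)))
    next_id = len(x)
    while len(active) > k:
        best = min(
            ((d(a, b), a, b) for ai, a in enumerate(active)
             for b in active[ai + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters.append(merged)
        for c in active:
            if c in (a, b):
                continue
            dist[(min(c, next_id), max(c, next_id))] = 0.5 * (d(a, c) + d(b, c))
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return frozenset(frozenset(clusters[c]) for c in active)


def _labeled_matrix():
    """Four well-separated clusters with the canonical phenotype signature."""
    rows, pids, clusters = [], [], []
    # columns: one density feature, tc_area, ic_area (+ cps to satisfy names)
    specs = [
        (1, dict(dens=0.5, tc=2.0, ic=-0.5)),    # Evasion: TC high
        (2, dict(dens=1.5, tc=-0.5, ic=2.0)),    # Inflamed High: IC high
        (3, dict(dens=0.8, tc=-0.6, ic=-0.5)),   # Inflamed Low: higher ICIS
        (4, dict(dens=-1.5, tc=-0.6, ic=-0.5)),  # Uninflamed
    ]
    for cid, s in specs:
        for i in range(3):
            pids.append(f"P{cid}{i}")
            clusters.append(cid)
            rows.append([s["dens"], 0.0, s["tc"], 0.0, s["ic"]])
    names = ["CD8_invasion_front", "cps_consensus", "tc_area_consensus",
             "ventana_ic_consensus", "ic_area_consensus"]
    m = FeatureMatrix(pids, names, np.array(rows))
    icis = {p: float(v) for p, v in zip(pids, np.array(rows)[:, 0])}
    return clusters, m, icis


class TestLabelPhenotypes:
    def test_canonical_signature_recovered(self):
        clusters, m, icis = _labeled_matrix()
        labels = {a.cluster_id: a.phenotype
                  for a in label_phenotypes(clusters, m, icis)}
        assert labels == {
            1: Phenotype.EVASION,
            2: Phenotype.INFLAMED_HIGH,
            3: Phenotype.INFLAMED_LOW,
            4: Phenotype.UNINFLAMED,
        }

    def test_tc_rule_applied_before_ic_rule(self):
        # cluster 1 maximizes both TC and IC -> Evasion by rule order
        clusters, m, icis = _labeled_matrix()
        values = m.values.copy()
        values[:3, 4] = 3.0  # boost cluster 1's ic_area above cluster 2's
        m2 = FeatureMatrix(m.patient_ids, m.feature_names, values)
        labels = {a.cluster_id: a.phenotype
                  for a in label_phenotypes(clusters, m2, icis)}
        assert labels[1] is Phenotype.EVASION
        assert labels[2] is Phenotype.INFLAMED_HIGH

    def test_all_zero_matrix_breaks_ties_by_cluster_id(self, caplog):
        clusters, m, icis = _labeled_matrix()
        zero = FeatureMatrix(m.patient_ids, m.feature_names,
                             np.zeros_like(m.values))
        icis0 = {p: 0.0 for p in m.patient_ids}
        with caplog.at_level(logging.WARNING):
            labels = {a.cluster_id: a.phenotype
                      for a in label_phenotypes(clusters, zero, icis0)}
        assert labels == {
            1: Phenotype.EVASION,
            2: Phenotype.INFLAMED_HIGH,
            3: Phenotype.INFLAMED_LOW,
            4: Phenotype.UNINFLAMED,
        }
        assert any("tie" in r.message for r in caplog.records)

    def test_wrong_cluster_count_rejected(self):
        clusters, m, icis = _labeled_matrix()
        with pytest.raises(ValueError, match="4 clusters"):
            label_phenotypes([1] * len(m.patient_ids), m, icis)
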