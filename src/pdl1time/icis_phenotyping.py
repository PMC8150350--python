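"""Immune-phenotype clustering and the immune cell infiltration score (ICIS).

Per-patient features are the per-region median densities of nine immune
markers (9 markers x 2 regions = 18 features), log2(x+1)-transformed and
Z-scored, plus the four PD-L1 consensus scores Z-scored on their native
percent scale. Patients are clustered by agglomerative WPGMA (weighted
pair-group average) linkage on Euclidean distances and the tree is cut into
k = 4 flat clusters, which are labeled with the four tumor immune phenotypes:

* **Evasion** — constitutive PD-L1 on tumor cells, low IC expression,
  intermediate infiltration;
* **Inflamed: High** — high PD-L1 on immune cells, high infiltration;
* **Inflamed: Low** — moderate infiltration, low PD-L1;
* **Uninflamed** — mostly absent inflammation and PD-L1.

ICIS is the mean of a patient's 18 Z-scored density features: a scale-free
summary of overall immune infiltration.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .io_model import Cohort, Marker, MarkerDensityRecord, Region
from .pdl1_scoring import ConsensusScores, consensus_table

logger = logging.getLogger(__name__)

__all__ = [
    "Phenotype",
    "FeatureMatrix",
    "PhenotypeAssignment",
    "PDL1_FEATURES",
    "density_feature_name",
    "DENSITY_FEATURES",
    "aggregate_densities",
    "transform_features",
    "compute_icis",
    "wpgma_cluster",
    "label_phenotypes",
    "assign_phenotypes",
]


class Phenotype(str, enum.Enum):
    """The four spatially organized tumor immune phenotypes."""

    EVASION = "Evasion"
    INFLAMED_HIGH = "Inflamed: High"
    INFLAMED_LOW = "Inflamed: Low"
    UNINFLAMED = "Uninflamed"


def density_feature_name(marker: Marker, region: Region) -> str:
    return f"{marker.value}_{region.value}"


#: the 18 density feature names, marker-major, invasion front before center
DENSITY_FEATURES = [
    density_feature_name(m, r) for m in Marker for r in Region
]
#: the four PD-L1 consensus features appended to the density features
PDL1_FEATURES = [
    "cps_consensus",
    "tc_area_consensus",
    "ventana_ic_consensus",
    "ic_area_consensus",
]


@dataclass
class FeatureMatrix:
    """Patients x features matrix after log2/Z transform.

    ``values[i, j]`` is patient ``patient_ids[i]``'s Z-score on feature
    ``feature_names[j]``. Non-constant columns have mean 0 and population
    SD 1; zero-variance columns are all zero.
    """

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids/features")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.patient_ids, columns=self.feature_names
        )

    def density_columns(self) -> list[str]:
        return [f for f in self.feature_names if f in set(DENSITY_FEATURES)]


@dataclass(frozen=True)
class PhenotypeAssignment:
    patient_id: str
    cluster_id: int
    phenotype: Phenotype
    icis: float


def aggregate_densities(
    records: Iterable[MarkerDensityRecord],
) -> pd.DataFrame:
    """Median density across a patient's QC-passing cores, per marker/region.

    Returns a patients x 18 frame (columns ordered as ``DENSITY_FEATURES``);
    cells with no contributing core are NaN and resolved later by the
    imputation policy in :func:`transform_features`.
    """
    rows = [
        {
            "patient_id": r.patient_id,
            "feature": density_feature_name(r.marker, r.region),
            "density": r.density,
        }
        for r in records
        if r.qc_pass
    ]
    if not rows:
        return pd.DataFrame(columns=DENSITY_FEATURES)
    df = pd.DataFrame(rows)
    table = df.pivot_table(
        index="patient_id", columns="feature", values="density", aggfunc="median"
    )
    # preserve first-appearance patient order and canonical feature order
    order = list(dict.fromkeys(df["patient_id"]))
    return table.reindex(index=order, columns=DENSITY_FEATURES)


def _zscore(columns: np.ndarray) -> np.ndarray:
    """Column-wise Z-score with population SD; zero-variance columns -> 0."""
    mean = columns.mean(axis=0)
    sd = columns.std(axis=0)  # population SD (divisor n)
    out = np.zeros_like(columns)
    nz = sd > 0
    out[:, nz] = (columns[:, nz] - mean[nz]) / sd[nz]
    return out


def transform_features(
    density_table: pd.DataFrame,
    pdl1_consensus: Optional[Sequence[ConsensusScores]] = None,
) -> FeatureMatrix:
    """Build the clustering feature matrix.

    Density features are mapped ``x -> log2(x + 1)`` (pseudocount keeps the
    common zero densities at 0) and Z-scored per feature with population SD.
    PD-L1 consensus features are Z-scored on their native percent scale.
    Missing cells are imputed with the feature's cohort median before the
    Z-transform; zero-variance features become all-zero columns.
    """
    patient_ids = list(density_table.index)
    log2 = np.log2(density_table.to_numpy(dtype=float) + 1.0)
    log2 = _impute_column_median(log2)
    blocks = [_zscore(log2)]
    names = list(density_table.columns)

    if pdl1_consensus is not None:
        by_pid = {c.patient_id: c for c in pdl1_consensus}
        unmatched = [p for p in patient_ids if p not in by_pid]
        if unmatched:
            logger.warning(
                "transform_features: %d patient(s) lack consensus scores; "
                "imputing with cohort medians", len(unmatched)
            )
        raw = np.full((len(patient_ids), len(PDL1_FEATURES)), np.nan)
        for i, pid in enumerate(patient_ids):
            c = by_pid.get(pid)
            if c is None:
                continue
            for j, f in enumerate(PDL1_FEATURES):
                v = getattr(c, f)
                raw[i, j] = np.nan if v is None else v
        raw = _impute_column_median(raw)
        blocks.append(_zscore(raw))
        names += PDL1_FEATURES

    return FeatureMatrix(patient_ids, names, np.hstack(blocks))


def _impute_column_median(values: np.ndarray) -> np.ndarray:
    values = values.copy()
    for j in range(values.shape[1]):
        col = values[:, j]
        mask = np.isnan(col)
        if mask.any():
            med = np.nanmedian(col) if (~mask).any() else 0.0
            col[mask] = med
    return values


def compute_icis(matrix: FeatureMatrix) -> pd.Series:
    """ICIS per patient: mean of the 18 Z-scored density features.

    Invariant to feature ordering; by construction the cohort mean is ~0
    when no cells were imputed.
    """
    cols = matrix.density_columns()
    if not cols:
        raise ValueError("matrix contains no density features")
    frame = matrix.to_frame()[cols]
    return frame.mean(axis=1).rename("icis")


def wpgma_cluster(matrix: FeatureMatrix, k: int = 4) -> np.ndarray:
    """WPGMA (weighted average-link) clustering on Euclidean distances.

    Returns integer cluster ids ``1..k`` aligned with ``matrix.patient_ids``
    and relabeled in order of first appearance, so the output is
    deterministic given the input row order.
    """
    n = len(matrix.patient_ids)
    if n < k:
        raise ValueError(f"cannot form {k} clusters from {n} patients")
    if np.isnan(matrix.values).any():
        raise ValueError("feature matrix contains missing values")
    z = linkage(pdist(matrix.values, metric="euclidean"), method="weighted")
    raw = fcluster(z, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[i] = relabel[c]
    return out


def label_phenotypes(
    assignments: Sequence[int],
    matrix: FeatureMatrix,
    icis: Mapping[str, float],
) -> list[PhenotypeAssignment]:
    """Map four clusters onto the named immune phenotypes.

    Deterministic rule, applied in order: the cluster with the highest mean
    Z of ``tc_area_consensus`` is *Evasion*; among the rest, the highest mean
    Z of ``ic_area_consensus`` is *Inflamed: High*; of the last two, the one
    with higher mean ICIS is *Inflamed: Low*, the other *Uninflamed*. Exact
    ties are broken toward the lower cluster id with a logged warning.
    """
    assignments = np.asarray(assignments, dtype=int)
    cluster_ids = sorted(set(assignments.tolist()))
    if len(cluster_ids) != 4:
        raise ValueError(
            f"phenotype labeling requires exactly 4 clusters, got {len(cluster_ids)}"
        )
    frame = matrix.to_frame()
    for needed in ("tc_area_consensus", "ic_area_consensus"):
        if needed not in frame.columns:
            raise ValueError(f"feature matrix lacks {needed}")
    icis_series = pd.Series({p: icis[p] for p in matrix.patient_ids})

    def cluster_mean(values: pd.Series) -> dict[int, float]:
        return {
            c: float(values[assignments == c].mean()) for c in cluster_ids
        }

    def argmax(stats: dict[int, float], candidates: list[int], what: str) -> int:
        best = max(stats[c] for c in candidates)
        winners = [c for c in candidates if stats[c] == best]
        if len(winners) > 1:
            logger.warning(
                "label_phenotypes: tie on %s between clusters %s; "
                "choosing lowest cluster id", what, winners
            )
        return winners[0]

    tc_mean = cluster_mean(pd.Series(frame["tc_area_consensus"].to_numpy()))
    remaining = list(cluster_ids)
    evasion = argmax(tc_mean, remaining, "mean TCarea Z")
    remaining.remove(evasion)
    ic_mean = cluster_mean(pd.Series(frame["ic_area_consensus"].to_numpy()))
    inflamed_high = argmax(ic_mean, remaining, "mean ICarea Z")
    remaining.remove(inflamed_high)
    icis_mean = cluster_mean(pd.Series(icis_series.to_numpy()))
    inflamed_low = argmax(icis_mean, remaining, "mean ICIS")
    remaining.remove(inflamed_low)
    (uninflamed,) = remaining

    label_of = {
        evasion: Phenotype.EVASION,
        inflamed_high: Phenotype.INFLAMED_HIGH,
        inflamed_low: Phenotype.INFLAMED_LOW,
        uninflamed: Phenotype.UNINFLAMED,
    }
    return [
        PhenotypeAssignment(
            patient_id=pid,
            cluster_id=int(c),
            phenotype=label_of[int(c)],
            icis=float(icis_series[pid]),
        )
        for pid, c in zip(matrix.patient_ids, assignments)
    ]


def assign_phenotypes(cohort: Cohort, k: int = 4) -> tuple[
    list[PhenotypeAssignment], FeatureMatrix, pd.Series
]:
    """End-to-end phenotyping of a QC-filtered cohort.

    Aggregates densities, builds consensus scores, transforms features,
    clusters with WPGMA and labels the clusters. Returns the assignments,
    the feature matrix and the ICIS series.
    """
    table = aggregate_densities(cohort.density_records)
    consensus = consensus_table(cohort)
    matrix = transform_features(table, consensus)
    icis = compute_icis(matrix)
    clusters = wpgma_cluster(matrix, k=k)
    labeled = label_phenotypes(clusters, matrix, icis)
    return labeled, matrix, icis
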