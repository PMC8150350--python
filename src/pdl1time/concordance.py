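"""Inter-algorithm agreement, Venn partitioning, phenotype coverage, rescue.

The three dichotomized PD-L1 algorithms (CPS10, Ventana IC5%,
TCarea25%/ICarea25%) select overlapping but distinct patient subsets. This
module quantifies that heterogeneity: pairwise overall percentage agreement
(OPA), the exact 8-region Venn partition of the three statuses, coverage of
each immune phenotype by each algorithm, and the sTILs/CD8 "rescue" rule
that recovers inflamed tumors scored PD-L1-negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .icis_phenotyping import Phenotype, PhenotypeAssignment
from .io_model import Marker, MarkerDensityRecord
from .pdl1_scoring import BinaryStatus

__all__ = [
    "ALGORITHMS",
    "VennPartition",
    "RescueResult",
    "overall_percentage_agreement",
    "opa_matrix",
    "venn_partition",
    "phenotype_coverage",
    "cd8_patient_density",
    "rescue_inflamed_low",
    "DEFAULT_CD8_CUTOFF",
    "DEFAULT_STILS_CUTOFF",
]

ALGORITHMS = ("cps10", "ventana_ic5", "tcic25")

#: cohort medians of the source study; other cohorts will have other medians
DEFAULT_CD8_CUTOFF = 201.0
DEFAULT_STILS_CUTOFF = 10.0


@dataclass(frozen=True)
class VennPartition:
    """Counts of the 8 regions of three binary PD-L1 statuses."""

    triple_positive: int
    cps_tcic_only: int
    ventana_tcic_only: int
    cps_ventana_only: int
    cps_only: int
    ventana_only: int
    tcic_only: int
    all_negative: int

    @property
    def total(self) -> int:
        return (
            self.triple_positive + self.cps_tcic_only + self.ventana_tcic_only
            + self.cps_ventana_only + self.cps_only + self.ventana_only
            + self.tcic_only + self.all_negative
        )

    @property
    def union_positive(self) -> int:
        return self.total - self.all_negative

    def algorithm_totals(self) -> dict[str, int]:
        return {
            "cps10": self.triple_positive + self.cps_tcic_only
            + self.cps_ventana_only + self.cps_only,
            "ventana_ic5": self.triple_positive + self.ventana_tcic_only
            + self.cps_ventana_only + self.ventana_only,
            "tcic25": self.triple_positive + self.cps_tcic_only
            + self.ventana_tcic_only + self.tcic_only,
        }

    def as_dict(self) -> dict[str, int]:
        return {
            "triple_positive": self.triple_positive,
            "cps_tcic_only": self.cps_tcic_only,
            "ventana_tcic_only": self.ventana_tcic_only,
            "cps_ventana_only": self.cps_ventana_only,
            "cps_only": self.cps_only,
            "ventana_only": self.ventana_only,
            "tcic_only": self.tcic_only,
            "all_negative": self.all_negative,
        }


@dataclass(frozen=True)
class RescueResult:
    """One PD-L1-negative Inflamed: Low patient and the rescue decision."""

    patient_id: str
    pdl1_negative_by: frozenset[str]
    cd8_density: float
    stils_percent: float
    rescued: bool


def overall_percentage_agreement(
    a: Sequence[bool], b: Sequence[bool]
) -> float:
    """Fraction of positions on which two binary status vectors agree."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty status vectors")
    return float(np.mean(a == b))


def opa_matrix(statuses: Iterable[BinaryStatus]) -> pd.DataFrame:
    """Pairwise OPA between the three algorithms over a cohort."""
    statuses = list(statuses)
    vectors = {
        alg: [getattr(s, alg) for s in statuses] for alg in ALGORITHMS
    }
    out = pd.DataFrame(index=ALGORITHMS, columns=ALGORITHMS, dtype=float)
    for i in ALGORITHMS:
        for j in ALGORITHMS:
            out.loc[i, j] = overall_percentage_agreement(vectors[i], vectors[j])
    return out


def venn_partition(statuses: Iterable[BinaryStatus]) -> VennPartition:
    """Exact 8-region partition of the three PD-L1 statuses."""
    counts = {key: 0 for key in (
        (True, True, True), (True, False, True), (False, True, True),
        (True, True, False), (True, False, False), (False, True, False),
        (False, False, True), (False, False, False),
    )}
    for s in statuses:
        counts[(s.cps10, s.ventana_ic5, s.tcic25)] += 1
    return VennPartition(
        triple_positive=counts[(True, True, True)],
        cps_tcic_only=counts[(True, False, True)],
        ventana_tcic_only=counts[(False, True, True)],
        cps_ventana_only=counts[(True, True, False)],
        cps_only=counts[(True, False, False)],
        ventana_only=counts[(False, True, False)],
        tcic_only=counts[(False, False, True)],
        all_negative=counts[(False, False, False)],
    )


PhenotypeMapping = Union[
    Mapping[str, Phenotype], Iterable[PhenotypeAssignment]
]


def _as_phenotype_map(phenotypes: PhenotypeMapping) -> dict[str, Phenotype]:
    if isinstance(phenotypes, Mapping):
        return {pid: Phenotype(p) for pid, p in phenotypes.items()}
    return {a.patient_id: a.phenotype for a in phenotypes}


def phenotype_coverage(
    statuses: Iterable[BinaryStatus], phenotypes: PhenotypeMapping
) -> pd.DataFrame:
    """Per (phenotype, algorithm): cluster size, positives, coverage fraction.

    Raises if the status and phenotype patient sets differ.
    """
    statuses = list(statuses)
    pheno = _as_phenotype_map(phenotypes)
    status_ids = {s.patient_id for s in statuses}
    unmatched = sorted(status_ids.symmetric_difference(pheno))
    if unmatched:
        raise ValueError(
            f"patients without both status and phenotype: {unmatched}"
        )
    rows = []
    for phenotype in Phenotype:
        members = [s for s in statuses if pheno[s.patient_id] is phenotype]
        for alg in ALGORITHMS:
            n_pos = sum(getattr(s, alg) for s in members)
            rows.append({
                "phenotype": phenotype.value,
                "algorithm": alg,
                "n_phenotype": len(members),
                "n_positive": n_pos,
                "coverage": n_pos / len(members) if members else float("nan"),
            })
    return pd.DataFrame(rows)


def cd8_patient_density(
    records: Iterable[MarkerDensityRecord],
) -> dict[str, float]:
    """Patient-level CD8 density: median across QC-passing cores, both
    regions pooled."""
    per_patient: dict[str, list[float]] = {}
    for r in records:
        if r.marker is Marker.CD8 and r.qc_pass:
            per_patient.setdefault(r.patient_id, []).append(r.density)
    return {pid: float(np.median(v)) for pid, v in per_patient.items()}


def rescue_inflamed_low(
    statuses: Iterable[BinaryStatus],
    phenotypes: PhenotypeMapping,
    cd8_densities: Mapping[str, float],
    stils: Mapping[str, float],
    cd8_cutoff: float = DEFAULT_CD8_CUTOFF,
    stils_cutoff: float = DEFAULT_STILS_CUTOFF,
) -> tuple[list[RescueResult], dict[str, object]]:
    """Rescue rule for PD-L1-negative Inflamed: Low tumors.

    Restricted to Inflamed: Low patients negative by at least one algorithm,
    a patient is *rescued* — flagged as harboring a relevant anti-tumoral
    immune infiltrate despite PD-L1 negativity — when CD8 density >=
    ``cd8_cutoff`` (cells/mm²) OR sTILs >= ``stils_cutoff`` (%), both
    inclusive. Returns the per-patient results and a summary with negatives
    per algorithm, the triple-negative count and the rescued fraction.
    """
    pheno = _as_phenotype_map(phenotypes)
    results: list[RescueResult] = []
    for s in statuses:
        if pheno.get(s.patient_id) is not Phenotype.INFLAMED_LOW:
            continue
        negative_by = frozenset(
            alg for alg in ALGORITHMS if not getattr(s, alg)
        )
        if not negative_by:
            continue
        cd8 = float(cd8_densities[s.patient_id])
        st = float(stils[s.patient_id])
        results.append(RescueResult(
            patient_id=s.patient_id,
            pdl1_negative_by=negative_by,
            cd8_density=cd8,
            stils_percent=st,
            rescued=(cd8 >= cd8_cutoff) or (st >= stils_cutoff),
        ))
    n = len(results)
    n_rescued = sum(r.rescued for r in results)
    summary = {
        "n_negative_by_any": n,
        "negatives_per_algorithm": {
            alg: sum(alg in r.pdl1_negative_by for r in results)
            for alg in ALGORITHMS
        },
        "n_triple_negative": sum(
            len(r.pdl1_negative_by) == 3 for r in results
        ),
        "n_rescued": n_rescued,
        "rescued_fraction": n_rescued / n if n else float("nan"),
    }
    return results, summary
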