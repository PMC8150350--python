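"""Clinical PD-L1 scoring algorithms and cross-assay consensus scores.

Three drug-linked scoring algorithms are implemented with their clinical
cut-offs (inclusive ``>=``):

* **CPS10** (pembrolizumab): combined positive score
  ``100 * (PD-L1+ tumor cells + PD-L1+ immune cells) / viable tumor cells``,
  capped at 100; positive at CPS >= 10.
* **Ventana IC5%** (atezolizumab): percentage of tumor area occupied by
  PD-L1 positive immune cells; positive at IC >= 5%.
* **TCarea25%/ICarea25%** (durvalumab): positive if >= 25% of tumor cells OR
  >= 25% of the immune-cell area express PD-L1.

To damp inter-assay and section effects, per-patient *consensus scores* are
formed as the median of each score across assays. TC-dependent scores (CPS,
TCarea) exclude SP142, whose TC detection sensitivity is reduced; IC-based
scores (Ventana IC, ICarea) use all four assays.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .io_model import Assay, Cohort, PDL1AssayReadout

__all__ = [
    "TC_CONSENSUS_ASSAYS",
    "ConsensusScores",
    "BinaryStatus",
    "UndefinedScoreError",
    "ClassificationError",
    "compute_cps",
    "build_consensus",
    "classify",
    "consensus_table",
    "status_table",
    "CPS_CUTOFF",
    "VENTANA_IC_CUTOFF",
    "TCIC_CUTOFF",
]

#: assays eligible for TC-dependent consensus scores (SP142 excluded)
TC_CONSENSUS_ASSAYS = (Assay.SP263, Assay.C22C3, Assay.C28_8)

CPS_CUTOFF = 10.0
VENTANA_IC_CUTOFF = 5.0
TCIC_CUTOFF = 25.0


class UndefinedScoreError(ValueError):
    """CPS is undefined when there are no viable tumor cells."""


class ClassificationError(ValueError):
    """A required consensus score is missing for a scoring algorithm."""


@dataclass(frozen=True)
class ConsensusScores:
    """Per-patient median-across-assay PD-L1 scores.

    Fields are ``None`` when no eligible assay contributed (a missing score
    propagates as a :class:`ClassificationError` only where it is needed).
    """

    patient_id: str
    cps_consensus: Optional[float]
    tc_area_consensus: Optional[float]
    ventana_ic_consensus: Optional[float]
    ic_area_consensus: Optional[float]

    def __post_init__(self) -> None:
        for name in ("cps_consensus", "tc_area_consensus",
                     "ventana_ic_consensus", "ic_area_consensus"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} out of [0, 100]: {v}")


@dataclass(frozen=True)
class BinaryStatus:
    """Dichotomized PD-L1 status per algorithm (True = positive)."""

    patient_id: str
    cps10: bool
    ventana_ic5: bool
    tcic25: bool


def compute_cps(pos_tc: float, pos_ic: float, total_viable_tc: float) -> float:
    """Combined positive score: ``100 * (pos_tc + pos_ic) / total_viable_tc``,
    capped at 100.

    Raises :class:`UndefinedScoreError` when ``total_viable_tc`` is zero.
    """
    if total_viable_tc <= 0:
        raise UndefinedScoreError(
            "CPS undefined: total viable tumor cell count must be >= 1"
        )
    if pos_tc < 0 or pos_ic < 0:
        raise ValueError("positive-cell counts must be non-negative")
    return min(100.0, 100.0 * (pos_tc + pos_ic) / total_viable_tc)


def _median(values: Sequence[float]) -> Optional[float]:
    return statistics.median(values) if values else None


def build_consensus(readouts: Iterable[PDL1AssayReadout]) -> ConsensusScores:
    """Median-across-assay consensus scores for one patient.

    CPS and TCarea consensus use SP263/22C3/28-8 only; the IC-based Ventana
    and ICarea consensus use all four assays (both are the percentage of
    tumor area covered by PD-L1+ immune cells, so they share the median of
    ``ic_percent``). Missing assays degrade gracefully to the median of the
    available eligible readouts. Even-count medians are the mean of the two
    middle values.
    """
    readouts = list(readouts)
    if not readouts:
        raise ValueError("build_consensus requires at least one readout")
    pids = {r.patient_id for r in readouts}
    if len(pids) != 1:
        raise ValueError(f"readouts span multiple patients: {sorted(pids)}")
    (pid,) = pids
    tc_eligible = [r for r in readouts if r.assay in TC_CONSENSUS_ASSAYS]
    ic_median = _median([r.ic_percent for r in readouts])
    return ConsensusScores(
        patient_id=pid,
        cps_consensus=_median([r.cps for r in tc_eligible]),
        tc_area_consensus=_median([r.tc_percent for r in tc_eligible]),
        ventana_ic_consensus=ic_median,
        ic_area_consensus=ic_median,
    )


def classify(consensus: ConsensusScores) -> BinaryStatus:
    """Apply the three clinical cut-offs (inclusive ``>=``) to consensus scores.

    The TCarea25%/ICarea25% rule is an OR over its two components; if one
    component is missing the other can still decide a positive, but a
    negative cannot be concluded.
    """
    if consensus.cps_consensus is None:
        raise ClassificationError(
            f"CPS10: cps_consensus missing for {consensus.patient_id}"
        )
    if consensus.ventana_ic_consensus is None:
        raise ClassificationError(
            f"Ventana IC5%: ventana_ic_consensus missing for {consensus.patient_id}"
        )
    cps10 = consensus.cps_consensus >= CPS_CUTOFF
    ventana = consensus.ventana_ic_consensus >= VENTANA_IC_CUTOFF

    tc, ic = consensus.tc_area_consensus, consensus.ic_area_consensus
    if tc is None and ic is None:
        raise ClassificationError(
            f"TCarea25%/ICarea25%: both components missing for {consensus.patient_id}"
        )
    components = [v for v in (tc, ic) if v is not None]
    if any(v >= TCIC_CUTOFF for v in components):
        tcic = True
    elif tc is not None and ic is not None:
        tcic = False
    else:
        raise ClassificationError(
            f"TCarea25%/ICarea25%: undecidable for {consensus.patient_id} "
            "(one component missing, the other below cut-off)"
        )
    return BinaryStatus(consensus.patient_id, cps10, ventana, tcic)


def consensus_table(cohort: Cohort) -> list[ConsensusScores]:
    """Consensus scores for every patient with at least one assay readout."""
    by_patient: dict[str, list[PDL1AssayReadout]] = {}
    for r in cohort.assay_readouts:
        by_patient.setdefault(r.patient_id, []).append(r)
    return [build_consensus(rs) for rs in by_patient.values()]


def status_table(consensus: Iterable[ConsensusScores]) -> list[BinaryStatus]:
    return [classify(c) for c in consensus]
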