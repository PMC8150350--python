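"""End-to-end orchestration: cohort in, all analysis artifacts out."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import pandas as pd

from . import concordance as conc
from . import icis_phenotyping as phen
from . import pdl1_scoring as scoring
from . import survival as surv
from .io_model import Cohort, filter_qc

__all__ = ["PipelineResult", "run_pipeline", "write_outputs"]


@dataclass
class PipelineResult:
    consensus: list[scoring.ConsensusScores]
    statuses: list[scoring.BinaryStatus]
    assignments: list[phen.PhenotypeAssignment]
    matrix: phen.FeatureMatrix
    icis: pd.Series
    opa: pd.DataFrame
    venn: conc.VennPartition
    coverage: pd.DataFrame
    rescue_results: list[conc.RescueResult]
    rescue_summary: dict
    survival_summary: dict
    km_curves: pd.DataFrame


def run_pipeline(
    cohort: Cohort,
    k: int = 4,
    cd8_cutoff: float = conc.DEFAULT_CD8_CUTOFF,
    stils_cutoff: float = conc.DEFAULT_STILS_CUTOFF,
) -> PipelineResult:
    """QC-filter, score, phenotype, cross-tabulate and model a cohort."""
    cohort = filter_qc(cohort)
    consensus = scoring.consensus_table(cohort)
    statuses = scoring.status_table(consensus)
    assignments, matrix, icis = phen.assign_phenotypes(cohort, k=k)

    status_by_pid = {s.patient_id: s for s in statuses}
    common = [a.patient_id for a in assignments if a.patient_id in status_by_pid]
    statuses_common = [status_by_pid[p] for p in common]
    pheno_map = {a.patient_id: a.phenotype for a in assignments
                 if a.patient_id in status_by_pid}

    opa = conc.opa_matrix(statuses_common)
    venn = conc.venn_partition(statuses_common)
    coverage = conc.phenotype_coverage(statuses_common, pheno_map)
    cd8 = conc.cd8_patient_density(cohort.density_records)
    stils = {a.patient_id: a.stils_percent for a in cohort.annotations}
    rescue_results, rescue_summary = conc.rescue_inflamed_low(
        statuses_common, pheno_map, cd8, stils,
        cd8_cutoff=cd8_cutoff, stils_cutoff=stils_cutoff,
    )

    survival_summary, km_curves = _survival_by_phenotype(cohort, pheno_map)
    return PipelineResult(
        consensus=consensus,
        statuses=statuses,
        assignments=assignments,
        matrix=matrix,
        icis=icis,
        opa=opa,
        venn=venn,
        coverage=coverage,
        rescue_results=rescue_results,
        rescue_summary=rescue_summary,
        survival_summary=survival_summary,
        km_curves=km_curves,
    )


def _survival_by_phenotype(cohort: Cohort, pheno_map) -> tuple[dict, pd.DataFrame]:
    ann_by_pid = {a.patient_id: a for a in cohort.annotations}
    summary: dict = {}
    curve_rows = []
    for endpoint in ("dss", "dfs"):
        groups = {}
        for phenotype in phen.Phenotype:
            pids = [p for p, ph in pheno_map.items()
                    if ph is phenotype and p in ann_by_pid]
            if not pids:
                continue
            t = [getattr(ann_by_pid[p], f"{endpoint}_time") for p in pids]
            e = [getattr(ann_by_pid[p], f"{endpoint}_event") for p in pids]
            groups[phenotype.value] = (t, e)
        rates = {}
        for name, (t, e) in groups.items():
            curve = surv.km_estimate(t, e)
            rates[name] = surv.five_year_rate(curve)
            for ti, si, ri in zip(curve.times, curve.survival, curve.at_risk):
                curve_rows.append({
                    "endpoint": endpoint, "group": name,
                    "time": float(ti), "survival": float(si),
                    "at_risk": int(ri),
                })
        try:
            stat, p = surv.logrank_test(groups)
        except ValueError:
            stat, p = float("nan"), float("nan")
        all_t = [t for ts, _ in groups.values() for t in ts]
        all_e = [e for _, es in groups.values() for e in es]
        summary[endpoint] = {
            "five_year_rates": rates,
            "logrank_statistic": stat,
            "logrank_p": p,
            "median_potential_followup": surv.reverse_km_followup(all_t, all_e),
        }
    km_curves = pd.DataFrame(
        curve_rows, columns=["endpoint", "group", "time", "survival", "at_risk"]
    )
    return summary, km_curves


def write_outputs(result: PipelineResult, directory: Union[str, Path]) -> None:
    """Write the External Interface files for every stage."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([
        {
            "patient_id": c.patient_id,
            "cps_consensus": c.cps_consensus,
            "tc_area_consensus": c.tc_area_consensus,
            "ventana_ic_consensus": c.ventana_ic_consensus,
            "ic_area_consensus": c.ic_area_consensus,
        }
        for c in result.consensus
    ]).to_csv(directory / "consensus.csv", index=False)

    def status_word(flag: bool) -> str:
        return "positive" if flag else "negative"

    pd.DataFrame([
        {
            "patient_id": s.patient_id,
            "cps10": status_word(s.cps10),
            "ventana_ic5": status_word(s.ventana_ic5),
            "tcic25": status_word(s.tcic25),
        }
        for s in result.statuses
    ]).to_csv(directory / "status.csv", index=False)

    pd.DataFrame([
        {
            "patient_id": a.patient_id,
            "cluster_id": a.cluster_id,
            "phenotype": a.phenotype.value,
            "icis": a.icis,
        }
        for a in result.assignments
    ]).to_csv(directory / "phenotypes.csv", index=False)

    pd.DataFrame(
        [{"region": k, "count": v} for k, v in result.venn.as_dict().items()]
    ).to_csv(directory / "venn.csv", index=False)

    concordance_payload = {
        "opa": result.opa.to_dict(),
        "venn_regions": result.venn.as_dict(),
        "algorithm_totals": result.venn.algorithm_totals(),
        "union_positive": result.venn.union_positive,
        "coverage": result.coverage.to_dict(orient="records"),
        "rescue_summary": result.rescue_summary,
    }
    (directory / "concordance.json").write_text(
        json.dumps(concordance_payload, indent=2, default=float)
    )
    (directory / "survival_summary.json").write_text(
        json.dumps(result.survival_summary, indent=2, default=float)
    )
    result.km_curves.to_csv(directory / "km_curves.csv", index=False)
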