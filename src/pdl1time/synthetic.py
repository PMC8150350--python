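"""Synthetic MIBC cohorts and exact fixtures from published marginal counts.

Two kinds of data live here:

1. A parametric cohort **generator** that emulates the statistical structure
   the analysis assumes: a 193-patient cohort carrying four spatially
   profiled immune phenotypes (Evasion, Inflamed: High, Inflamed: Low,
   Uninflamed) with log-normal per-core marker densities, four PD-L1 assays
   with additive readout noise and attenuated SP142 tumor-cell sensitivity,
   and phenotype-linked exponential survival calibrated to per-phenotype
   5-year rates.
2. **Fixtures** that reconstruct, patient by patient, the published
   cross-tabulations (Venn partition of the three PD-L1 statuses; phenotype
   coverage; the CD8/sTILs rescue set). These are synthetic stand-ins built
   from printed marginal counts — individual patient assignments are
   arbitrary; only the region counts are contractual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .icis_phenotyping import Phenotype
from .io_model import (
    Assay,
    Cohort,
    Marker,
    MarkerDensityRecord,
    PatientAnnotation,
    PDL1AssayReadout,
    Region,
)
from .pdl1_scoring import BinaryStatus

__all__ = [
    "PhenotypeProfile",
    "SimulationConfig",
    "DEFAULT_PROFILES",
    "generate_cohort",
    "generate_cohort_with_truth",
    "simulate_survival_frame",
    "simulate_cox_frame",
    "fixture_from_venn",
    "fixture_crosstab",
    "CrosstabFixture",
]

# shared marker/region structure of the density panel (log2 cells/mm²
# offsets relative to a phenotype's base infiltration level)
_MARKER_OFFSETS = {
    Marker.CD3: 1.5,
    Marker.CD8: 1.0,
    Marker.GZMB: 0.0,
    Marker.CD68: 0.5,
    Marker.FOXP3: -0.5,
    Marker.PD1: -0.5,
    Marker.CTLA4: -1.5,
    Marker.LAG3: -1.5,
    Marker.CD56: -2.5,
}
_REGION_OFFSETS = {Region.INVASION_FRONT: 0.3, Region.TUMOR_CENTER: -0.3}


def _density_means(base_log2: float) -> dict[tuple[Marker, Region], float]:
    return {
        (m, r): base_log2 + _MARKER_OFFSETS[m] + _REGION_OFFSETS[r]
        for m in Marker
        for r in Region
    }


@dataclass(frozen=True)
class PhenotypeProfile:
    """Generative parameters of one immune phenotype."""

    phenotype: Phenotype
    density_log2_means: Mapping[Tuple[Marker, Region], float]
    density_log2_sd: float
    pdl1_ic_mean: float       # % tumor area covered by PD-L1+ immune cells
    pdl1_tc_mean: float       # % viable tumor cells stained
    pdl1_sd: float            # patient-level spread of the PD-L1 latents
    five_year_dss: float
    five_year_dfs: float
    stils_mean: float
    stils_sd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.five_year_dss <= 1.0 and 0.0 <= self.five_year_dfs <= 1.0):
            raise ValueError("five-year rates must lie in [0, 1]")
        if self.density_log2_sd <= 0 or self.pdl1_sd <= 0 or self.stils_sd <= 0:
            raise ValueError("spread parameters must be positive")


#: canonical phenotype order used for prevalence vectors
PHENOTYPE_ORDER = (
    Phenotype.EVASION,
    Phenotype.INFLAMED_HIGH,
    Phenotype.INFLAMED_LOW,
    Phenotype.UNINFLAMED,
)

DEFAULT_PROFILES: dict[Phenotype, PhenotypeProfile] = {
    Phenotype.EVASION: PhenotypeProfile(
        phenotype=Phenotype.EVASION,
        density_log2_means=_density_means(7.0),
        density_log2_sd=1.0,
        pdl1_ic_mean=3.0,
        pdl1_tc_mean=60.0,
        pdl1_sd=8.0,
        five_year_dss=0.298,
        five_year_dfs=0.258,
        stils_mean=15.0,
        stils_sd=8.0,
    ),
    Phenotype.INFLAMED_HIGH: PhenotypeProfile(
        phenotype=Phenotype.INFLAMED_HIGH,
        density_log2_means=_density_means(9.0),
        density_log2_sd=1.0,
        pdl1_ic_mean=30.0,
        pdl1_tc_mean=4.0,
        pdl1_sd=8.0,
        five_year_dss=0.747,
        five_year_dfs=0.751,
        stils_mean=35.0,
        stils_sd=10.0,
    ),
    Phenotype.INFLAMED_LOW: PhenotypeProfile(
        phenotype=Phenotype.INFLAMED_LOW,
        density_log2_means=_density_means(6.5),
        density_log2_sd=1.0,
        pdl1_ic_mean=2.0,
        pdl1_tc_mean=1.0,
        pdl1_sd=2.0,
        five_year_dss=0.431,
        five_year_dfs=0.437,
        stils_mean=12.0,
        stils_sd=6.0,
    ),
    Phenotype.UNINFLAMED: PhenotypeProfile(
        phenotype=Phenotype.UNINFLAMED,
        density_log2_means=_density_means(4.0),
        density_log2_sd=1.0,
        pdl1_ic_mean=0.5,
        pdl1_tc_mean=0.5,
        pdl1_sd=1.0,
        five_year_dss=0.277,
        five_year_dfs=0.237,
        stils_mean=3.0,
        stils_sd=3.0,
    ),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation settings.

    Defaults emulate the study design: 193 patients, four TMA cores each
    (two per region), four PD-L1 assays with additive readout noise, SP142
    tumor-cell signal attenuated by 80%, and ~40% censoring.
    """

    n_patients: int = 193
    prevalences: Tuple[float, float, float, float] = (0.14, 0.14, 0.35, 0.37)
    seed: int = 0
    assay_noise_sd: float = 5.0
    sp142_tc_attenuation: float = 0.8
    censoring_rate: float = 0.4
    cores_per_region: int = 2

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be at least 4")
        if len(self.prevalences) != 4 or any(p < 0 for p in self.prevalences):
            raise ValueError("prevalences must be four non-negative reals")
        if abs(sum(self.prevalences) - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1 (within 1e-9)")
        if not (0.0 <= self.sp142_tc_attenuation <= 1.0):
            raise ValueError("sp142_tc_attenuation must lie in [0, 1]")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.cores_per_region < 1:
            raise ValueError("cores_per_region must be >= 1")


def _largest_remainder_counts(n: int, prevalences: Sequence[float]) -> list[int]:
    """Exact integer allocation of n patients to the four phenotypes."""
    quotas = [n * p for p in prevalences]
    counts = [math.floor(q) for q in quotas]
    remainder = n - sum(counts)
    order = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _hazard(five_year_rate: float) -> float:
    """Exponential rate solving S(60 months) = five_year_rate."""
    if five_year_rate <= 0 or five_year_rate >= 1:
        raise ValueError("five-year rate must lie strictly in (0, 1)")
    return -math.log(five_year_rate) / 60.0


def _censor_horizon(
    hazards: Sequence[float], weights: Sequence[float], censoring_rate: float
) -> float:
    """Horizon H of the U(0, H) censoring law hitting the target rate.

    Under T ~ Exp(lambda) and C ~ U(0, H), P(censored) = (1 - e^{-lambda H})
    / (lambda H); the mixture-weighted version is solved for H by bisection.
    """
    if censoring_rate <= 0:
        return math.inf

    def censored_fraction(h: float) -> float:
        return sum(
            w * (1.0 - math.exp(-lam * h)) / (lam * h)
            for lam, w in zip(hazards, weights)
        )

    lo, hi = 1e-6, 1e7
    return brentq(lambda h: censored_fraction(h) - censoring_rate, lo, hi)


def _clip_pct(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 100.0)


def generate_cohort_with_truth(
    config: SimulationConfig,
    profiles: Optional[Mapping[Phenotype, PhenotypeProfile]] = None,
) -> tuple[Cohort, dict[str, Phenotype]]:
    """Generate a cohort plus the generating phenotype of every patient.

    Fully reproducible from ``config.seed``; the returned cohort passes
    io_model validation for any valid configuration.
    """
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    rng = np.random.default_rng(config.seed)
    counts = _largest_remainder_counts(config.n_patients, config.prevalences)

    patient_ids: list[str] = []
    truth: dict[str, Phenotype] = {}
    i = 0
    for phenotype, count in zip(PHENOTYPE_ORDER, counts):
        for _ in range(count):
            i += 1
            pid = f"P{i:04d}"
            patient_ids.append(pid)
            truth[pid] = phenotype

    density_records: list[MarkerDensityRecord] = []
    assay_readouts: list[PDL1AssayReadout] = []
    annotations: list[PatientAnnotation] = []

    hazards_dss = {p: _hazard(profiles[p].five_year_dss) for p in PHENOTYPE_ORDER}
    hazards_dfs = {p: _hazard(profiles[p].five_year_dfs) for p in PHENOTYPE_ORDER}
    weights = [c / config.n_patients for c in counts]
    h_dss = _censor_horizon(
        [hazards_dss[p] for p in PHENOTYPE_ORDER], weights, config.censoring_rate
    )
    h_dfs = _censor_horizon(
        [hazards_dfs[p] for p in PHENOTYPE_ORDER], weights, config.censoring_rate
    )

    region_tag = {Region.INVASION_FRONT: "IF", Region.TUMOR_CENTER: "TC"}
    for pid in patient_ids:
        prof = profiles[truth[pid]]

        # per-core log-normal densities around the phenotype's log2 means
        for region in Region:
            for j in range(1, config.cores_per_region + 1):
                core_id = f"{pid}-{region_tag[region]}{j}"
                for marker in Marker:
                    mu = prof.density_log2_means[(marker, region)]
                    log2_val = rng.normal(mu, prof.density_log2_sd)
                    density = max(0.0, 2.0 ** log2_val - 1.0)
                    density_records.append(MarkerDensityRecord(
                        patient_id=pid,
                        core_id=core_id,
                        region=region,
                        marker=marker,
                        density=density,
                        qc_pass=True,
                    ))

        # patient-level PD-L1 latents, then per-assay readouts with noise
        ic_latent = float(_clip_pct(np.array(
            rng.normal(prof.pdl1_ic_mean, prof.pdl1_sd)
        )))
        tc_latent = float(_clip_pct(np.array(
            rng.normal(prof.pdl1_tc_mean, prof.pdl1_sd)
        )))
        cps_latent = min(100.0, tc_latent + ic_latent)
        for assay in Assay:
            ic = float(_clip_pct(np.array(
                ic_latent + rng.normal(0.0, config.assay_noise_sd)
            )))
            tc_true = tc_latent
            if assay is Assay.SP142:
                tc_true = tc_latent * (1.0 - config.sp142_tc_attenuation)
            tc = float(_clip_pct(np.array(
                tc_true + rng.normal(0.0, config.assay_noise_sd)
            )))
            cps_true = cps_latent
            if assay is Assay.SP142:
                cps_true = min(100.0, tc_true + ic_latent)
            cps = float(_clip_pct(np.array(
                cps_true + rng.normal(0.0, config.assay_noise_sd)
            )))
            assay_readouts.append(PDL1AssayReadout(
                patient_id=pid, assay=assay,
                ic_percent=ic, tc_percent=tc, cps=cps,
            ))

        # phenotype-linked exponential survival with uniform censoring
        def observe(lam: float, horizon: float) -> tuple[float, bool]:
            t_true = rng.exponential(1.0 / lam)
            if math.isinf(horizon):
                return t_true, True
            c = rng.uniform(0.0, horizon)
            return (t_true, True) if t_true <= c else (c, False)

        dss_time, dss_event = observe(hazards_dss[truth[pid]], h_dss)
        dfs_time, dfs_event = observe(hazards_dfs[truth[pid]], h_dfs)

        stils = float(np.clip(
            rng.normal(prof.stils_mean, prof.stils_sd), 0.0, 100.0
        ))
        covariates = {
            "pT_stage": rng.choice(["pT2", "pT3", "pT4"], p=[0.35, 0.45, 0.20]),
            "pN_stage": rng.choice(["pN0", "pN1", "pN2"], p=[0.60, 0.20, 0.20]),
            "lymphovascular_invasion": rng.choice(["L0", "L1"]),
            "age": float(np.clip(rng.normal(69.7, 9.0), 40.0, 92.0)),
            "gender": rng.choice(["male", "female"], p=[0.72, 0.28]),
            "margin_status": rng.choice(["R0", "R1"], p=[0.85, 0.15]),
            "adjuvant_chemo": rng.choice(["no", "yes"], p=[0.746, 0.254]),
            "grade": rng.choice(["G2", "G3"], p=[0.20, 0.80]),
        }
        annotations.append(PatientAnnotation(
            patient_id=pid,
            stils_percent=stils,
            dss_time=dss_time,
            dss_event=dss_event,
            dfs_time=dfs_time,
            dfs_event=dfs_event,
            covariates=covariates,
        ))

    return Cohort(density_records, assay_readouts, annotations), truth


def generate_cohort(
    config: SimulationConfig,
    profiles: Optional[Mapping[Phenotype, PhenotypeProfile]] = None,
) -> Cohort:
    """Generate a synthetic cohort (see :func:`generate_cohort_with_truth`)."""
    cohort, _ = generate_cohort_with_truth(config, profiles)
    return cohort


def simulate_survival_frame(
    n: int,
    seed: int,
    prevalences: Sequence[float] = SimulationConfig.prevalences,
    profiles: Optional[Mapping[Phenotype, PhenotypeProfile]] = None,
    censoring_rate: float = SimulationConfig.censoring_rate,
    endpoint: str = "dss",
) -> pd.DataFrame:
    """Survival-only simulation: columns (phenotype, time, event).

    Same phenotype-linked exponential/uniform-censoring model as
    :func:`generate_cohort`, without the marker and assay layers — intended
    for large-n calibration checks of the Kaplan–Meier recovery.
    """
    profiles = dict(DEFAULT_PROFILES if profiles is None else profiles)
    attr = f"five_year_{endpoint}"
    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(n, prevalences)
    hazards = [getattr(profiles[p], attr) for p in PHENOTYPE_ORDER]
    hazards = [_hazard(r) for r in hazards]
    horizon = _censor_horizon(hazards, [c / n for c in counts], censoring_rate)
    rows = []
    for phenotype, count, lam in zip(PHENOTYPE_ORDER, counts, hazards):
        t_true = rng.exponential(1.0 / lam, size=count)
        if math.isinf(horizon):
            t_obs, ev = t_true, np.ones(count, dtype=bool)
        else:
            c = rng.uniform(0.0, horizon, size=count)
            ev = t_true <= c
            t_obs = np.where(ev, t_true, c)
        for t, e in zip(t_obs, ev):
            rows.append({"phenotype": phenotype.value, "time": float(t),
                         "event": bool(e)})
    return pd.DataFrame(rows)


def simulate_cox_frame(
    n: int,
    hazard_ratio: float,
    seed: int,
    baseline_five_year: float = 0.5,
    censoring_rate: float = 0.3,
) -> pd.DataFrame:
    """Two-arm exponential survival with a known indicator hazard ratio.

    The binary ``indicator`` (fair coin) multiplies the baseline hazard by
    ``hazard_ratio``; the eight standard adjustment covariates are drawn
    independently of the hazard, so the adjusted model should recover the
    generating HR without confounding.
    """
    rng = np.random.default_rng(seed)
    lam0 = _hazard(baseline_five_year)
    indicator = rng.integers(0, 2, size=n)
    lam = lam0 * np.where(indicator == 1, hazard_ratio, 1.0)
    t_true = rng.exponential(1.0 / lam)
    horizon = _censor_horizon(
        [lam0, lam0 * hazard_ratio], [0.5, 0.5], censoring_rate
    )
    if math.isinf(horizon):
        event = np.ones(n, dtype=bool)
        t_obs = t_true
    else:
        c = rng.uniform(0.0, horizon, size=n)
        event = t_true <= c
        t_obs = np.where(event, t_true, c)
    return pd.DataFrame({
        "time": t_obs,
        "event": event,
        "indicator": indicator.astype(float),
        "pT_stage": rng.choice(["pT2", "pT3", "pT4"], size=n),
        "pN_stage": rng.choice(["pN0", "pN1", "pN2"], size=n),
        "lymphovascular_invasion": rng.choice(["L0", "L1"], size=n),
        "age": rng.normal(69.7, 9.0, size=n),
        "gender": rng.choice(["male", "female"], size=n),
        "margin_status": rng.choice(["R0", "R1"], size=n),
        "adjuvant_chemo": rng.choice(["no", "yes"], size=n),
        "grade": rng.choice(["G2", "G3"], size=n),
    })


# ---------------------------------------------------------------------------
# Fixtures reconstructed from published marginal counts (synthetic stand-ins
# for the unavailable patient-level cohort; ids are sequential and carry no
# meaning — only the cross-tabulated counts are contractual).
# ---------------------------------------------------------------------------

#: Venn region counts of the three PD-L1 statuses in the 193-patient cohort
VENN_REGION_COUNTS = {
    "triple_positive": 54,
    "cps_tcic_only": 21,
    "ventana_tcic_only": 10,
    "cps_ventana_only": 1,
    "cps_only": 8,
    "ventana_only": 5,
    "tcic_only": 4,
    "all_negative": 90,
}

_REGION_FLAGS = {
    "triple_positive": (True, True, True),
    "cps_tcic_only": (True, False, True),
    "ventana_tcic_only": (False, True, True),
    "cps_ventana_only": (True, True, False),
    "cps_only": (True, False, False),
    "ventana_only": (False, True, False),
    "tcic_only": (False, False, True),
    "all_negative": (False, False, False),
}


def fixture_from_venn() -> list[BinaryStatus]:
    """Status table (n = 193) realizing the published Venn partition exactly.

    Per-algorithm totals implied: CPS10 = 84, Ventana IC5% = 70,
    TCarea25%/ICarea25% = 89; union positive = 103.
    """
    statuses = []
    i = 0
    for region, count in VENN_REGION_COUNTS.items():
        cps, ventana, tcic = _REGION_FLAGS[region]
        for _ in range(count):
            i += 1
            statuses.append(BinaryStatus(f"V{i:03d}", cps, ventana, tcic))
    return statuses


@dataclass(frozen=True)
class CrosstabFixture:
    """Statuses, phenotypes and CD8/sTILs values realizing the published
    phenotype-coverage and rescue cross-tabulations."""

    statuses: list[BinaryStatus]
    phenotypes: dict[str, Phenotype]
    cd8: dict[str, float]
    stils: dict[str, float]


def fixture_crosstab() -> CrosstabFixture:
    """Synthetic 193-patient cross-tabulation fixture.

    Encodes: *Evasion* n=27 (CPS10 27+, Ventana 14+ i.e. 13 missed,
    TC/IC 27+); *Inflamed: High* n=27 (Ventana 26+, CPS10 25+, TC/IC 26+);
    *Inflamed: Low* n=68 of which 48 are PD-L1-negative by at least one
    algorithm (all 48 CPS-negative, 46 Ventana-negative, 33 negative by all
    three) with CD8/sTILs values such that exactly 39 of the 48 meet
    (CD8 >= 201/mm² OR sTILs >= 10%); *Uninflamed* n=71, all negative.

    The published per-algorithm negative counts within the 48 (46 Ventana,
    44 TC/IC, 48 CPS) are mutually inconsistent with the published
    triple-negative count of 33 (46 + 44 − 48 forces an overlap of at least
    42), so this fixture keeps 48/46/33 exact and encodes 35 TC/IC-negative,
    the maximum consistent value.
    """
    statuses: list[BinaryStatus] = []
    phenotypes: dict[str, Phenotype] = {}
    cd8: dict[str, float] = {}
    stils: dict[str, float] = {}
    counter = {"i": 0}

    def add(phenotype: Phenotype, cps: bool, ventana: bool, tcic: bool,
            cd8_val: float, stils_val: float, count: int) -> None:
        for _ in range(count):
            counter["i"] += 1
            pid = f"C{counter['i']:03d}"
            statuses.append(BinaryStatus(pid, cps, ventana, tcic))
            phenotypes[pid] = phenotype
            cd8[pid] = cd8_val
            stils[pid] = stils_val

    # Evasion (n=27): CPS 27+, Ventana 14+, TC/IC 27+
    add(Phenotype.EVASION, True, True, True, 300.0, 15.0, 14)
    add(Phenotype.EVASION, True, False, True, 300.0, 15.0, 13)

    # Inflamed: High (n=27): Ventana 26+, CPS 25+, TC/IC 26+
    add(Phenotype.INFLAMED_HIGH, True, True, True, 900.0, 40.0, 24)
    add(Phenotype.INFLAMED_HIGH, True, True, False, 900.0, 40.0, 1)
    add(Phenotype.INFLAMED_HIGH, False, True, True, 900.0, 40.0, 1)
    add(Phenotype.INFLAMED_HIGH, False, False, True, 900.0, 40.0, 1)

    # Inflamed: Low (n=68): 20 triple-positive plus the 48-patient
    # negative-by->=1 set: 33 triple-negative, 2 (V+, T-), 13 (V-, T+),
    # all CPS-negative. Rescue: 39 of the 48 meet the CD8/sTILs rule
    # (20 both, 10 CD8-only, 9 sTILs-only), 9 meet neither.
    add(Phenotype.INFLAMED_LOW, True, True, True, 350.0, 18.0, 20)
    add(Phenotype.INFLAMED_LOW, False, False, False, 400.0, 25.0, 14)  # both
    add(Phenotype.INFLAMED_LOW, False, False, False, 250.0, 4.0, 10)   # CD8 only
    add(Phenotype.INFLAMED_LOW, False, False, False, 120.0, 15.0, 9)   # sTILs only
    add(Phenotype.INFLAMED_LOW, False, True, False, 400.0, 25.0, 2)    # V+, T- (both)
    add(Phenotype.INFLAMED_LOW, False, False, True, 400.0, 25.0, 4)    # V-, T+ (both)
    add(Phenotype.INFLAMED_LOW, False, False, True, 80.0, 3.0, 9)      # V-, T+ (neither)

    # Uninflamed (n=71): all negative
    add(Phenotype.UNINFLAMED, False, False, False, 50.0, 2.0, 71)

    assert counter["i"] == 193
    return CrosstabFixture(statuses, phenotypes, cd8, stils)
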