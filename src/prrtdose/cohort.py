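"""Synthetic cohort generator for four-cycle [177Lu]Lu-DOTATATE therapy.

Virtual patients carry ground-truth kinetics — mono-exponential retention
per organ-at-risk and tumour lesion, bi-exponential blood concentration and
whole-body retention, one quadruple per cycle — from which noisy measurement
series are emitted on the clinical sampling schedules (SPECT VOIs at ~3, 20
and 90/120 h; blood at 0.5, 1.5, 6, 20 and 90/120 h; whole-body probe at 1,
1.5, 4, 20 and 90/120 h).  Defaults are calibrated to the published
30-patient cohort: administered activity 7.2 ± 0.4 GBq/cycle within
6.3–7.7 GBq, kidney TIAC drifting up across cycles, liver / whole-body /
tumour TIAC drifting down, spleen and red marrow roughly constant, and
tumour uptake declining geometrically so cycle contributions fall from
about 35% to about 18% of the cumulative dose.

Ground truth is kept separate from measurements so downstream fitting and
dose code can be validated against the generating parameters.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .constants import LN2, LU177_HALF_LIFE_H
from .biokinetics import MeasurementSeries, monoexp, biexp

__all__ = [
    "CohortConfig",
    "PatientTruth",
    "OrganKinetics",
    "TumorTruth",
    "BiexpParams",
    "generate_cohort",
    "simulate_series",
    "OAR_REGIONS",
    "TUMOR_SITES",
]

CYCLES = (1, 2, 3, 4)
OAR_REGIONS = ("kidney", "spleen", "liver")
TUMOR_SITES = ("liver", "pancreas", "bone", "node")
_KIND_CODE = {"voi": 1, "blood": 2, "wb": 3}

#: Hard cap keeping every simulated effective half-life below the 177Lu
#: physical half-life (159.5 h).
_TEFF_CAP_H = LU177_HALF_LIFE_H - 1.0


@dataclass(frozen=True)
class BiexpParams:
    """One bi-exponential quadruple: amplitudes and time constants (h)."""

    a1: float
    a2: float
    tau1: float
    tau2: float

    def curve(self, t):
        return biexp(t, self.a1, self.a2, self.tau1, self.tau2)

    @property
    def tiac_h(self) -> float:
        return self.a1 * self.tau1 + self.a2 * self.tau2


@dataclass(frozen=True)
class OrganKinetics:
    """Per-cycle mono-exponential kinetics of one organ: uptake amplitude
    (fraction of injected activity at t=0) and effective half-life (h)."""

    amplitudes: tuple[float, float, float, float]
    teff_h: tuple[float, float, float, float]

    def fia(self, t, cycle: int):
        tau = self.teff_h[cycle - 1] / LN2
        return monoexp(t, self.amplitudes[cycle - 1], tau)

    def tiac_h(self, cycle: int) -> float:
        return self.amplitudes[cycle - 1] * self.teff_h[cycle - 1] / LN2


@dataclass(frozen=True)
class TumorTruth:
    """One lesion: volume, anatomical site, per-cycle uptake."""

    tumor_id: str
    site: str
    volume_ml: float
    kinetics: OrganKinetics


@dataclass(frozen=True)
class PatientTruth:
    """Ground-truth biokinetics and demographics of one virtual patient."""

    patient_id: str
    gender: str
    weight_kg: float
    liver_burden: float
    organ_volumes: Mapping[str, float]
    organs: Mapping[str, OrganKinetics]
    tumors: tuple[TumorTruth, ...]
    blood: tuple[BiexpParams, ...]   # MBq/mL per MBq injected (1/mL)
    wb: tuple[BiexpParams, ...]      # fraction of injected activity
    activities_gbq: tuple[float, float, float, float]
    late_time_h: float
    blood_missing: bool = False

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError("weight must be > 0")
        if not 0.0 <= self.liver_burden <= 1.0:
            raise ValueError("liver_burden must lie in [0, 1]")
        for kin in list(self.organs.values()) + [t.kinetics for t in self.tumors]:
            if any(h <= 0 or h > LU177_HALF_LIFE_H for h in kin.teff_h):
                raise ValueError("effective half-lives must lie in (0, 159.5] h")
        for tum in self.tumors:
            if tum.volume_ml < 4.0:
                raise ValueError("tumour volumes below 4 mL are not analysed")
        for p in self.wb:
            if p.a1 + p.a2 > 1.0 + 1e-9:
                raise ValueError("whole-body amplitudes must sum to <= 1 at t=0")
            if max(p.tau1, p.tau2) * LN2 > LU177_HALF_LIFE_H + 1e-9:
                raise ValueError("whole-body effective half-life exceeds physical")

    # --- analytic ground truth used by recovery / end-to-end tests -------
    def organ_tiac(self, region: str, cycle: int) -> float:
        return self.organs[region].tiac_h(cycle)

    def blood_conc_tiac(self, cycle: int) -> float:
        """Integral of blood concentration per MBq injected (h/mL)."""
        return self.blood[cycle - 1].tiac_h

    def wb_tiac(self, cycle: int) -> float:
        return self.wb[cycle - 1].tiac_h


def _mapping(**kw):
    return field(default_factory=lambda: dict(kw))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the published cohort; per-region per-cycle mean TIAC
    targets encode the cycle drifts (kidney up, liver/whole-body/tumour
    down) whose cycle IV-minus-I differences match the printed trends in
    sign.
    """

    n_patients: int = 30
    activity_mean_gbq: float = 7.2
    activity_sd_gbq: float = 0.4
    activity_range_gbq: tuple[float, float] = (6.3, 7.7)

    schedule_voi: tuple[float, ...] = (3.0, 20.0)
    schedule_blood: tuple[float, ...] = (0.5, 1.5, 6.0, 20.0)
    schedule_wb: tuple[float, ...] = (1.0, 1.5, 4.0, 20.0)
    late_window_h: tuple[float, float] = (90.0, 120.0)
    time_jitter_h: float = 0.25

    noise_cv: float = 0.10
    intercycle_corr: float = 0.9
    n_missing_blood: int = 3

    p_male: float = 17.0 / 30.0
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 12.0

    # Per-cycle mean TIAC targets (h); kidney rises ~0.2 h I->IV, spleen
    # roughly flat, matching the printed cycle tables.
    organ_tiac_targets_h: Mapping[str, tuple[float, ...]] = _mapping(
        kidney=(1.7, 1.9, 1.9, 1.9), spleen=(1.6, 1.6, 1.7, 1.7))
    organ_teff_h: Mapping[str, float] = _mapping(kidney=50.0, spleen=60.0, liver=65.0)
    organ_cv: Mapping[str, float] = _mapping(kidney=0.30, spleen=0.45, liver=0.25)
    organ_volume_mean_ml: Mapping[str, float] = _mapping(
        kidney=300.0, spleen=220.0, liver=1900.0)
    organ_volume_cv: float = 0.12
    kidney_burden_coupling: float = 0.30

    # Liver TIAC grows with infiltrated fraction and declines over cycles.
    liver_tiac_base_h: float = 2.0
    liver_tiac_burden_scale_h: float = 55.0
    liver_cycle_decline: tuple[float, ...] = (1.0, 0.876, 0.806, 0.741)

    tumor_extra_mean: float = 0.4          # lesions/patient = 1 + Poisson
    tumor_volume_median_ml: float = 22.0
    tumor_volume_sigma: float = 0.85
    tumor_tiac_per_ml_h: float = 0.073
    tumor_decline: float = 0.8             # geometric uptake decline/cycle
    tumor_teff_h: float = 70.0
    tumor_cv: float = 0.6
    tumor_site_p: tuple[float, ...] = (0.5, 0.2, 0.15, 0.15)
    tumor_site_uptake: Mapping[str, float] = _mapping(
        liver=1.2, pancreas=1.2, bone=0.6, node=0.6)

    # Blood (concentration per MBq injected) and whole-body retention.
    blood_base: tuple[float, float, float, float] = (3.0e-5, 2.0e-6, 2.0, 47.0)
    blood_cycle_mult: tuple[float, ...] = (1.0, 1.056, 1.056, 1.056)
    blood_cv: float = 0.25
    wb_base: tuple[float, float, float, float] = (0.58, 0.38, 2.58, 89.3)
    wb_t2_cycle_mult: tuple[float, ...] = (1.0, 0.78, 0.70, 0.70)
    wb_cv: float = 0.35

    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        lo, hi = self.activity_range_gbq
        if not lo <= self.activity_mean_gbq <= hi:
            raise ValueError("activity_range must contain activity_mean")
        if not 0.0 <= self.intercycle_corr <= 1.0:
            raise ValueError("intercycle_corr must lie in [0, 1]")

    # -- administered-activity law ---------------------------------------
    def activity_loc_gbq(self) -> float:
        """Pre-truncation location of the activity normal, calibrated so the
        truncated distribution's mean equals ``activity_mean_gbq``."""
        lo, hi = self.activity_range_gbq
        sd = self.activity_sd_gbq
        if sd == 0:
            return self.activity_mean_gbq

        def gap(loc):
            a, b = (lo - loc) / sd, (hi - loc) / sd
            return truncnorm.mean(a, b, loc=loc, scale=sd) - self.activity_mean_gbq

        return float(brentq(gap, lo, hi, xtol=1e-12))

    def activity_analytic_mean_gbq(self) -> float:
        """Analytic mean of the generator's truncated-normal activity law
        (equals ``activity_mean_gbq`` by calibration)."""
        lo, hi = self.activity_range_gbq
        sd = self.activity_sd_gbq
        if sd == 0:
            return self.activity_mean_gbq
        loc = self.activity_loc_gbq()
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd))


def _crc(text: str) -> int:
    return zlib.crc32(text.encode("utf-8"))


def _series_rng(config: CohortConfig, patient_id: str, kind: str,
                region: str, cycle: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [config.rng_seed & 0x7FFFFFFF, _crc(patient_id), _KIND_CODE[kind],
         _crc(region), int(cycle)])
    return np.random.default_rng(ss)


def _lognorm_factor(rng, sigma: float, z: float | None = None) -> float:
    """Mean-one lognormal multiplier; z overrides the draw when supplied."""
    if sigma <= 0:
        return 1.0
    zz = rng.standard_normal() if z is None else z
    return math.exp(sigma * zz - 0.5 * sigma * sigma)


def _cycle_factors(rng, sigma: float, rho: float) -> np.ndarray:
    """Four mean-one lognormal factors sharing a patient-level component
    with inter-cycle correlation ``rho``."""
    zp = rng.standard_normal()
    zc = rng.standard_normal(4)
    z = rho * zp + math.sqrt(max(0.0, 1.0 - rho * rho)) * zc
    return np.exp(sigma * z - 0.5 * sigma * sigma)


def _draw_truncated_activity(rng, loc: float, sd: float,
                             lo: float, hi: float) -> float:
    if sd == 0:
        return loc
    for _ in range(10000):
        x = rng.normal(loc, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(loc, lo), hi))  # pragma: no cover


def _draw_patient(config: CohortConfig, index: int, blood_missing: bool
                  ) -> PatientTruth:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed & 0x7FFFFFFF, 1000 + index]))
    rho = config.intercycle_corr
    pid = f"P{index + 1:03d}"

    gender = "male" if rng.random() < config.p_male else "female"
    weight = float(np.clip(rng.normal(config.weight_mean_kg, config.weight_sd_kg),
                           40.0, 130.0))
    burden = float(rng.beta(0.8, 1.6))
    late = float(rng.uniform(*config.late_window_h))
    loc = config.activity_loc_gbq()
    lo, hi = config.activity_range_gbq
    acts = tuple(_draw_truncated_activity(rng, loc, config.activity_sd_gbq, lo, hi)
                 for _ in CYCLES)

    volumes = {r: float(m * _lognorm_factor(rng, config.organ_volume_cv))
               for r, m in config.organ_volume_mean_ml.items()}

    organs: dict[str, OrganKinetics] = {}
    for region in OAR_REGIONS:
        teff = min(config.organ_teff_h[region] * _lognorm_factor(rng, 0.10),
                   _TEFF_CAP_H)
        fac = _cycle_factors(rng, config.organ_cv[region], rho)
        if region == "liver":
            base = (config.liver_tiac_base_h
                    + config.liver_tiac_burden_scale_h * burden)
            tiacs = base * np.asarray(config.liver_cycle_decline) * fac
        else:
            tiacs = np.asarray(config.organ_tiac_targets_h[region]) * fac
            if region == "kidney":
                tiacs = tiacs * (1.0 - config.kidney_burden_coupling * burden)
        amps = tuple(float(x) for x in tiacs * LN2 / teff)
        organs[region] = OrganKinetics(amps, (teff,) * 4)

    tumors = []
    n_lesions = 1 + int(rng.poisson(config.tumor_extra_mean))
    for j in range(n_lesions):
        site = str(rng.choice(TUMOR_SITES, p=config.tumor_site_p))
        vol = max(4.0, float(config.tumor_volume_median_ml
                             * math.exp(config.tumor_volume_sigma
                                        * rng.standard_normal())))
        teff = min(config.tumor_teff_h * _lognorm_factor(rng, 0.10), _TEFF_CAP_H)
        fac = _cycle_factors(rng, config.tumor_cv, rho)
        decline = config.tumor_decline ** np.arange(4)
        tiac1 = (config.tumor_tiac_per_ml_h * vol
                 * config.tumor_site_uptake[site])
        tiacs = tiac1 * decline * fac
        amps = tuple(float(x) for x in tiacs * LN2 / teff)
        tumors.append(TumorTruth(f"{pid}_T{j + 1}", site, vol,
                                 OrganKinetics(amps, (teff,) * 4)))

    b1, b2, bt1, bt2 = config.blood_base
    bfac = _cycle_factors(rng, config.blood_cv, rho)
    btau2 = min(bt2 * _lognorm_factor(rng, 0.15), _TEFF_CAP_H / LN2)
    blood = tuple(
        BiexpParams(b1 * config.blood_cycle_mult[c] * bfac[c],
                    b2 * config.blood_cycle_mult[c] * bfac[c], bt1, btau2)
        for c in range(4))

    wa1, wa2, wt1, wt2 = config.wb_base
    wfac = _cycle_factors(rng, config.wb_cv, rho)
    wtau1 = min(max(wt1 * _lognorm_factor(rng, 0.20), 0.2), 10.0)
    wb = []
    for c in range(4):
        tau2 = float(np.clip(wt2 * config.wb_t2_cycle_mult[c] * wfac[c],
                             20.0, _TEFF_CAP_H / LN2))
        wb.append(BiexpParams(wa1, wa2, wtau1, tau2))

    return PatientTruth(pid, gender, weight, burden, volumes, organs,
                        tuple(tumors), blood, tuple(wb), acts, late,
                        blood_missing)


def simulate_series(truth: PatientTruth, kind: str, region: str, cycle: int,
                    config: CohortConfig) -> MeasurementSeries:
    """Emit one noisy measurement series from a patient's ground truth.

    Values are the model curve at jittered sample times multiplied by
    mean-one lognormal noise of coefficient of variation ``noise_cv``;
    the 90/120 h outpatient point is the patient's fixed late time.
    """
    config.validate()
    if cycle not in CYCLES:
        raise ValueError(f"unknown cycle {cycle}")
    if kind == "voi":
        schedule = config.schedule_voi
    elif kind == "blood":
        schedule = config.schedule_blood
    elif kind == "wb":
        schedule = config.schedule_wb
    else:
        raise ValueError(f"unknown series kind {kind!r}")
    if any(t <= 0 for t in schedule):
        raise ValueError("schedule times must be > 0")

    rng = _series_rng(config, truth.patient_id, kind, region, cycle)
    jit = config.time_jitter_h
    times = np.asarray(
        [max(0.05, t + rng.uniform(-jit, jit)) for t in schedule]
        + [truth.late_time_h])
    times = np.sort(times)

    a_mbq = truth.activities_gbq[cycle - 1] * 1000.0
    volume = None
    if kind == "voi":
        if region in truth.organs:
            fia = truth.organs[region].fia(times, cycle)
            volume = truth.organ_volumes[region]
        else:
            match = [t for t in truth.tumors if t.tumor_id == region]
            if not match:
                raise ValueError(f"unknown region {region!r} for patient "
                                 f"{truth.patient_id}")
            fia = match[0].kinetics.fia(times, cycle)
            volume = match[0].volume_ml
        values, unit = fia * a_mbq / volume, "MBq/mL"
    elif kind == "blood":
        if region != "blood":
            raise ValueError("blood series use region 'blood'")
        if truth.blood_missing:
            raise ValueError(f"no blood samples for patient {truth.patient_id}")
        values, unit = truth.blood[cycle - 1].curve(times) * a_mbq, "MBq/mL"
    else:
        if region != "whole_body":
            raise ValueError("wb series use region 'whole_body'")
        values, unit = truth.wb[cycle - 1].curve(times), "FIA"

    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
        values = values * np.exp(sigma * rng.standard_normal(values.size)
                                 - 0.5 * sigma * sigma)
    return MeasurementSeries(truth.patient_id, cycle, kind, region,
                             times, values, volume_ml=volume, unit=unit)


def generate_cohort(config: CohortConfig | None = None
                    ) -> tuple[list[PatientTruth], list[MeasurementSeries]]:
    """Generate the virtual cohort: ground truths plus measurement series.

    Deterministic given ``config.rng_seed``; blood series are withheld for
    ``n_missing_blood`` randomly chosen patients (emulating samples never
    collected), with the flag recorded on the truth object.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed & 0x7FFFFFFF, 0]))
    n_missing = min(config.n_missing_blood, config.n_patients)
    missing = set(rng.choice(config.n_patients, size=n_missing, replace=False)
                  .tolist()) if n_missing else set()

    truths, series = [], []
    for i in range(config.n_patients):
        truth = _draw_patient(config, i, blood_missing=i in missing)
        truths.append(truth)
        for cycle in CYCLES:
            for region in OAR_REGIONS:
                series.append(simulate_series(truth, "voi", region, cycle, config))
            for tum in truth.tumors:
                series.append(simulate_series(truth, "voi", tum.tumor_id,
                                              cycle, config))
            if not truth.blood_missing:
                series.append(simulate_series(truth, "blood", "blood", cycle,
                                              config))
            series.append(simulate_series(truth, "wb", "whole_body", cycle,
                                          config))
    return truths, series


def truth_to_dict(truth: PatientTruth) -> dict:
    """JSON-serialisable view of a patient's ground truth."""
    d = asdict(truth)
    d["organ_volumes"] = dict(truth.organ_volumes)
    return d
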