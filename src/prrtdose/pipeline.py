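"""End-to-end pipeline: simulate -> fit & dose -> protocol comparison.

File formats: measurement series travel as tidy CSV (patient_id, cycle,
kind, region, volume_ml, time_h, value, unit), administered activities as a
companion CSV (patient_id, cycle, activity_gbq), cohort ground truth and
reports as JSON, per-cycle doses and the protocol comparison as tidy CSV.
Every output directory records the seed and a hash of the configuration so
runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import agreement as agr
from . import protocols as proto
from .biokinetics import (MeasurementSeries, RetentionFit, compute_tiac,
                          fit_series)
from .cohort import (CYCLES, OAR_REGIONS, CohortConfig, PatientTruth,
                     generate_cohort, truth_to_dict)
from .constants import LN2
from .dose import (CycleDose, DoseFactorTable, kidney_bed, organ_dose,
                   red_marrow_dose, tumor_sphere_dose)

__all__ = [
    "MEASUREMENT_COLUMNS",
    "config_hash",
    "measurements_to_frame",
    "frame_to_measurements",
    "run_simulate",
    "read_measurements",
    "read_administrations",
    "compute_cycle_doses",
    "analytic_cycle_doses",
    "run_dose",
    "protocol_table",
    "run_compare",
]

log = logging.getLogger("prrtdose")

MEASUREMENT_COLUMNS = ("patient_id", "cycle", "kind", "region", "volume_ml",
                       "time_h", "value", "unit")
DISPLAY_REGIONS = ("kidney", "spleen", "liver", "red_marrow", "tumor")


def config_hash(config) -> str:
    """Stable sha256 of a (dataclass or mapping) configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        payload = dataclasses.asdict(config)
    else:
        payload = dict(config)
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:16]


# ---------------------------------------------------------------------------
# measurement I/O

def measurements_to_frame(series: Iterable[MeasurementSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for t, v in zip(s.times_h, s.values):
            rows.append((s.patient_id, s.cycle, s.kind, s.region,
                         s.volume_ml if s.volume_ml is not None else np.nan,
                         t, v, s.unit))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def frame_to_measurements(df: pd.DataFrame) -> list[MeasurementSeries]:
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")
    out = []
    for (pid, cyc, kind, region), grp in df.groupby(
            ["patient_id", "cycle", "kind", "region"], sort=True):
        grp = grp.sort_values("time_h")
        vol = grp["volume_ml"].iloc[0]
        try:
            out.append(MeasurementSeries(
                str(pid), int(cyc), str(kind), str(region),
                grp["time_h"].to_numpy(float), grp["value"].to_numpy(float),
                volume_ml=None if pd.isna(vol) else float(vol),
                unit=str(grp["unit"].iloc[0])))
        except (ValueError, TypeError) as exc:
            lines = ", ".join(str(i + 2) for i in grp.index[:5])  # 1-based + header
            raise ValueError(
                f"malformed measurement rows (csv lines {lines}) for "
                f"patient={pid} cycle={cyc} kind={kind} region={region}: {exc}"
            ) from exc
    return out


def read_measurements(path) -> list[MeasurementSeries]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"no measurement rows in {path}")
    return frame_to_measurements(df)


def read_administrations(path) -> dict[tuple[str, int], float]:
    df = pd.read_csv(path)
    return {(str(r.patient_id), int(r.cycle)): float(r.activity_gbq)
            for r in df.itertuples()}


def run_simulate(config: CohortConfig, outdir) -> dict:
    """Generate a cohort and write truth JSON + measurement/administration CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths, series = generate_cohort(config)
    meta = {"rng_seed": config.rng_seed, "config_hash": config_hash(config),
            "n_patients": config.n_patients}
    log.info("simulate: seed=%s hash=%s", config.rng_seed, meta["config_hash"])

    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump({"meta": meta,
                   "patients": [truth_to_dict(t) for t in truths]},
                  fh, indent=1, sort_keys=True)
    measurements_to_frame(series).to_csv(outdir / "measurements.csv",
                                         index=False)
    admin = pd.DataFrame(
        [(t.patient_id, c, t.activities_gbq[c - 1])
         for t in truths for c in CYCLES],
        columns=["patient_id", "cycle", "activity_gbq"])
    admin.to_csv(outdir / "administrations.csv", index=False)
    with open(outdir / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return meta


# ---------------------------------------------------------------------------
# fitting + dose

def _fit_to_record(key, fit: RetentionFit) -> dict:
    pid, cycle, kind, region = key
    return {"patient_id": pid, "cycle": cycle, "kind": kind, "region": region,
            "model": fit.model, "amplitudes": list(fit.amplitudes),
            "time_constants_h": list(fit.time_constants),
            "effective_half_lives_h": ([tc * LN2 for tc in fit.time_constants]),
            "tiac": compute_tiac(fit), "r_squared": fit.r_squared,
            "flags": list(fit.flags)}


def compute_cycle_doses(series: Sequence[MeasurementSeries],
                        activities: Mapping[tuple[str, int], float],
                        factors: DoseFactorTable | None = None,
                        r2_threshold: float = 0.95,
                        ) -> tuple[pd.DataFrame, dict]:
    """Fit every series and convert TIACs to per-cycle doses.

    Returns a tidy dose table (one row per patient, cycle and region —
    tumour lesions keep their own region labels, red marrow is derived from
    the blood and whole-body series) and the fit records keyed by
    (patient, cycle, kind, region).
    """
    factors = factors or DoseFactorTable()
    fits: dict[tuple, RetentionFit] = {}
    for s in series:
        fits[(s.patient_id, s.cycle, s.kind, s.region)] = fit_series(
            s, r2_threshold=r2_threshold)

    rows = []
    keys = sorted({(s.patient_id, s.cycle) for s in series})
    by_pc: dict[tuple, list[MeasurementSeries]] = {}
    for s in series:
        by_pc.setdefault((s.patient_id, s.cycle), []).append(s)

    for pid, cycle in keys:
        if (pid, cycle) not in activities:
            raise ValueError(f"no administered activity for patient {pid} "
                             f"cycle {cycle}")
        a_gbq = activities[(pid, cycle)]
        blood_fit = fits.get((pid, cycle, "blood", "blood"))
        wb_fit = fits.get((pid, cycle, "wb", "whole_body"))
        for s in sorted(by_pc[(pid, cycle)], key=lambda s: (s.kind, s.region)):
            if s.kind != "voi":
                continue
            fit = fits[(s.patient_id, s.cycle, s.kind, s.region)]
            conc_tiac = compute_tiac(fit)          # h * MBq/mL
            fia_tiac = conc_tiac * s.volume_ml / (a_gbq * 1000.0)
            teff = (fit.time_constants[0] * LN2 if fit.model == "monoexp"
                    else None)
            if s.region in OAR_REGIONS:
                mass = s.volume_ml * factors.density_g_per_ml
                dose = organ_dose(fia_tiac, mass, factors, a_gbq,
                                  region=s.region, cycle=cycle, teff_h=teff)
                kind_out = "organ"
            else:
                dose = tumor_sphere_dose(fia_tiac, s.volume_ml, factors,
                                         a_gbq, region=s.region, cycle=cycle)
                kind_out = "tumor"
            rows.append({
                "patient_id": pid, "cycle": cycle, "region": s.region,
                "region_kind": kind_out,
                "ad_per_activity_gy_per_gbq": dose.ad_per_activity_gy_per_gbq,
                "ad_gy": dose.ad_gy, "activity_gbq": a_gbq,
                "self_mgy_per_gbq": np.nan, "cross_mgy_per_gbq": np.nan,
                "teff_h": teff if teff is not None else np.nan,
                "model": fit.model, "flags": ";".join(fit.flags),
                "blood_missing": False})
        if wb_fit is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rm = red_marrow_dose(blood_fit, wb_fit, factors, a_gbq,
                                     cycle=cycle)
            rows.append({
                "patient_id": pid, "cycle": cycle, "region": "red_marrow",
                "region_kind": "red_marrow",
                "ad_per_activity_gy_per_gbq": rm.ad_per_activity_gy_per_gbq,
                "ad_gy": rm.ad_gy, "activity_gbq": a_gbq,
                "self_mgy_per_gbq": (np.nan if rm.self_mgy_per_gbq is None
                                     else rm.self_mgy_per_gbq),
                "cross_mgy_per_gbq": rm.cross_mgy_per_gbq,
                "teff_h": np.nan, "model": "biexp",
                "flags": ";".join(rm.flags),
                "blood_missing": blood_fit is None})
    records = {k: _fit_to_record(k, f) for k, f in fits.items()}
    return pd.DataFrame(rows), records


def analytic_cycle_doses(truth: PatientTruth,
                         factors: DoseFactorTable | None = None
                         ) -> pd.DataFrame:
    """Noise-free per-cycle doses straight from a patient's ground truth.

    The oracle counterpart of :func:`compute_cycle_doses` for recovery and
    protocol studies: identical dose formulas, analytic TIACs.
    """
    factors = factors or DoseFactorTable()
    rows = []
    for cycle in CYCLES:
        a_gbq = truth.activities_gbq[cycle - 1]
        for region, kin in truth.organs.items():
            mass = truth.organ_volumes[region] * factors.density_g_per_ml
            d = organ_dose(kin.tiac_h(cycle), mass, factors, a_gbq,
                           region=region, cycle=cycle)
            rows.append((truth.patient_id, cycle, region, "organ",
                         d.ad_per_activity_gy_per_gbq, d.ad_gy, a_gbq,
                         kin.teff_h[cycle - 1], truth.blood_missing))
        for tum in truth.tumors:
            d = tumor_sphere_dose(tum.kinetics.tiac_h(cycle), tum.volume_ml,
                                  factors, a_gbq, region=tum.tumor_id,
                                  cycle=cycle)
            rows.append((truth.patient_id, cycle, tum.tumor_id, "tumor",
                         d.ad_per_activity_gy_per_gbq, d.ad_gy, a_gbq,
                         np.nan, truth.blood_missing))
        cross = truth.wb_tiac(cycle) * factors.wb_to_rm_cross_gy_per_gbq_h
        if truth.blood_missing:
            total = cross
        else:
            self_c = (truth.blood_conc_tiac(cycle) * factors.rm_blood_ratio
                      * factors.red_marrow_mass_g / factors.density_g_per_ml
                      * 1000.0 * factors.k_gy_g_per_mbq_h("red_marrow")
                      / factors.red_marrow_mass_g)
            total = self_c + cross
        rows.append((truth.patient_id, cycle, "red_marrow", "red_marrow",
                     total, total * a_gbq, a_gbq, np.nan,
                     truth.blood_missing))
    return pd.DataFrame(rows, columns=[
        "patient_id", "cycle", "region", "region_kind",
        "ad_per_activity_gy_per_gbq", "ad_gy", "activity_gbq", "teff_h",
        "blood_missing"])


def run_dose(measurements_path, administrations_path, outdir,
             factors: DoseFactorTable | None = None,
             r2_threshold: float = 0.95) -> pd.DataFrame:
    """Fit a measurement CSV and write fits.json + doses.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series = read_measurements(measurements_path)
    activities = read_administrations(administrations_path)
    doses, fit_records = compute_cycle_doses(series, activities, factors,
                                             r2_threshold)
    doses.to_csv(outdir / "doses.csv", index=False)
    with open(outdir / "fits.json", "w", encoding="utf-8") as fh:
        json.dump(sorted(fit_records.values(),
                         key=lambda r: (r["patient_id"], r["cycle"],
                                        r["kind"], r["region"])),
                  fh, indent=1)
    n_trap = sum(1 for r in fit_records.values()
                 if r["model"] == "trapezoid_tail")
    if n_trap:
        log.warning("trapezoid fallback used for %d series", n_trap)
    return doses


# ---------------------------------------------------------------------------
# protocol assembly + comparison

def protocol_table(doses: pd.DataFrame) -> pd.DataFrame:
    """Per patient and region, cumulative doses under M0, M1 and M2."""
    rows = []
    for (pid, region), grp in doses.groupby(["patient_id", "region"],
                                            sort=True):
        grp = grp.sort_values("cycle")
        if list(grp["cycle"]) != list(CYCLES):
            missing = sorted(set(CYCLES) - set(grp["cycle"]))
            raise ValueError(f"patient {pid} region {region} missing "
                             f"cycle(s) {missing}")
        ads = grp["ad_gy"].to_numpy(float)
        acts = grp["activity_gbq"].to_numpy(float)
        cds = [CycleDose(region, int(c), float(ad / a), float(a), float(ad))
               for c, ad, a in zip(grp["cycle"], ads, acts)]
        m0 = proto.cumulative_m0(cds)
        m1 = proto.extrapolate_m1(ads[0], acts, region=region)
        m2 = proto.extrapolate_m2(ads[0], ads[3], acts, region=region)
        kind = grp["region_kind"].iloc[0]
        bm = bool(grp["blood_missing"].iloc[0]) if "blood_missing" in grp else False
        for p in (m0, m1, m2):
            for cyc, ad, prov in zip(CYCLES, p.ad_gy, p.provenance):
                rows.append((pid, region, kind, p.method, cyc, ad, prov, bm))
    return pd.DataFrame(rows, columns=[
        "patient_id", "region", "region_kind", "method", "cycle", "ad_gy",
        "provenance", "blood_missing"])


def _cad_matrix(protocols: pd.DataFrame, display_region: str) -> pd.DataFrame:
    """Wide table of cADs (rows = patient or lesion, cols = M0/M1/M2)."""
    if display_region == "tumor":
        sub = protocols[protocols.region_kind == "tumor"]
    else:
        sub = protocols[protocols.region == display_region]
        if display_region == "red_marrow":
            sub = sub[~sub.blood_missing]
    if sub.empty:
        return pd.DataFrame()
    cad = (sub.groupby(["patient_id", "region", "method"])["ad_gy"].sum()
           .unstack("method"))
    return cad.dropna()


def run_compare(doses: pd.DataFrame | str, outdir=None, alpha: float = 0.05,
                limits: proto.SafetyLimits | None = None,
                bed_alpha_beta_gy: float = 2.6, bed_t_rep_h: float = 2.8,
                bed_limit_gy: float = 28.0) -> dict:
    """Compare M1 and M2 with the per-cycle reference M0.

    Produces the per-region comparison table (mean +/- SD cumulative dose
    per method, per-patient percent differences, Wilcoxon p, Bland–Altman
    limits with CI, out-of-bound percentage), per-patient safety flags, the
    kidney BED with extra-cycle eligibility counts, and Bland–Altman plot
    data.  Red-marrow comparisons exclude patients without blood samples.
    """
    if isinstance(doses, (str, Path)):
        doses = pd.read_csv(doses)
    if doses.empty:
        raise ValueError("empty dose table")
    protocols = protocol_table(doses)
    limits = limits or proto.SafetyLimits()

    table_rows, plot_rows = [], []
    comparison: dict = {}
    for region in DISPLAY_REGIONS:
        cad = _cad_matrix(protocols, region)
        if cad.empty or len(cad) < 2:
            continue
        m0 = cad["M0"].to_numpy()
        entry = {"n": int(len(cad)),
                 "cad_m0_gy": {"mean": float(m0.mean()),
                               "sd": float(m0.std(ddof=1))}}
        for method in ("M1", "M2"):
            mx = cad[method].to_numpy()
            diffs = mx - m0
            res = agr.bland_altman(diffs, alpha=alpha, region=region,
                                   pair=f"{method}_vs_M0")
            # differences at float resolution are ties, not signal
            tol = 1e-9 * max(1.0, float(np.abs(m0).max()))
            mx_eff = np.where(np.abs(diffs) < tol, m0, mx)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res.wilcoxon_p = agr.wilcoxon_signed_rank(mx_eff, m0)
                except ValueError:
                    res.wilcoxon_p = None
            res.mean_pct_diff, res.sd_pct_diff = (
                agr.summarize_percent_differences(mx, m0))
            entry[method] = {
                "cad_gy": {"mean": float(mx.mean()),
                           "sd": float(mx.std(ddof=1))},
                "mean_diff_gy": res.mu_delta, "sd_diff_gy": res.sigma_delta,
                "loa_gy": [res.loa_low, res.loa_high],
                "ci_gy": [res.ci_low, res.ci_high],
                "pct_out_of_bounds": res.pct_out_of_bounds,
                "wilcoxon_p": res.wilcoxon_p,
                "pct_diff": {"mean": res.mean_pct_diff,
                             "sd": res.sd_pct_diff}}
            table_rows.append((region, f"{method}_vs_M0", res.n,
                               float(m0.mean()), float(mx.mean()),
                               res.mean_pct_diff, res.sd_pct_diff,
                               res.wilcoxon_p, res.mu_delta, res.sigma_delta,
                               res.loa_low, res.loa_high, res.ci_low,
                               res.ci_high, res.pct_out_of_bounds))
            for (pid, reg), mxv, m0v in zip(cad.index, mx, m0):
                plot_rows.append((region, f"{method}_vs_M0", pid, reg,
                                  0.5 * (mxv + m0v), mxv - m0v,
                                  res.loa_low, res.loa_high))
        comparison[region] = entry

    # per-patient kidney safety, BED and extra-cycle eligibility
    safety_rows = []
    eligibility: dict[int, int] = {}
    kidney = doses[doses.region == "kidney"].sort_values(["patient_id",
                                                          "cycle"])
    rm_prot = protocols[(protocols.region == "red_marrow")
                        & (protocols.method == "M0")]
    for pid, grp in kidney.groupby("patient_id"):
        if list(grp["cycle"]) != list(CYCLES):
            continue
        teffs = grp["teff_h"].to_numpy(float)
        teffs = np.where(np.isnan(teffs), 60.0, teffs)  # trapezoid fallback
        bed = kidney_bed(list(zip(grp["ad_gy"], teffs)),
                         alpha_beta_gy=bed_alpha_beta_gy,
                         t_rep_h=bed_t_rep_h)
        n_extra = proto.extra_cycle_eligibility(bed, limit_gy=bed_limit_gy)
        eligibility[n_extra] = eligibility.get(n_extra, 0) + 1
        cad_k = float(grp["ad_gy"].sum())
        rm_cad = float(rm_prot[rm_prot.patient_id == pid]["ad_gy"].sum())
        safety_rows.append((pid, cad_k, cad_k >= limits.kidney_cad_gy,
                            bed.total_bed_gy,
                            bed.total_bed_gy >= limits.kidney_bed_risk_gy,
                            bed.total_bed_gy >= limits.kidney_bed_norisk_gy,
                            rm_cad, rm_cad >= limits.red_marrow_cad_gy,
                            n_extra))
    safety = pd.DataFrame(safety_rows, columns=[
        "patient_id", "kidney_cad_gy", "kidney_cad_exceeds_23gy",
        "kidney_bed_gy", "kidney_bed_exceeds_28gy",
        "kidney_bed_exceeds_40gy", "red_marrow_cad_gy",
        "red_marrow_cad_exceeds_2gy", "n_extra_cycles"])

    table5 = pd.DataFrame(table_rows, columns=[
        "region", "pair", "n", "cad_m0_mean_gy", "cad_mx_mean_gy",
        "mean_pct_diff", "sd_pct_diff", "wilcoxon_p", "mean_diff_gy",
        "sd_diff_gy", "loa_low_gy", "loa_high_gy", "ci_low_gy", "ci_high_gy",
        "pct_out_of_bounds"])
    plot_df = pd.DataFrame(plot_rows, columns=[
        "region", "pair", "patient_id", "source_region", "mean_gy",
        "diff_gy", "loa_low_gy", "loa_high_gy"])

    report = {"alpha": alpha, "comparison": comparison,
              "bed": {"alpha_beta_gy": bed_alpha_beta_gy,
                      "t_rep_h": bed_t_rep_h, "limit_gy": bed_limit_gy,
                      "mean_total_bed_gy": (float(safety["kidney_bed_gy"]
                                                  .mean())
                                            if len(safety) else None)},
              "extra_cycle_counts": {str(k): v for k, v
                                     in sorted(eligibility.items())},
              "safety": {
                  "kidney_cad_over_23gy": int(safety["kidney_cad_exceeds_23gy"]
                                              .sum()) if len(safety) else 0,
                  "red_marrow_cad_over_2gy": int(
                      safety["red_marrow_cad_exceeds_2gy"].sum())
                  if len(safety) else 0}}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table5.to_csv(outdir / "comparison.csv", index=False)
        plot_df.to_csv(outdir / "bland_altman_points.csv", index=False)
        safety.to_csv(outdir / "safety.csv", index=False)
        protocols.to_csv(outdir / "protocol_doses.csv", index=False)
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
    report["table"] = table5
    report["plot_data"] = plot_df
    report["safety_table"] = safety
    return report
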