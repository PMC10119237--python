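"""Cumulative doses under the full and simplified dosimetry protocols.

The reference protocol M0 sums the four measured per-cycle absorbed doses.
The simplified protocols extrapolate unmeasured cycles by scaling a measured
anchor dose with the ratio of administered activities,
``AD_x = AD_anchor * A_x / A_anchor``:

* M1 anchors every later cycle on cycle 1;
* M2 anchors cycle 2 on cycle 1 and cycle 3 on cycle 4, with cycles 1 and 4
  measured.

Also here: cycle-contribution fractions, safety-limit checks (kidney 23 Gy
absorbed, kidney BED 28/40 Gy with/without risk factors, red marrow 2 Gy)
and the extra-cycle eligibility count derived from the kidney BED headroom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .dose import BEDResult, CycleDose

__all__ = [
    "ProtocolDose",
    "SafetyLimits",
    "cumulative_m0",
    "extrapolate_m1",
    "extrapolate_m2",
    "cycle_contribution_fractions",
    "safety_check",
    "extra_cycle_eligibility",
]

_CYCLES = (1, 2, 3, 4)


@dataclass(frozen=True)
class ProtocolDose:
    """Cumulative absorbed dose for one region under one protocol."""

    region: str
    method: str  # "M0" | "M1" | "M2"
    ad_gy: tuple[float, float, float, float]
    activities_gbq: tuple[float, float, float, float]
    provenance: tuple[str, str, str, str]  # "measured" | "extrapolated"

    def __post_init__(self) -> None:
        if self.method not in ("M0", "M1", "M2"):
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.ad_gy) != 4 or len(self.activities_gbq) != 4:
            raise ValueError("exactly four cycles are required")
        if self.method == "M0" and any(p != "measured" for p in self.provenance):
            raise ValueError("M0 must be fully measured")

    @property
    def cad_gy(self) -> float:
        """Cumulative absorbed dose over the four cycles."""
        return float(sum(self.ad_gy))


def _check_activities(activities: Sequence[float]) -> tuple[float, ...]:
    acts = tuple(float(a) for a in activities)
    if len(acts) != 4:
        raise ValueError("four per-cycle activities are required")
    return acts


def cumulative_m0(cycle_doses: Sequence[CycleDose]) -> ProtocolDose:
    """Reference protocol: sum of the four measured per-cycle doses."""
    by_cycle = {d.cycle: d for d in cycle_doses}
    missing = [c for c in _CYCLES if c not in by_cycle]
    if missing:
        raise ValueError(f"missing measured cycle(s): {missing}")
    regions = {d.region for d in cycle_doses}
    if len(regions) != 1:
        raise ValueError(f"cycle doses mix regions: {sorted(regions)}")
    return ProtocolDose(
        regions.pop(), "M0",
        tuple(by_cycle[c].ad_gy for c in _CYCLES),
        tuple(by_cycle[c].administered_gbq for c in _CYCLES),
        ("measured",) * 4)


def extrapolate_m1(ad1_gy: float, activities_gbq: Sequence[float],
                   region: str = "") -> ProtocolDose:
    """Single-cycle protocol: cycles 2-4 scaled from cycle 1 by activity."""
    acts = _check_activities(activities_gbq)
    if acts[0] <= 0:
        raise ValueError("first-cycle activity must be > 0")
    ads = (ad1_gy,) + tuple(ad1_gy * a / acts[0] for a in acts[1:])
    return ProtocolDose(region, "M1", ads, acts,
                        ("measured",) + ("extrapolated",) * 3)


def extrapolate_m2(ad1_gy: float, ad4_gy: float,
                   activities_gbq: Sequence[float],
                   region: str = "") -> ProtocolDose:
    """Two-anchor protocol: cycle 2 from cycle 1, cycle 3 from cycle 4."""
    acts = _check_activities(activities_gbq)
    if acts[0] <= 0 or acts[3] <= 0:
        raise ValueError("anchor-cycle activities must be > 0")
    ad2 = ad1_gy * acts[1] / acts[0]
    ad3 = ad4_gy * acts[2] / acts[3]
    return ProtocolDose(region, "M2", (ad1_gy, ad2, ad3, ad4_gy), acts,
                        ("measured", "extrapolated", "extrapolated",
                         "measured"))


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def cycle_contribution_fractions(protocol: ProtocolDose) -> tuple[int, ...]:
    """Per-cycle share of the cumulative dose, in whole percent
    (half away from zero); fractions sum to 100 up to rounding."""
    cad = protocol.cad_gy
    if cad <= 0:
        raise ValueError("cumulative dose must be > 0")
    return tuple(_round_half_away(ad / cad * 100.0) for ad in protocol.ad_gy)


@dataclass(frozen=True)
class SafetyLimits:
    """Published dose limits for the organs at risk."""

    kidney_cad_gy: float = 23.0
    kidney_bed_risk_gy: float = 28.0
    kidney_bed_norisk_gy: float = 40.0
    red_marrow_cad_gy: float = 2.0


def safety_check(region_protocols: Mapping[str, ProtocolDose],
                 bed: BEDResult | None = None,
                 limits: SafetyLimits | None = None) -> dict:
    """Flag each safety limit; a value at the limit counts as a breach
    (conservative >= comparison)."""
    limits = limits or SafetyLimits()
    report: dict = {"limits": {
        "kidney_cad_gy": limits.kidney_cad_gy,
        "kidney_bed_risk_gy": limits.kidney_bed_risk_gy,
        "kidney_bed_norisk_gy": limits.kidney_bed_norisk_gy,
        "red_marrow_cad_gy": limits.red_marrow_cad_gy,
    }}
    if "kidney" in region_protocols:
        cad = region_protocols["kidney"].cad_gy
        report["kidney_cad_gy"] = cad
        report["kidney_cad_exceeds_23gy"] = cad >= limits.kidney_cad_gy
    if bed is not None:
        report["kidney_bed_gy"] = bed.total_bed_gy
        report["kidney_bed_exceeds_28gy"] = (bed.total_bed_gy
                                             >= limits.kidney_bed_risk_gy)
        report["kidney_bed_exceeds_40gy"] = (bed.total_bed_gy
                                             >= limits.kidney_bed_norisk_gy)
    if "red_marrow" in region_protocols:
        cad = region_protocols["red_marrow"].cad_gy
        report["red_marrow_cad_gy"] = cad
        report["red_marrow_cad_exceeds_2gy"] = cad >= limits.red_marrow_cad_gy
    return report


def extra_cycle_eligibility(bed: BEDResult, limit_gy: float = 28.0,
                            max_extra: int = 4,
                            basis: str = "cycle4") -> int:
    """How many extra cycles fit under the kidney BED limit.

    Future cycles are projected to repeat the cycle-4 (default) or the
    mean per-cycle BED; the count is the largest ``n <= max_extra`` with
    ``total_BED + n * BED_projected <= limit``.
    """
    if basis == "cycle4":
        per_cycle = bed.per_cycle_bed_gy[-1]
    elif basis == "mean":
        per_cycle = sum(bed.per_cycle_bed_gy) / len(bed.per_cycle_bed_gy)
    else:
        raise ValueError("basis must be 'cycle4' or 'mean'")
    n = 0
    for k in range(1, max_extra + 1):
        if bed.total_bed_gy + k * per_cycle <= limit_gy:
            n = k
        else:
            break
    if per_cycle == 0 and bed.total_bed_gy <= limit_gy:
        return max_extra
    return n
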