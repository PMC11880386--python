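"""Preclinical tumor-growth analytics.

Caliper measurements (long axis a, short axis b, mm) give the ellipsoid
volume V = a * b^2 * pi/6 (mm^3). Animals are allocated to treatment arms
by serpentine ("S-curve") assignment of size-ranked tumors so arm baseline
means match. Treatment effect is summarized as tumor growth inhibition
(TGI, %) and per-mouse responder calls (stable or shrinking volume).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "CaliperMeasurement",
    "GrowthCurve",
    "TGIResult",
    "tumor_volume",
    "s_curve_allocate",
    "compute_tgi",
    "classify_mouse_response",
    "response_rate",
]


@dataclass(frozen=True)
class CaliperMeasurement:
    mouse_id: str
    day: int
    long_axis: float  # mm
    short_axis: float  # mm

    def __post_init__(self) -> None:
        if not (self.long_axis >= self.short_axis >= 0):
            raise ValueError(
                f"axes must satisfy long >= short >= 0, got "
                f"({self.long_axis}, {self.short_axis}); are they swapped?"
            )

    @property
    def volume(self) -> float:
        return tumor_volume(self.long_axis, self.short_axis)


@dataclass
class GrowthCurve:
    """One mouse's (day, volume mm^3) series, days strictly increasing."""

    mouse_id: str
    arm: str
    days: tuple[int, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.volumes):
            raise ValueError("days and volumes must have equal length")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(v < 0 for v in self.volumes):
            raise ValueError("volumes must be >= 0")

    def volume_at(self, day: int) -> float:
        try:
            return self.volumes[self.days.index(day)]
        except ValueError:
            raise KeyError(
                f"mouse {self.mouse_id!r} has no measurement on day {day}; "
                f"measured days: {list(self.days)} (no interpolation is performed)"
            ) from None

    @property
    def baseline_day(self) -> int:
        return self.days[0]


@dataclass(frozen=True)
class TGIResult:
    tgi_percent: float
    control_arm: str
    treated_arm: str
    evaluation_day: int
    formula_variant: Literal["endpoint_ratio", "delta_ratio"]


def tumor_volume(long_axis: float, short_axis: float) -> float:
    """Ellipsoid volume a*b^2*pi/6 (mm^3) from caliper axes in mm."""
    if not (long_axis >= short_axis >= 0):
        raise ValueError(
            f"axes must satisfy long >= short >= 0, got ({long_axis}, {short_axis}); "
            "are they swapped?"
        )
    return long_axis * short_axis**2 * math.pi / 6.0


def s_curve_allocate(
    baseline_volumes: dict[str, float],
    n_groups: int,
    seed: int = 0,
) -> dict[str, int]:
    """Serpentine assignment of size-ranked animals to ``n_groups`` arms.

    Animals are sorted by baseline volume descending (ties broken by a
    seeded shuffle applied before sorting) and dealt out in snake order
    1..k, k..1, 1..k, ... so every arm receives animals from every size
    stratum and arm sizes differ by at most one.

    Returns a map mouse_id -> group index (0-based).
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    mice = list(baseline_volumes)
    if n_groups > len(mice):
        raise ValueError(f"n_groups={n_groups} exceeds number of mice ({len(mice)})")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(mice)))  # tie-break shuffle
    shuffled = [mice[i] for i in order]
    ranked = sorted(shuffled, key=lambda m: -baseline_volumes[m])  # stable

    pattern: list[int] = []
    forward = True
    while len(pattern) < len(mice):
        block = range(n_groups) if forward else range(n_groups - 1, -1, -1)
        pattern.extend(block)
        forward = not forward
    return {m: g for m, g in zip(ranked, pattern)}


def _arm_mean(curves: Sequence[GrowthCurve], day: int) -> float:
    return float(np.mean([c.volume_at(day) for c in curves]))


def compute_tgi(
    control: Sequence[GrowthCurve],
    treated: Sequence[GrowthCurve],
    day: int,
    variant: Literal["endpoint_ratio", "delta_ratio"] = "delta_ratio",
) -> TGIResult:
    """Tumor growth inhibition of the treated arm versus control at ``day``.

    endpoint_ratio: TGI% = (1 - Vt(day)/Vc(day)) * 100, using arm-mean
    volumes. delta_ratio (default): the same ratio of baseline-subtracted
    growth, (1 - (Vt(day)-Vt(t0)) / (Vc(day)-Vc(t0))) * 100, where t0 is
    each curve's first measured day. Days absent from any curve raise;
    no interpolation is performed.

    Regression below baseline is reported as full 100% inhibition so both
    variants share the same <= 100% scale; negative values (treated arm
    outgrowing control) are kept as-is.
    """
    if not control or not treated:
        raise ValueError("both arms must contain at least one growth curve")
    if variant not in ("endpoint_ratio", "delta_ratio"):
        raise ValueError(f"unknown TGI variant {variant!r}")
    vc = _arm_mean(control, day)
    vt = _arm_mean(treated, day)
    if variant == "endpoint_ratio":
        if vc <= 0:
            raise ValueError("mean control volume must be > 0 at the evaluation day")
        tgi = (1.0 - vt / vc) * 100.0
    else:
        vc0 = float(np.mean([c.volumes[0] for c in control]))
        vt0 = float(np.mean([c.volumes[0] for c in treated]))
        dc = vc - vc0
        if dc <= 0:
            raise ValueError("mean control growth (delta) must be > 0 for delta_ratio")
        tgi = (1.0 - (vt - vt0) / dc) * 100.0
    return TGIResult(
        tgi_percent=min(tgi, 100.0),
        control_arm=control[0].arm,
        treated_arm=treated[0].arm,
        evaluation_day=day,
        formula_variant=variant,
    )


def classify_mouse_response(
    curve: GrowthCurve,
    baseline_day: int | None = None,
    final_day: int | None = None,
    stability_tolerance: float = 0.20,
) -> bool:
    """Responder call: final volume stable or reduced relative to baseline.

    A mouse responds when V(final) <= V(baseline) * (1 + stability_tolerance);
    the tolerance (default 20%) defines how much growth still counts as
    "stable". Defaults evaluate the first against the last measured day.
    """
    if baseline_day is None:
        baseline_day = curve.days[0]
    if final_day is None:
        final_day = curve.days[-1]
    v0 = curve.volume_at(baseline_day)
    v1 = curve.volume_at(final_day)
    return v1 <= v0 * (1.0 + stability_tolerance)


def response_rate(flags: Iterable[bool]) -> float:
    """Percent responders among an arm's responder flags."""
    flags = list(flags)
    if not flags:
        raise ValueError("response_rate requires a non-empty arm")
    return 100.0 * sum(bool(f) for f in flags) / len(flags)
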