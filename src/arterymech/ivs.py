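"""In-vivo axial stretch (IVS) estimation and axial-force quality control.

An artery's transducer force at its in-vivo axial length is nearly
insensitive to lumen pressure, so force-stretch curves recorded at several
constant pressures cross close to a common point.  The protocol defines
the IVS as that intersection; this module computes it as the arithmetic
mean of all defined pairwise crossings of piecewise-linearly interpolated
curves, keeping the crossing scatter as a diagnostic.

Validity is checked on the pressure sweep recorded at the IVS: if the
axial force deviates from its across-pressure mean by more than 25%
(default threshold), the sample is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import ForceLengthCurve, PressureSweep


class NoOverlapError(ValueError):
    """Two force-length curves share no stretch span."""


class IntersectionError(ValueError):
    """No pair of force-length curves crosses; IVS is undefined."""


class QCUndefinedError(ValueError):
    """Axial-force QC statistic is undefined (non-positive mean force)."""


def pairwise_intersection(a: ForceLengthCurve, b: ForceLengthCurve) -> float | None:
    """Stretch at which two force-length curves cross, or None.

    Both curves are piecewise-linearly interpolated onto the union of
    their stretch knots within the overlapping span; the crossing is a
    zero of their difference (exact for the piecewise-linear
    interpolants).  If several zeros exist, the physically expected ones
    are preferred: where the higher-pressure curve passes from below to
    above the lower-pressure curve as stretch increases (the median of
    those, which stays unbiased when noise produces a cluster of zeros
    around the true crossover); if no upward zero exists, the zero closest
    to the midpoint of the overlap.

    Raises
    ------
    NoOverlapError
        If the curves' stretch spans do not overlap.
    """
    lo = max(a.span[0], b.span[0])
    hi = min(a.span[1], b.span[1])
    if lo >= hi:
        raise NoOverlapError(
            f"curves at {a.pressure_mmhg} and {b.pressure_mmhg} mmHg share no stretch span"
        )
    knots = np.union1d(a.lambda_z, b.lambda_z)
    knots = knots[(knots >= lo) & (knots <= hi)]
    if knots.size < 2 or knots[0] > lo or knots[-1] < hi:
        knots = np.union1d(knots, [lo, hi])
    hi_curve, lo_curve = (a, b) if a.pressure_mmhg >= b.pressure_mmhg else (b, a)
    d = np.interp(knots, hi_curve.lambda_z, hi_curve.force_mn) - np.interp(
        knots, lo_curve.lambda_z, lo_curve.force_mn
    )
    zeros: list[tuple[float, bool]] = []  # (stretch, crosses upward)
    for i in range(knots.size - 1):
        d0, d1 = d[i], d[i + 1]
        if d0 == 0.0:
            zeros.append((float(knots[i]), d1 > 0.0))
        elif d0 * d1 < 0.0:
            x = knots[i] - d0 * (knots[i + 1] - knots[i]) / (d1 - d0)
            zeros.append((float(x), d1 > d0))
    if d[-1] == 0.0:
        zeros.append((float(knots[-1]), d[-1] > d[-2]))
    if not zeros:
        return None
    upward = sorted(x for x, up in zeros if up)
    if upward:
        # several upward zeros arise when noise wiggles the difference near
        # the true crossover; the median is a symmetric (bias-free) choice
        k = len(upward)
        if k % 2:
            return upward[(k - 1) // 2]
        return 0.5 * (upward[k // 2 - 1] + upward[k // 2])
    mid = 0.5 * (lo + hi)
    return min((x for x, _ in zeros), key=lambda x: abs(x - mid))


@dataclass(frozen=True)
class IVSResult:
    """Estimated in-vivo stretch with intersection diagnostics and QC verdict."""

    ivs: float
    pairwise_crossings: tuple[tuple[tuple[float, float], float], ...]
    spread: float
    low_confidence: bool = False
    qc_force_spread: float | None = None
    qc_pass: bool | None = None

    def with_qc(self, qc_force_spread: float, qc_pass: bool) -> "IVSResult":
        return IVSResult(
            ivs=self.ivs,
            pairwise_crossings=self.pairwise_crossings,
            spread=self.spread,
            low_confidence=self.low_confidence,
            qc_force_spread=qc_force_spread,
            qc_pass=qc_pass,
        )


def estimate_ivs(curves: list[ForceLengthCurve]) -> IVSResult:
    """IVS as the mean of all defined pairwise curve crossings.

    ``spread`` is the maximum absolute deviation of individual crossings
    from the mean.  With three or more curves but fewer than two usable
    crossings the result is flagged low-confidence rather than dropped.

    Raises
    ------
    ValueError
        Fewer than two curves, or duplicate pressures.
    IntersectionError
        If no pair of curves crosses.
    """
    if len(curves) < 2:
        raise ValueError("need force-length curves at >= 2 pressures")
    pressures = [c.pressure_mmhg for c in curves]
    if len(set(pressures)) != len(pressures):
        raise ValueError(f"curves must be at distinct pressures, got {pressures}")
    crossings = []
    for i in range(len(curves)):
        for j in range(i + 1, len(curves)):
            x = pairwise_intersection(curves[i], curves[j])
            if x is not None:
                pair = (curves[i].pressure_mmhg, curves[j].pressure_mmhg)
                crossings.append((pair, x))
    if not crossings:
        raise IntersectionError(
            f"no pair of force-length curves crosses (pressures {pressures})"
        )
    values = np.array([x for _, x in crossings])
    ivs = float(values.mean())
    spread = float(np.abs(values - ivs).max())
    low_confidence = len(curves) >= 3 and len(crossings) < 2
    return IVSResult(
        ivs=ivs,
        pairwise_crossings=tuple(crossings),
        spread=spread,
        low_confidence=low_confidence,
    )


def qc_axial_force_spread(
    sweep: PressureSweep,
    threshold: float = 0.25,
    pressure_floor_mmhg: float = 20.0,
) -> tuple[float, bool]:
    """Relative axial-force spread over the pressure sweep, and pass/fail.

    spread = max_P |f(P) - mean_P f| / mean_P f over steps with
    P >= ``pressure_floor_mmhg`` (low-pressure steps are excluded because
    the statistic is unstable where force approaches zero); the sample
    passes if spread <= ``threshold`` (default 0.25, i.e. the >25%
    exclusion rule).

    Raises
    ------
    QCUndefinedError
        If the mean force over the retained steps is not positive.
    """
    if not (0.0 < threshold):
        raise ValueError("threshold must be positive")
    mask = sweep.pressure_mmhg >= pressure_floor_mmhg
    if not np.any(mask):
        raise QCUndefinedError(
            f"no sweep steps at or above the {pressure_floor_mmhg} mmHg floor"
        )
    f = sweep.force_mn[mask]
    mean = float(f.mean())
    if mean <= 0.0:
        raise QCUndefinedError(
            f"mean axial force {mean:.4f} mN is not positive; spread undefined"
        )
    spread = float(np.abs(f - mean).max() / mean)
    return spread, spread <= threshold
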