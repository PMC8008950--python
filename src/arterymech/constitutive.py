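"""Four-fiber-family constitutive model for the passive arterial wall.

The simulator's ground truth is the widely used incompressible
neo-Hookean-matrix / four-fiber-family strain energy (per unit reference
volume)

    W = c/2 (I1 - 3) + sum_k c1_k / (4 c2_k) [exp(c2_k (I4_k - 1)^2) - 1],

with fiber invariant I4_k = lambda_theta^2 cos^2(alpha_k)
+ lambda_z^2 sin^2(alpha_k); ``alpha_k`` is the fiber angle measured from
the circumferential axis (0 = circumferential family, pi/2 = axial family,
and a symmetric +/- diagonal pair).  Under the membrane assumption with
incompressibility
(lambda_r = 1/(lambda_theta lambda_z)) and zero radial stress, the Cauchy
stresses are

    sigma_theta = lambda_theta dW/dlambda_theta,
    sigma_z     = lambda_z     dW/dlambda_z,

evaluated on W restricted to (lambda_theta, lambda_z).  This exponential
form reproduces the strain-stiffening (collagen-recruitment) behavior of
carotid pressure-diameter data and gives closed-form stresses for oracle
tests downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_AXIS_TOL = 1e-9


@dataclass(frozen=True)
class FiberFamily:
    """One fiber family: stiffness c1 (kPa), exponent c2 (-), angle alpha (rad)."""

    c1: float
    c2: float
    alpha: float

    def __post_init__(self) -> None:
        if self.c1 < 0.0 or self.c2 < 0.0:
            raise ValueError(f"fiber stiffness/exponent must be >= 0: {self}")


@dataclass(frozen=True)
class ConstitutiveParams:
    """Ground-truth material parameters plus the measurement-noise model.

    ``fibers`` is conventionally (circumferential, axial, +diagonal,
    -diagonal); any off-axis family must appear as a symmetric +/- pair
    with identical (c1, c2).  Fiber stress is smooth in the invariant
    I4 (no tension-only cutoff).  ``noise_od_sd`` (um) and ``noise_f_sd`` (mN)
    are the additive Gaussian instrument-noise SDs on outer diameter and
    transducer force; pressure and axial stretch are treated as exactly
    controlled.
    """

    c_iso: float
    fibers: tuple[FiberFamily, ...] = field(default_factory=tuple)
    noise_od_sd: float = 2.0
    noise_f_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_iso < 0.0:
            raise ValueError(f"c_iso must be >= 0, got {self.c_iso}")
        if self.noise_od_sd < 0.0 or self.noise_f_sd < 0.0:
            raise ValueError("noise SDs must be >= 0")
        stiff = [self.c_iso] + [f.c1 for f in self.fibers]
        if not any(s > 0.0 for s in stiff):
            raise ValueError("at least one stiffness parameter must be > 0")
        # off-axis families must come as symmetric +/- pairs
        off_axis = [
            f for f in self.fibers
            if abs(f.alpha) > _AXIS_TOL and abs(abs(f.alpha) - np.pi / 2) > _AXIS_TOL
        ]
        unmatched = list(off_axis)
        while unmatched:
            f = unmatched.pop()
            partner = next(
                (
                    g for g in unmatched
                    if abs(g.alpha + f.alpha) < _AXIS_TOL
                    and abs(g.c1 - f.c1) < _AXIS_TOL
                    and abs(g.c2 - f.c2) < _AXIS_TOL
                ),
                None,
            )
            if partner is None:
                raise ValueError(
                    f"diagonal fiber family alpha={f.alpha} lacks a symmetric -alpha partner"
                )
            unmatched.remove(partner)


def cauchy_stresses(params: ConstitutiveParams, lambda_theta, lambda_z):
    """Biaxial Cauchy stresses (sigma_theta, sigma_z) in kPa, vectorized.

    Inputs broadcast.
    """
    lt = np.asarray(lambda_theta, dtype=float)
    lz = np.asarray(lambda_z, dtype=float)
    lt2 = lt * lt
    lz2 = lz * lz
    lr2 = 1.0 / (lt2 * lz2)
    sig_t = params.c_iso * (lt2 - lr2)
    sig_z = params.c_iso * (lz2 - lr2)
    for f in params.fibers:
        cos2 = np.cos(f.alpha) ** 2
        sin2 = np.sin(f.alpha) ** 2
        i4 = lt2 * cos2 + lz2 * sin2
        e = i4 - 1.0
        # exponent capped to keep root-scans finite at unphysical stretches
        common = f.c1 * e * np.exp(np.minimum(f.c2 * e * e, 700.0))
        sig_t = sig_t + common * lt2 * cos2
        sig_z = sig_z + common * lz2 * sin2
    return sig_t, sig_z


def stress_derivatives(params: ConstitutiveParams, lambda_theta, lambda_z):
    """Analytic tangent moduli (dsigma_theta/dlambda_theta, dsigma_z/dlambda_z).

    Partial derivatives of :func:`cauchy_stresses` holding the other
    stretch fixed — the oracle for windowed tangent-modulus estimates on
    curves where the other stretch is constant.
    """
    lt = np.asarray(lambda_theta, dtype=float)
    lz = np.asarray(lambda_z, dtype=float)
    lt2, lz2 = lt * lt, lz * lz
    lr2 = 1.0 / (lt2 * lz2)
    # d/dlt of c(lt^2 - 1/(lt^2 lz^2)) and d/dlz of c(lz^2 - 1/(lt^2 lz^2))
    d_t = params.c_iso * (2.0 * lt + 2.0 * lr2 / lt)
    d_z = params.c_iso * (2.0 * lz + 2.0 * lr2 / lz)
    for f in params.fibers:
        cos2 = np.cos(f.alpha) ** 2
        sin2 = np.sin(f.alpha) ** 2
        i4 = lt2 * cos2 + lz2 * sin2
        e = i4 - 1.0
        ex = np.exp(np.minimum(f.c2 * e * e, 700.0))
        g = f.c1 * e * ex                      # fiber stress factor
        dg = f.c1 * ex * (1.0 + 2.0 * f.c2 * e * e)  # dg/de
        # sigma_t_fiber = g * lt2 * cos2 ; de/dlt = 2 lt cos2
        d_t = d_t + cos2 * (dg * 2.0 * lt * cos2 * lt2 + g * 2.0 * lt)
        d_z = d_z + sin2 * (dg * 2.0 * lz * sin2 * lz2 + g * 2.0 * lz)
    return d_t, d_z


def scale_fiber_stiffness(
    params: ConstitutiveParams,
    multiplier: float,
    families: str = "all",
) -> ConstitutiveParams:
    """Return params with fiber c1 values scaled.

    ``families`` selects which fibers are scaled: "all", "axial"
    (alpha = pi/2), or "collagen" (circumferential + diagonal families,
    the ones that left-shift the circumferential stress-stretch curve).
    """
    if multiplier < 0.0:
        raise ValueError("multiplier must be >= 0")

    def selected(f: FiberFamily) -> bool:
        axial = abs(abs(f.alpha) - np.pi / 2) < _AXIS_TOL
        if families == "all":
            return True
        if families == "axial":
            return axial
        if families == "collagen":
            return not axial
        raise ValueError(f"unknown family selector {families!r}")

    new = tuple(
        replace(f, c1=f.c1 * multiplier) if selected(f) else f for f in params.fibers
    )
    return replace(params, fibers=new)


def set_diagonal_angle(params: ConstitutiveParams, alpha: float) -> ConstitutiveParams:
    """Return params with the diagonal (+/-) fiber pair rotated to +/- alpha."""
    if not (0.0 < alpha < np.pi / 2):
        raise ValueError("diagonal angle must lie strictly between 0 and pi/2")
    new = tuple(
        replace(f, alpha=np.copysign(alpha, f.alpha))
        if abs(f.alpha) > _AXIS_TOL and abs(abs(f.alpha) - np.pi / 2) > _AXIS_TOL
        else f
        for f in params.fibers
    )
    return replace(params, fibers=new)


def default_params(
    fiber_multiplier: float = 1.0,
    diagonal_angle: float = np.deg2rad(32.6),
    noise_od_sd: float = 2.0,
    noise_f_sd: float = 0.05,
    seed: int = 0,
) -> ConstitutiveParams:
    """Mouse-carotid-scale default parameter set (wild-type-like).

    Chosen to put the simulated vessel in the physiological envelope of a
    young mouse common carotid: loaded OD of a few hundred um over
    0-140 mmHg, circumferential stress of order 100 kPa in the
    physiological pressure range, axial force of a few mN near the in-vivo
    stretch, and force-length curves at 90/120/140 mmHg that nearly share a
    crossing close to a stretch of 1.85.  The crossover location is most
    sensitive to the diagonal-fiber angle (the axial family adds a
    pressure-independent force term that cancels between curves), so
    ``diagonal_angle`` is the calibration knob.  ``fiber_multiplier``
    scales the collagen-like (circumferential + diagonal) families to
    emulate a stiffened phenotype.
    """
    p = ConstitutiveParams(
        c_iso=10.0,
        fibers=(
            FiberFamily(c1=8.0, c2=1.0, alpha=0.0),                 # circumferential
            FiberFamily(c1=3.0, c2=0.15, alpha=np.pi / 2),          # axial
            FiberFamily(c1=2.0, c2=1.5, alpha=diagonal_angle),      # +diagonal
            FiberFamily(c1=2.0, c2=1.5, alpha=-diagonal_angle),     # -diagonal
        ),
        noise_od_sd=noise_od_sd,
        noise_f_sd=noise_f_sd,
        seed=seed,
    )
    if fiber_multiplier != 1.0:
        p = scale_fiber_stiffness(p, fiber_multiplier, families="collagen")
    return p
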