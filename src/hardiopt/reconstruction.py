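"""Single-shell ODF and propagator reconstructions.

Four reconstructions of angular structure from one q-shell of normalized
attenuations E(g), all expressed as real even-order SH series:

``qball_odf``
    Analytical Q-ball: the Funk-Radon transform of the shell signal is
    diagonal in SH with eigenvalues ``2 pi P_l(0)``, so an SH fit of E maps
    directly to ODF coefficients.  No regularization is applied.

``dot_pdf_shell``
    Diffusion orientation transform: under the mono-exponential model
    ``E(q u) = exp(-q^2 t D(u))`` the displacement propagator on a shell of
    radius R0 follows from the Rayleigh plane-wave expansion,

        p(R0 u) = sum_lm (-1)^{l/2} Y_lm(u) < I_l(u', R0), Y_lm(u') >,
        I_l(u', R0) = (1 / 2 pi^2) Int_0^inf q^2 exp(-q^2 t D(u')) j_l(q R0) dq,

    with the q convention fixed by the isotropic Gaussian limit
    ``p(r) = (4 pi t D)^{-3/2} exp(-r^2 / 4 t D)``.

``dot_odf_numerical``
    Radial integral of the DOT propagator, either unweighted (DOT-ODF) or
    weighted by R0^2 (DOT-mODF, the angular marginal of the normalized
    propagator), truncated at R0max and summed on a grid.

``dot_odf_analytical``
    Carrying the radial integral of the DOT-ODF through analytically
    collapses the double integral to

        psi_lm = (-1)^{l/2} (I~_l / t) c_lm,      I~_l = |P_l(0)| / (8 pi),

    where c_lm are the SH coefficients of the *reciprocal* diffusivity
    1/D(u).  The radial coefficients I~_l are equivalently
    ``(1 / 4 pi^2) Int_0^inf j_l(x) dx``; both routes are implemented.  The
    isotropic case reduces to ``psi = 1 / (8 pi t D)``, the exact radial
    integral of the Gaussian propagator.

Diffusion times are accepted in milliseconds (as printed in protocol
tables) and converted to seconds internally; with q in 1/mm, DOT-ODF values
are in 1/mm and mODF values are dimensionless surface densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import spherical_jn

from .sphere_math import (
    SHSeries,
    SphereMesh,
    fit_sh,
    legendre_at_zero,
    n_sh_coeffs,
    real_sh_basis,
    sh_index_pairs,
    tessellate_icosahedron,
)
from .signal_sim import DWSignal, GradientScheme

__all__ = [
    "ADCProfile",
    "ODFProfile",
    "PDFShell",
    "D_MAX_CLAMP",
    "estimate_adc",
    "qball_odf",
    "radial_coefficient",
    "radial_coefficient_quadrature",
    "dot_odf_analytical",
    "dot_pdf_shell",
    "dot_odf_numerical",
]

#: Diffusivity ceiling used when clamping noisy attenuations (mm^2/s).
D_MAX_CLAMP = 5.0e-3
_E_EPS = 1.0e-6


@dataclass
class ADCProfile:
    """Per-direction apparent diffusivity and its SH fits."""

    directions: np.ndarray
    d_values: np.ndarray  # mm^2/s
    sh: SHSeries  # fit of D(u)
    sh_reciprocal: SHSeries  # fit of 1/D(u), s/mm^2
    b: float
    n_clamped: int = 0

    @property
    def lmax(self) -> int:
        return self.sh.lmax


@dataclass
class ODFProfile:
    """Reconstructed orientation function as an SH series."""

    sh: SHSeries
    method: str
    b: float | None = None
    t_ms: float | None = None
    units: str = ""

    @property
    def lmax(self) -> int:
        return self.sh.lmax

    def sample(self, mesh_or_directions) -> np.ndarray:
        if isinstance(mesh_or_directions, SphereMesh):
            return self.sh.evaluate(mesh_or_directions.vertices)
        return self.sh.evaluate(mesh_or_directions)


@dataclass
class PDFShell:
    """Propagator values p(R0 u) on a sphere of radius R0."""

    r0_mm: float
    t_ms: float
    sh: SHSeries

    def sample(self, mesh_or_directions) -> np.ndarray:
        if isinstance(mesh_or_directions, SphereMesh):
            return self.sh.evaluate(mesh_or_directions.vertices)
        return self.sh.evaluate(mesh_or_directions)


def estimate_adc(
    signal: DWSignal | np.ndarray,
    scheme: GradientScheme,
    b: float,
    lmax: int = 6,
) -> ADCProfile:
    """Mono-exponential ADC profile D(g) = -ln E(g) / b with SH fits.

    Noise can push measured attenuations outside (0, 1); values are clamped
    to ``[exp(-b * D_MAX_CLAMP), 1 - 1e-6]`` before the log and the number
    of clamped directions is recorded.  Fits of both D and 1/D are stored;
    the reciprocal is fitted directly per direction because the analytical
    DOT-ODF consumes SH coefficients of 1/D.
    """
    e = signal.attenuations if isinstance(signal, DWSignal) else np.asarray(signal)
    e = np.asarray(e, dtype=float)
    if b <= 0:
        raise ValueError("b must be positive")
    if np.all(e <= 0):
        raise ValueError("all attenuations non-positive; cannot estimate ADC")
    lo = np.exp(-b * D_MAX_CLAMP)
    clamped = np.count_nonzero((e < lo) | (e > 1.0 - _E_EPS))
    e_c = np.clip(e, lo, 1.0 - _E_EPS)
    d = -np.log(e_c) / b
    return ADCProfile(
        directions=scheme.directions,
        d_values=d,
        sh=fit_sh(d, scheme.directions, lmax),
        sh_reciprocal=fit_sh(1.0 / d, scheme.directions, lmax),
        b=b,
        n_clamped=int(clamped),
    )


def qball_odf(
    signal: DWSignal | np.ndarray,
    scheme: GradientScheme,
    lmax: int = 6,
    b: float | None = None,
) -> ODFProfile:
    """Analytical Q-ball ODF: Funk-Radon transform of the shell signal.

    The SH fit ``s_lm`` of E(g) maps to ODF coefficients
    ``psi_lm = 2 pi P_l(0) s_lm``.
    """
    e = signal.attenuations if isinstance(signal, DWSignal) else np.asarray(signal)
    s = fit_sh(e, scheme.directions, lmax)
    eig = {l: 2.0 * np.pi * legendre_at_zero(l) for l in range(0, lmax + 1, 2)}
    return ODFProfile(
        sh=s.scaled_by_degree(eig),
        method="qball",
        b=b if b is not None else scheme.b,
        units="dimensionless (unnormalized radial projection)",
    )


def radial_coefficient(l: int) -> float:
    """Radial DOT-ODF coefficient I~_l = |P_l(0)| / (8 pi) in closed form."""
    return abs(legendre_at_zero(l)) / (8.0 * np.pi)


def radial_coefficient_quadrature(l: int, tol: float = 1e-8) -> float:
    """I~_l via the Bessel route (1 / 4 pi^2) Int_0^inf j_l(x) dx.

    The improper integral is evaluated on [0, X] with the oscillatory tail
    accelerated by averaging partial integrals over successive half-periods
    (the tail of j_l decays as 1/x, so bare truncation converges too slowly).
    """
    if l % 2 != 0 or l < 0:
        raise ValueError(f"l must be a non-negative even integer, got {l}")
    from scipy.integrate import quad

    base, _ = quad(lambda x: spherical_jn(l, x), 0.0, 200.0, limit=400)
    # tail: average partial sums over half-periods pi to damp oscillation
    partials = []
    acc = 0.0
    for k in range(40):
        seg, _ = quad(
            lambda x: spherical_jn(l, x),
            200.0 + k * np.pi,
            200.0 + (k + 1) * np.pi,
            limit=100,
        )
        acc += seg
        partials.append(acc)
    tail = float(np.mean(partials[-20:]))
    return (base + tail) / (4.0 * np.pi**2)


def dot_odf_analytical(
    adc: ADCProfile, t_ms: float, lmax: int | None = None
) -> ODFProfile:
    """Closed-form DOT-ODF from the reciprocal-diffusivity SH fit."""
    if t_ms <= 0:
        raise ValueError("diffusion time must be positive")
    if np.any(adc.d_values <= 0):
        raise ValueError("non-positive diffusivity in ADC profile")
    lmax = adc.lmax if lmax is None else lmax
    if lmax > adc.lmax:
        raise ValueError("requested lmax exceeds the fitted ADC order")
    t_s = t_ms * 1e-3
    recip = adc.sh_reciprocal
    if lmax < adc.lmax:
        keep = [i for i, (l, _) in enumerate(sh_index_pairs(adc.lmax)) if l <= lmax]
        recip = SHSeries(lmax, recip.coeffs[keep])
    factors = {
        l: (-1.0) ** (l // 2) * radial_coefficient(l) / t_s
        for l in range(0, lmax + 1, 2)
    }
    return ODFProfile(
        sh=recip.scaled_by_degree(factors),
        method="dot_odf_analytic",
        b=adc.b,
        t_ms=t_ms,
        units="1/mm",
    )


# ---------------------------------------------------------------------------
# numerical DOT


def _gauss_q_nodes(t_s: float, d_min: float, n: int = 400):
    """Gauss-Legendre nodes/weights on [0, qmax] covering exp(-q^2 t D)."""
    qmax = 8.0 / np.sqrt(t_s * d_min)
    x, w = np.polynomial.legendre.leggauss(n)
    q = 0.5 * qmax * (x + 1.0)
    return q, 0.5 * qmax * w


def _dot_shell_coeffs(
    adc: ADCProfile,
    r0_grid: np.ndarray,
    t_s: float,
    lmax: int,
    quad_mesh: SphereMesh,
) -> np.ndarray:
    """SH coefficients of p(R0 u) for every R0 in ``r0_grid``.

    Returns an array of shape (len(r0_grid), R).  The radial transform
    I_l(u', R0) is integrated by fixed Gauss-Legendre quadrature in q and
    the sphere projection by vertex-area weights on a dense icosahedral
    mesh.
    """
    d_v = adc.sh.evaluate(quad_mesh.vertices)
    d_v = np.clip(d_v, 1e-6, None)  # SH ringing guard; D must stay positive
    q, wq = _gauss_q_nodes(t_s, float(d_v.min()))
    decay = np.exp(-np.outer(q**2 * t_s, d_v))  # (nq, nvert)
    decay_w = decay * (wq * q**2)[:, None]
    basis = real_sh_basis(quad_mesh.vertices, lmax)  # (nvert, R)
    wv = quad_mesh.vertex_weights
    coeffs = np.empty((len(r0_grid), n_sh_coeffs(lmax)))
    degs = [l for l, _ in sh_index_pairs(lmax)]
    for l in sorted(set(degs)):
        jl = spherical_jn(l, np.outer(q, r0_grid))  # (nq, nr0)
        i_l = (decay_w.T @ jl) / (2.0 * np.pi**2)  # (nvert, nr0)
        cols = [i for i, d in enumerate(degs) if d == l]
        proj = basis[:, cols].T @ (i_l * wv[:, None])  # (len(cols), nr0)
        coeffs[:, cols] = ((-1.0) ** (l // 2) * proj).T
    return coeffs


def dot_pdf_shell(
    adc: ADCProfile,
    r0_mm: float,
    t_ms: float,
    lmax: int | None = None,
    quad_order: int = 4,
) -> PDFShell:
    """DOT propagator shell p(R0 u) as an SH series.

    ``quad_order`` sets the icosahedral quadrature mesh for the sphere
    projection (order 4 = 2562 vertices, ample for lmax <= 8).
    """
    if r0_mm < 0 or t_ms <= 0:
        raise ValueError("need R0 >= 0 and t > 0")
    lmax = adc.lmax if lmax is None else lmax
    mesh = tessellate_icosahedron(quad_order)
    c = _dot_shell_coeffs(adc, np.array([r0_mm]), t_ms * 1e-3, lmax, mesh)[0]
    return PDFShell(r0_mm=r0_mm, t_ms=t_ms, sh=SHSeries(lmax, c))


def dot_odf_numerical(
    adc: ADCProfile,
    t_ms: float,
    lmax: int | None = None,
    r0_max_mm: float | None = None,
    n_steps: int = 64,
    weight: str = "uniform",
    quad_order: int = 4,
) -> ODFProfile:
    """DOT-ODF (or mODF) by trapezoidal radial summation of DOT shells.

    ``weight="uniform"`` integrates p(R0 u) dR0 (DOT-ODF); ``"r_squared"``
    integrates p(R0 u) R0^2 dR0 (DOT-mODF).  The truncation radius defaults
    to ``4 sqrt(6 t D_max)``, four times the rms displacement.
    """
    if weight not in ("uniform", "r_squared"):
        raise ValueError(f"unknown weight {weight!r}")
    if n_steps < 32:
        raise ValueError("n_steps must be at least 32")
    if t_ms <= 0:
        raise ValueError("diffusion time must be positive")
    lmax = adc.lmax if lmax is None else lmax
    t_s = t_ms * 1e-3
    d_max = float(adc.d_values.max())
    r_char = np.sqrt(6.0 * t_s * d_max)
    if r0_max_mm is None:
        r0_max_mm = 4.0 * r_char
    elif r0_max_mm < 2.0 * r_char:
        warnings.warn(
            f"R0max = {r0_max_mm:.3g} mm < 2 sqrt(6 t Dmax) = "
            f"{2 * r_char:.3g} mm: radial truncation will bias the ODF",
            RuntimeWarning,
            stacklevel=2,
        )
    mesh = tessellate_icosahedron(quad_order)
    r0 = np.linspace(0.0, r0_max_mm, n_steps + 1)
    shells = _dot_shell_coeffs(adc, r0, t_s, lmax, mesh)
    w = np.ones_like(r0) if weight == "uniform" else r0**2
    coeffs = np.trapezoid(shells * w[:, None], r0, axis=0)
    return ODFProfile(
        sh=SHSeries(lmax, coeffs),
        method="dot_odf_numeric" if weight == "uniform" else "dot_modf",
        b=adc.b,
        t_ms=t_ms,
        units="1/mm" if weight == "uniform" else "dimensionless",
    )
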