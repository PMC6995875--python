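"""Real spherical-harmonic machinery for the depth-resolved transport solver.

The radiance in a laterally modulated slab problem, L(x, z, s) =
psi(z, s) exp(i k x) with k = 2*pi*fx, is expanded on real spherical
harmonics Y_lm(s) up to order N. The streaming operator s.grad splits into
mu * d/dz (mu = s_z, coupling l -> l+-1 at fixed m) and i k s_x
(s_x = sin(theta) cos(phi), coupling l -> l+-1, m -> m+-1). This module
builds, once per expansion order, the matrix representations of mu and s_x,
the half-range (hemisphere) Gram matrices used for Marshak boundary and
interface conditions, the Fresnel-weighted boundary integrals, and the
detection weights that turn surface radiance coefficients into hemispheric
diffuse reflectance.

Two structural reductions are exploited (and verified in the test suite):

* azimuthal parity — for a normally incident, azimuthally even source the
  sine-azimuth harmonics (m < 0) are never excited, so the working system is
  the cosine sector of size (N+1)(N+2)/2 out of the full (N+1)^2;
* realification — conjugating the depth operator by diag(i^|m|) turns the
  complex i*k coupling into a real antisymmetric one, because s_x obeys the
  selection rule m' = m +- 1. All eigenproblems are therefore real.

All integrals are evaluated by Gauss-Legendre / uniform-azimuth quadrature
that is exact for the band-limited integrands involved (Fresnel-weighted
integrals are split at the critical angle so each piece is smooth).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import lpmv, gammaln


# ---------------------------------------------------------------------------
# basis evaluation


def _norm_lm(l: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Orthonormalization constant sqrt((2l+1)/(4 pi) (l-m)!/(l+m)!)."""
    l = np.asarray(l, dtype=float)
    m = np.asarray(m, dtype=float)
    return np.sqrt(
        (2 * l + 1) / (4 * np.pi) * np.exp(gammaln(l - m + 1) - gammaln(l + m + 1))
    )


def theta_part(l: int, m: int, mu) -> np.ndarray:
    """Polar factor F_lm(mu) of the real harmonic: Y_lm = F_lm(mu) cos(m phi).

    m = 0: F = N_l0 P_l(mu); m > 0: F = sqrt(2) N_lm P_l^m(mu).
    (Condon-Shortley phase included via scipy's lpmv; the convention cancels
    in every operator since source and detection use the same basis.)
    """
    mu = np.asarray(mu, dtype=float)
    f = _norm_lm(l, m) * lpmv(m, l, mu)
    if m > 0:
        f = np.sqrt(2.0) * f
    return f


def real_sph_harm(l: int, m: int, mu, phi) -> np.ndarray:
    """Real spherical harmonic; m >= 0 carries cos(m phi), m < 0 sin(|m| phi)."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    am = abs(m)
    f = theta_part(l, am, mu)
    if m >= 0:
        return f * np.cos(am * phi)
    return f * np.sin(am * phi)


def full_basis(order: int) -> list[tuple[int, int]]:
    """(l, m) indices of the full real basis, size (order+1)^2."""
    return [(l, m) for l in range(order + 1) for m in range(-l, l + 1)]


def cos_basis(order: int) -> list[tuple[int, int]]:
    """(l, m) indices of the cosine azimuthal sector (m >= 0), ordered by (m, l)."""
    return [(l, m) for m in range(order + 1) for l in range(m, order + 1)]


# ---------------------------------------------------------------------------
# quadrature operator assembly


def _sphere_quadrature(order: int):
    n_mu = 2 * order + 6
    n_phi = 4 * order + 8
    mu, w_mu = leggauss(n_mu)
    phi = 2 * np.pi * np.arange(n_phi) / n_phi
    w_phi = 2 * np.pi / n_phi
    return mu, w_mu, phi, w_phi


def _operator_matrices(order: int, basis: list[tuple[int, int]]):
    """Matrices of mu and s_x = sin(theta) cos(phi) on the given basis."""
    mu, w_mu, phi, w_phi = _sphere_quadrature(order)
    MU, PHI = np.meshgrid(mu, phi, indexing="ij")
    W = np.outer(w_mu, np.full_like(phi, w_phi))
    vals = np.stack([real_sph_harm(l, m, MU, PHI) for (l, m) in basis])
    flat = vals.reshape(len(basis), -1)
    wf = W.reshape(-1)
    sx = (np.sqrt(1 - MU**2) * np.cos(PHI)).reshape(-1)
    muf = MU.reshape(-1)
    a_z = flat @ (flat * (wf * muf)).T
    a_x = flat @ (flat * (wf * sx)).T
    # symmetrize and zero the entries the selection rules forbid
    a_z = 0.5 * (a_z + a_z.T)
    a_x = 0.5 * (a_x + a_x.T)
    a_z[np.abs(a_z) < 1e-13] = 0.0
    a_x[np.abs(a_x) < 1e-13] = 0.0
    return a_z, a_x


def _realified_coupling(a_x: np.ndarray, basis: list[tuple[int, int]]) -> np.ndarray:
    """Realified transverse coupling: entry -> -a_x where |m'| = |m|+1,
    +a_x where |m'| = |m|-1 (similarity transform by diag(i^|m|))."""
    out = np.zeros_like(a_x)
    for i, (_, mi) in enumerate(basis):
        for j, (_, mj) in enumerate(basis):
            if abs(mj) == abs(mi) + 1:
                out[i, j] = -a_x[i, j]
            elif abs(mj) == abs(mi) - 1:
                out[i, j] = a_x[i, j]
    return out


def _half_gauss(n: int, lo: float, hi: float):
    x, w = leggauss(n)
    return 0.5 * (hi - lo) * x + 0.5 * (hi + lo), 0.5 * (hi - lo) * w


def _azimuth_factor(m: int) -> float:
    return 2 * np.pi if m == 0 else np.pi


def fresnel_reflectance(mu: np.ndarray, n_in: float, n_out: float) -> np.ndarray:
    """Unpolarized Fresnel reflectance for incidence cosine mu, from medium
    n_in into medium n_out (total internal reflection handled)."""
    mu = np.asarray(mu, dtype=float)
    s2_t = (n_in / n_out) ** 2 * (1 - mu**2)
    r = np.ones_like(mu)
    ok = s2_t < 1
    mu_t = np.sqrt(1 - s2_t[ok])
    mui = mu[ok]
    rs = ((n_in * mui - n_out * mu_t) / (n_in * mui + n_out * mu_t)) ** 2
    rp = ((n_in * mu_t - n_out * mui) / (n_in * mu_t + n_out * mui)) ** 2
    r[ok] = 0.5 * (rs + rp)
    return r


@dataclass(frozen=True)
class HarmonicWorkspace:
    """Precomputed basis data for one expansion order (cosine sector)."""

    order: int
    basis: tuple[tuple[int, int], ...]
    a_z: np.ndarray              # streaming (mu) matrix, cosine sector
    coupling: np.ndarray         # realified s_x coupling (multiplied by k)
    tests: tuple[tuple[int, int], ...]   # Marshak test harmonics (l'-m odd)
    half_plus: np.ndarray        # n_test x n_basis, integral over mu > 0
    interface: np.ndarray        # 2*n_test x n_basis, both hemispheres
    source: np.ndarray           # unit-moment source shape: sqrt((2l+1)/4pi) delta_m0

    @property
    def dim(self) -> int:
        return len(self.basis)

    @property
    def n_tests(self) -> int:
        return len(self.tests)


@lru_cache(maxsize=8)
def workspace(order: int) -> HarmonicWorkspace:
    basis = cos_basis(order)
    a_z, a_x = _operator_matrices(order, basis)
    coupling = _realified_coupling(a_x, basis)

    # Marshak test set: per azimuthal order m, harmonics Y_{l'}^m with l'-m
    # odd; counts floor((order+1-m)/2) close the boundary systems exactly.
    tests = [
        (lp, m)
        for m in range(order + 1)
        for lp in range(m + 1, order + 1)
        if (lp - m) % 2 == 1
    ]

    mu_h, w_h = _half_gauss(2 * order + 6, 0.0, 1.0)
    n_t, n_b = len(tests), len(basis)
    half_plus = np.zeros((n_t, n_b))
    for ti, (lt, mt) in enumerate(tests):
        ft = theta_part(lt, mt, mu_h)
        for bi, (lb, mb) in enumerate(basis):
            if mb != mt:
                continue
            fb = theta_part(lb, mb, mu_h)
            half_plus[ti, bi] = _azimuth_factor(mt) * np.sum(w_h * ft * fb)

    # mu < 0 hemisphere via parity: Y_lm(-mu) = (-1)^(l+m) Y_lm(mu)
    parity_b = np.array([(-1) ** (l + m) for (l, m) in basis])
    parity_t = np.array([(-1) ** (l + m) for (l, m) in tests])
    half_minus = half_plus * np.outer(parity_t, parity_b)
    interface = np.vstack([half_plus, half_minus])

    source = np.zeros(n_b)
    for bi, (l, m) in enumerate(basis):
        if m == 0:
            source[bi] = np.sqrt((2 * l + 1) / (4 * np.pi))

    return HarmonicWorkspace(
        order=order,
        basis=tuple(basis),
        a_z=a_z,
        coupling=coupling,
        tests=tuple(tests),
        half_plus=half_plus,
        interface=interface,
        source=source,
    )


@lru_cache(maxsize=64)
def surface_matrices(order: int, n_in: float, n_out: float):
    """Top-surface condition rows and detection weights for a medium of
    index ``n_in`` below an ambient of index ``n_out``.

    Returns ``(rows, weights, t_normal)`` where ``rows @ c(0) = 0`` is the
    Marshak condition with internal Fresnel reflection, ``weights @ c(0)``
    is the Fresnel-transmitted outgoing hemispheric flux (diffuse
    reflectance for unit incident AC irradiance), and ``t_normal`` is the
    normal-incidence Fresnel transmission applied to the collimated beam.
    """
    ws = workspace(order)
    # split at the total-internal-reflection critical cosine so each
    # integrand is smooth
    if n_in > n_out:
        mu_c = np.sqrt(1 - (n_out / n_in) ** 2)
        pieces = [(0.0, mu_c), (mu_c, 1.0)]
    else:
        pieces = [(0.0, 1.0)]
    mu = np.concatenate([_half_gauss(64, lo, hi)[0] for (lo, hi) in pieces])
    w = np.concatenate([_half_gauss(64, lo, hi)[1] for (lo, hi) in pieces])
    refl = fresnel_reflectance(mu, n_in, n_out)

    n_t, n_b = ws.n_tests, ws.dim
    g_mat = np.zeros((n_t, n_b))
    for ti, (lt, mt) in enumerate(ws.tests):
        ft = theta_part(lt, mt, mu)
        for bi, (lb, mb) in enumerate(ws.basis):
            if mb != mt:
                continue
            fb = theta_part(lb, mb, mu)
            g_mat[ti, bi] = _azimuth_factor(mt) * np.sum(w * refl * ft * fb)

    parity_b = np.array([(-1) ** (l + m) for (l, m) in ws.basis])
    rows = ws.half_plus - g_mat * parity_b[None, :]

    weights = np.zeros(n_b)
    for bi, (l, m) in enumerate(ws.basis):
        if m != 0:
            continue
        fb = theta_part(l, 0, -mu)  # outgoing directions have mu_z < 0
        weights[bi] = 2 * np.pi * np.sum(w * (1 - refl) * mu * fb)

    t_normal = 1.0 - ((n_in - n_out) / (n_in + n_out)) ** 2
    return rows, weights, t_normal
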