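"""Neural field connectivity kernels, gain and diffusion functions.

The connectivity function ``w(x, y)`` weights the synaptic influence of
location ``y`` on location ``x``.  Homogeneous kernels depend only on the
displacement ``x - y`` and additionally expose a profile on displacement
nodes so the nonlocal drift can be applied by FFT convolution; the
anisotropic long-range kernel built on an orientation-preference map is the
canonical non-homogeneous example.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import integrate, special

from .grid import GridSpec


def _as_points(x, dimension: int) -> np.ndarray:
    """Coerce coordinates to shape ``(..., N)``; scalars allowed when N=1."""
    x = np.asarray(x, dtype=float)
    if dimension == 1 and (x.ndim == 0 or x.shape[-1] != 1):
        x = x[..., np.newaxis]
    if x.shape[-1] != dimension:
        raise ValueError(f"points must have last axis of size {dimension}")
    return x


@dataclass
class Kernel:
    """A neural field kernel with lazy pairwise evaluation.

    ``evaluate(x, y)`` accepts coordinate arrays of shape ``(..., N)``
    (plain scalars for N=1) and broadcasts.  ``profile`` maps a displacement
    to ``w(d)`` and exists only for homogeneous kernels.
    """

    evaluate: Callable[[np.ndarray, np.ndarray], np.ndarray]
    dimension: int
    homogeneous: bool
    symmetric: bool
    analytic_l1: Optional[float] = None
    profile: Optional[Callable[[np.ndarray], np.ndarray]] = None
    length_scale: float = 1.0
    name: str = "kernel"

    def __call__(self, x, y) -> np.ndarray:
        x = _as_points(x, self.dimension)
        y = _as_points(y, self.dimension)
        return self.evaluate(x, y)

    def profile_on_grid(self, grid: GridSpec) -> np.ndarray:
        """Sample ``w(d)`` on the centred displacement mesh."""
        if not self.homogeneous or self.profile is None:
            raise ValueError("profile_on_grid requires a homogeneous kernel")
        d = np.stack(grid.displacement_mesh(), axis=-1)
        return self.profile(d)

    def matrix(self, grid: GridSpec) -> np.ndarray:
        """Dense matrix ``W[i, j] = w(x_i, x_j)`` over grid nodes.

        Homogeneous kernels are evaluated at periodically wrapped
        displacements, consistent with the FFT convolution path.
        """
        pts = grid.coords()
        if self.homogeneous and self.profile is not None:
            d = grid.wrap(pts[:, np.newaxis, :] - pts[np.newaxis, :, :])
            return self.profile(d)
        return self.evaluate(pts[:, np.newaxis, :], pts[np.newaxis, :, :])

    def l1_norm(self, grid: Optional[GridSpec] = None) -> float:
        """``sup_x ||w(x, .)||_L1``; exact when a closed form exists.

        For homogeneous kernels this is the (x-independent) L1 norm of the
        profile; the quadrature fallback integrates ``|w|`` either adaptively
        (N=1) or on the supplied grid.
        """
        if self.analytic_l1 is not None:
            return self.analytic_l1
        if self.homogeneous and self.profile is not None:
            if self.dimension == 1:
                span = 60.0 * self.length_scale
                val, _ = integrate.quad(
                    lambda u: abs(float(self.profile(np.array([u])))),
                    -span, span, limit=400)
                return val
            if grid is None:
                raise ValueError("grid required for quadrature L1 norm in N>1")
            return float(np.sum(np.abs(self.profile_on_grid(grid))) * grid.cell_volume)
        if grid is None:
            raise ValueError("grid required for non-homogeneous L1 norm")
        W = np.abs(self.matrix(grid))
        return float(np.max(W.sum(axis=1)) * grid.cell_volume)


def _homogeneous(profile, dimension, analytic_l1, length_scale, name, symmetric=True):
    def evaluate(x, y):
        return profile(x - y)
    return Kernel(evaluate=evaluate, dimension=dimension, homogeneous=True,
                  symmetric=symmetric, analytic_l1=analytic_l1, profile=profile,
                  length_scale=length_scale, name=name)


# ---------------------------------------------------------------------------
# Kernel constructors
# ---------------------------------------------------------------------------

def gaussian_kernel(K: float, beta_loc: float, dimension: int = 1) -> Kernel:
    """Local isotropic Gaussian connectivity ``K exp(-|x-y|^2 / 2 beta^2)``.

    The exact L1 norm is ``K (2 pi)^{N/2} beta^N``.
    """
    if K <= 0 or beta_loc <= 0:
        raise ValueError("K and beta_loc must be positive")

    def profile(d):
        r2 = np.sum(np.asarray(d) ** 2, axis=-1)
        return K * np.exp(-r2 / (2.0 * beta_loc ** 2))

    l1 = K * (2.0 * np.pi) ** (dimension / 2.0) * beta_loc ** dimension
    return _homogeneous(profile, dimension, l1, beta_loc, "gaussian")


def exponential_kernel(beta: float, dimension: int = 1) -> Kernel:
    """Laplacian-profile kernel ``(1/2 beta) exp(-|x-y| / beta)``.

    In one dimension this is a probability density, so its L1 norm is exactly
    one for every ``x``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")

    def profile(d):
        r = np.sqrt(np.sum(np.asarray(d) ** 2, axis=-1))
        return np.exp(-r / beta) / (2.0 * beta)

    l1 = 1.0 if dimension == 1 else None
    if dimension == 2:
        # 2 pi ∫ r e^{-r/b} dr / (2b) = pi b
        l1 = np.pi * beta
    return _homogeneous(profile, dimension, l1, beta, "exponential")


def _mexican_hat_l1(K1, K2, beta1, beta2, dimension):
    """Exact L1 norm of the difference of two centred Gaussians.

    When the two Gaussians do not cross, the norm is the absolute difference
    of their masses; with a single radial crossing ``u0`` the integral splits
    into closed-form pieces (erf in 1D, radial exponentials in 2D).
    """
    mass = lambda K, b: K * (2.0 * np.pi) ** (dimension / 2.0) * b ** dimension
    a = np.log(K1 / K2)
    b = 0.5 * (1.0 / beta1 ** 2 - 1.0 / beta2 ** 2)
    if a == 0.0 and b == 0.0:
        return 0.0
    if b == 0.0 or a / b <= 0.0:
        return abs(mass(K1, beta1) - mass(K2, beta2))
    u0 = np.sqrt(a / b)
    if dimension == 1:
        part = lambda K, bb: np.sqrt(2 * np.pi) * K * bb * (
            2.0 * special.erf(u0 / (np.sqrt(2) * bb)) - 1.0)
        return abs(part(K1, beta1) - part(K2, beta2))
    if dimension == 2:
        part = lambda K, bb: 2 * np.pi * K * bb ** 2 * (
            1.0 - 2.0 * np.exp(-u0 ** 2 / (2 * bb ** 2)))
        return abs(part(K1, beta1) - part(K2, beta2))
    return None  # fall back to quadrature


def mexican_hat_kernel(K1: float, K2: float, beta1: float, beta2: float,
                       dimension: int = 1) -> Kernel:
    """Difference-of-Gaussians kernel: local excitation, surround inhibition
    when ``beta2 > beta1`` and ``K1 > K2``."""
    if min(K1, K2, beta1, beta2) <= 0:
        raise ValueError("all Mexican-hat parameters must be positive")

    def profile(d):
        r2 = np.sum(np.asarray(d) ** 2, axis=-1)
        return (K1 * np.exp(-r2 / (2.0 * beta1 ** 2))
                - K2 * np.exp(-r2 / (2.0 * beta2 ** 2)))

    l1 = _mexican_hat_l1(K1, K2, beta1, beta2, dimension)
    return _homogeneous(profile, dimension, l1, max(beta1, beta2), "mexican_hat")


def anisotropy_factor(chi: float, x, beta_lr: float) -> np.ndarray:
    """Anisotropic envelope ``exp(-((1-chi)^2 x1^2 + x2^2) / 2 beta_lr^2)``.

    ``chi = 0`` is the isotropic case (macaque-like); ``chi in (0,1)`` squeezes
    the envelope along the first axis (tree-shrew-like anisotropy).
    """
    if not (0.0 <= chi < 1.0):
        raise ValueError("chi must lie in [0, 1)")
    if beta_lr <= 0:
        raise ValueError("beta_lr must be positive")
    x = _as_points(x, 2)
    arg = ((1.0 - chi) ** 2 * x[..., 0] ** 2 + x[..., 1] ** 2) / (2.0 * beta_lr ** 2)
    return np.exp(-arg)


@dataclass
class OrientationMap:
    """Preferred-orientation map ``theta(x) in [0, pi)`` with pinwheels."""

    theta: Callable[[np.ndarray], np.ndarray]
    pinwheel_centers: list

    def __call__(self, x) -> np.ndarray:
        return self.theta(_as_points(x, 2))


def orientation_map_synthetic(grid: GridSpec, n_pinwheels: int, seed: int) -> OrientationMap:
    """Synthesize an orientation map as the half-argument of a band-passed
    superposition of complex plane waves.

    ``n_pinwheels = 0`` yields a single plane wave (theta linear in x modulo
    pi, no pinwheels); otherwise the number of random wave components scales
    with the requested pinwheel density.  Wavevectors are commensurate with
    the periodic box, so the map is well defined on the torus.  Deterministic
    given the seed.
    """
    if grid.dimension != 2:
        raise ValueError("orientation maps require a 2D grid")
    rng = np.random.default_rng(seed)
    k0 = np.pi / grid.half_width  # fundamental wavenumber of the box

    if n_pinwheels == 0:
        kvecs = np.array([[1.0, 0.0]]) * k0
        coeffs = np.array([1.0 + 0.0j])
    else:
        n_waves = max(4, int(n_pinwheels))
        # integer wavevectors on a ring; ring radius grows with pinwheel count
        ring = max(1, int(round(np.sqrt(n_pinwheels))))
        angles = rng.uniform(0, 2 * np.pi, n_waves)
        ints = np.round(ring * np.stack([np.cos(angles), np.sin(angles)], axis=-1))
        ints[np.all(ints == 0, axis=-1)] = [ring, 0]
        kvecs = ints * k0
        coeffs = rng.normal(size=n_waves) + 1j * rng.normal(size=n_waves)

    def complex_field(x):
        x = _as_points(x, 2)
        phases = x @ kvecs.T  # (..., n_waves)
        return np.tensordot(np.exp(1j * phases), coeffs, axes=([-1], [0]))

    def theta(x):
        z = complex_field(x)
        return np.mod(0.5 * np.angle(z), np.pi)

    # pinwheels: plaquettes where the phase of the complex field winds by 2 pi
    X1, X2 = grid.mesh()
    z = complex_field(np.stack([X1, X2], axis=-1))
    ang = np.angle(z)

    def dwrap(a):
        return (a + np.pi) % (2 * np.pi) - np.pi

    winding = (dwrap(ang[1:, :-1] - ang[:-1, :-1])
               + dwrap(ang[1:, 1:] - ang[1:, :-1])
               + dwrap(ang[:-1, 1:] - ang[1:, 1:])
               + dwrap(ang[:-1, :-1] - ang[:-1, 1:]))
    ii, jj = np.nonzero(np.abs(winding) > np.pi)
    h = grid.spacing
    centers = [(grid.axis[i] + h / 2, grid.axis[j] + h / 2) for i, j in zip(ii, jj)]
    return OrientationMap(theta=theta, pinwheel_centers=centers)


def long_range_kernel(eps_lr: float, chi: float, beta_lr: float, beta_theta: float,
                      theta_map: OrientationMap) -> Kernel:
    """Anisotropic patchy long-range connectivity on a 2D orientation map:

    ``w_lr(x, y) = eps_lr * A(chi, R_{-2 theta(x)}(x - y)) * G_{beta_theta}(theta(x) - theta(y))``

    where ``R_alpha`` is the rotation by ``alpha`` and ``G`` the 1D Gaussian
    density.  Not homogeneous whenever ``theta`` is non-constant.
    """
    if theta_map is None:
        raise ValueError("long_range_kernel requires an orientation map")
    if beta_theta <= 0:
        raise ValueError("beta_theta must be positive")

    norm = 1.0 / (np.sqrt(2.0 * np.pi) * beta_theta)

    def evaluate(x, y):
        x = _as_points(x, 2)
        y = _as_points(y, 2)
        tx = theta_map.theta(x)
        ty = theta_map.theta(y)
        d = x - y
        ang = -2.0 * tx
        c, s = np.cos(ang), np.sin(ang)
        d1 = c * d[..., 0] - s * d[..., 1]
        d2 = s * d[..., 0] + c * d[..., 1]
        rot = np.stack([d1, d2], axis=-1)
        A = anisotropy_factor(chi, rot, beta_lr)
        dtheta = tx - ty
        G = norm * np.exp(-dtheta ** 2 / (2.0 * beta_theta ** 2))
        return eps_lr * A * G

    return Kernel(evaluate=evaluate, dimension=2, homogeneous=False,
                  symmetric=False, analytic_l1=None, profile=None,
                  length_scale=beta_lr, name="long_range")


def pva_kernel(local: Kernel, longrange: Kernel) -> Kernel:
    """Primary-visual-area kernel: pointwise sum of local and long-range parts."""
    if local.dimension != longrange.dimension:
        raise ValueError("kernel dimensions must match")
    homogeneous = local.homogeneous and longrange.homogeneous

    def evaluate(x, y):
        return local.evaluate(x, y) + longrange.evaluate(x, y)

    profile = None
    if homogeneous and local.profile is not None and longrange.profile is not None:
        profile = lambda d: local.profile(d) + longrange.profile(d)
    return Kernel(evaluate=evaluate, dimension=local.dimension,
                  homogeneous=homogeneous,
                  symmetric=local.symmetric and longrange.symmetric,
                  analytic_l1=None, profile=profile,
                  length_scale=max(local.length_scale, longrange.length_scale),
                  name="pva")


def zero_kernel(dimension: int = 1) -> Kernel:
    """The identically-zero kernel (additive identity, test fixture)."""
    profile = lambda d: np.zeros(np.asarray(d).shape[:-1])
    return _homogeneous(profile, dimension, 0.0, 1.0, "zero")


# ---------------------------------------------------------------------------
# Gain and diffusion functions
# ---------------------------------------------------------------------------

@dataclass
class GainFunction:
    """Bounded globally Lipschitz firing-rate nonlinearity."""

    apply: Callable[[np.ndarray], np.ndarray]
    bound: float
    lipschitz: float
    name: str = "gain"

    def __call__(self, a) -> np.ndarray:
        return self.apply(np.asarray(a, dtype=float))


@dataclass
class DiffusionFunction:
    """Lipschitz, linear-growth modulation of the noise amplitude."""

    apply: Callable[[np.ndarray], np.ndarray]
    lipschitz: float
    linear_growth: float
    lam: Optional[float] = None
    name: str = "diffusion"

    def __call__(self, a) -> np.ndarray:
        return self.apply(np.asarray(a, dtype=float))


def sigmoid_gain() -> GainFunction:
    """Logistic gain ``G(a) = 1 / (1 + e^{-a})``: bound 1, slope bound 1/4."""
    return GainFunction(apply=lambda a: special.expit(a), bound=1.0,
                        lipschitz=0.25, name="sigmoid")


def constant_gain(c: float) -> GainFunction:
    return GainFunction(apply=lambda a: np.full_like(np.asarray(a, dtype=float), c),
                        bound=abs(c), lipschitz=0.0, name="constant")


def linear_diffusion(lam: float) -> DiffusionFunction:
    """Multiplicative noise ``sigma(a) = lambda a``."""
    return DiffusionFunction(apply=lambda a: lam * np.asarray(a, dtype=float),
                             lipschitz=abs(lam), linear_growth=abs(lam),
                             lam=lam, name="linear")


def constant_diffusion(c: float) -> DiffusionFunction:
    """Additive noise ``sigma = c`` (bounded, hence linear growth)."""
    return DiffusionFunction(apply=lambda a: np.full_like(np.asarray(a, dtype=float), c),
                             lipschitz=0.0, linear_growth=abs(c), name="constant")


def bounded_diffusion(c: float, scale: float = 1.0) -> DiffusionFunction:
    """Saturating diffusion ``sigma(a) = c tanh(a / scale)`` (bounded by |c|)."""
    return DiffusionFunction(
        apply=lambda a: c * np.tanh(np.asarray(a, dtype=float) / scale),
        lipschitz=abs(c) / scale, linear_growth=abs(c), name="tanh")
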