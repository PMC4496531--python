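"""Noise objects: space-time white noise, spatially smoothed noise, Q-Wiener.

Space-time white noise is represented by its increments over grid cells and
one time step: independent centred Gaussians of variance ``dt * h^N``, so the
covariance of cell-union sums reproduces the Lebesgue measure of overlaps.
Smoothing in space with ``φ ∈ L^2`` produces the correlated field
``W^φ(t,x) = ∫∫ φ(x−y) W(ds dy)``, white in time with spatial covariance
``t (φ ⋆ φ̃)(x−y)``.  The Hilbert-space route instead expands a Q-Wiener
process over an orthonormal eigenbasis with summable eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .grid import GridSpec, circular_convolve, convolve


# ---------------------------------------------------------------------------
# Smoothing kernels φ
# ---------------------------------------------------------------------------

@dataclass
class SmoothingKernel:
    """Spatial correlation function φ sampled on the centred grid mesh."""

    values: np.ndarray
    grid: GridSpec
    form: str = "custom"
    shift_alpha: Optional[float] = None  # known modulus exponent, when analytic

    @property
    def l2_norm(self) -> float:
        return float(np.sqrt(np.sum(self.values ** 2) * self.grid.cell_volume))

    def boundary_mass_fraction(self) -> float:
        """Fraction of |φ|^2 mass outside |x| <= L/4 (wrap-around hazard)."""
        mesh = np.stack(self.grid.mesh(), axis=-1)
        outside = np.max(np.abs(mesh), axis=-1) > self.grid.half_width / 4.0
        total = np.sum(self.values ** 2)
        if total == 0:
            return 0.0
        return float(np.sum(self.values[outside] ** 2) / total)


def gaussian_smoothing(grid: GridSpec, beta: float, amplitude: float = 1.0) -> SmoothingKernel:
    """Gaussian φ(x) = amplitude * exp(-|x|^2 / 2 beta^2); lies in W^{1,2},
    so its shift-modulus exponent is 1."""
    mesh = np.stack(grid.mesh(), axis=-1)
    r2 = np.sum(mesh ** 2, axis=-1)
    return SmoothingKernel(amplitude * np.exp(-r2 / (2 * beta ** 2)), grid,
                           form="gaussian", shift_alpha=1.0)


def indicator_smoothing(grid: GridSpec, half_width: float = 0.5) -> SmoothingKernel:
    """Indicator φ = 1 on the centred box of the given half width; its
    L^2 shift modulus scales like |z|^{1/2}."""
    mesh = np.stack(grid.mesh(), axis=-1)
    inside = np.all(np.abs(mesh) < half_width, axis=-1)
    return SmoothingKernel(inside.astype(float), grid,
                           form="indicator", shift_alpha=0.5)


def zero_smoothing(grid: GridSpec) -> SmoothingKernel:
    return SmoothingKernel(np.zeros(grid.field_shape), grid, form="zero")


# ---------------------------------------------------------------------------
# White noise
# ---------------------------------------------------------------------------

@dataclass
class WhiteNoiseIncrement:
    """One time step of set-indexed white noise, one Gaussian per grid cell."""

    values: np.ndarray
    dt: float
    grid: GridSpec


def white_noise_increments(grid: GridSpec, dt: float,
                           rng: np.random.Generator,
                           n: Optional[int] = None) -> WhiteNoiseIncrement:
    """Draw i.i.d. ``N(0, dt h^N)`` per cell; with ``n`` given, a leading
    replicate axis is prepended."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    shape = grid.field_shape if n is None else (n,) + grid.field_shape
    scale = np.sqrt(dt * grid.cell_volume)
    return WhiteNoiseIncrement(rng.normal(0.0, scale, size=shape), dt, grid)


def smoothed_increment(white: WhiteNoiseIncrement, phi: SmoothingKernel,
                       grid: Optional[GridSpec] = None) -> np.ndarray:
    """One increment of W^φ: ``ΔW^φ(x) = Σ_cells φ(x − y_cell) ΔW(cell)``.

    Circular FFT convolution; no extra cell-volume factor because the white
    noise increments already carry the cell measure.
    """
    grid = white.grid if grid is None else grid
    if phi.grid.field_shape != grid.field_shape:
        raise ValueError("smoothing kernel and noise live on different grids")
    vals = white.values
    if vals.ndim == grid.dimension:
        return circular_convolve(phi.values, vals)
    # replicate axis: convolve each realization (FFT along trailing axes)
    axes = tuple(range(1, vals.ndim))
    F = np.fft.fftn(np.fft.ifftshift(phi.values))
    out = np.fft.ifftn(np.fft.fftn(np.fft.ifftshift(vals, axes=axes), axes=axes)
                       * F, axes=axes)
    return np.fft.fftshift(out, axes=axes).real


def theoretical_covariance(phi: SmoothingKernel, t: float) -> np.ndarray:
    """Spatial covariance of W^φ(t, ·): ``r ↦ t (φ ⋆ φ̃)(r)`` on displacement
    nodes (centred layout); its value at r = 0 is ``t ||φ||_L2^2``."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    grid = phi.grid
    flip = np.flip(phi.values)
    flip = np.roll(flip, 1, axis=tuple(range(grid.dimension)))  # φ̃ on [-L, L)
    return t * convolve(phi.values, flip, grid)


def shift_modulus(phi: SmoothingKernel, z) -> float:
    """Cell-weighted L^2 norm of ``φ − φ(· + z)`` for a lattice displacement z."""
    grid = phi.grid
    z = np.atleast_1d(np.asarray(z, dtype=float))
    steps = z / grid.spacing
    ints = np.round(steps).astype(int)
    if np.max(np.abs(steps - ints)) > 1e-9:
        raise ValueError("displacement must be commensurate with the grid spacing")
    shifted = np.roll(phi.values, shift=tuple(-ints), axis=tuple(range(grid.dimension)))
    return float(np.sqrt(np.sum((phi.values - shifted) ** 2) * grid.cell_volume))


# ---------------------------------------------------------------------------
# Q-Wiener processes
# ---------------------------------------------------------------------------

@dataclass
class QSpec:
    """Truncated spectral data of a trace-class covariance operator Q.

    ``eigenvalues`` are the nonnegative λ_k, ``eigenfunctions`` the matching
    orthonormal grid functions e_k (orthonormal under the cell-weighted inner
    product), stacked along the leading axis.
    """

    eigenvalues: np.ndarray
    eigenfunctions: np.ndarray
    grid: GridSpec
    basis: str = "custom"

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenfunctions = np.asarray(self.eigenfunctions, dtype=float)
        if np.any(self.eigenvalues < 0):
            raise ValueError("eigenvalues must be nonnegative")
        if len(self.eigenvalues) != self.eigenfunctions.shape[0]:
            raise ValueError("eigenvalue/eigenfunction count mismatch")

    @property
    def trace(self) -> float:
        return float(np.sum(self.eigenvalues))

    def gram(self) -> np.ndarray:
        """Cell-weighted Gram matrix of the eigenfunctions (identity expected)."""
        E = self.eigenfunctions.reshape(len(self.eigenvalues), -1)
        return E @ E.T * self.grid.cell_volume

    def orthonormality_defect(self) -> float:
        G = self.gram()
        return float(np.max(np.abs(G - np.eye(len(G)))))

    @classmethod
    def fourier(cls, grid: GridSpec, lambdas) -> "QSpec":
        """Diagonal-in-Fourier Q on a 1D grid: real sin/cos eigenbasis.

        Modes are ordered constant, cos(k), sin(k) for k = 1, 2, ...; with all
        M modes retained the basis is complete on the lattice.
        """
        if grid.dimension != 1:
            raise NotImplementedError("Fourier Q basis implemented for N=1")
        lambdas = np.asarray(lambdas, dtype=float)
        M, L = grid.points_per_axis, grid.half_width
        x = grid.axis
        funcs = []
        funcs.append(np.full(M, 1.0 / np.sqrt(2 * L)))
        k = 1
        while len(funcs) < len(lambdas):
            w = np.pi * k / L
            funcs.append(np.cos(w * x) / np.sqrt(L))
            if len(funcs) < len(lambdas):
                if 2 * k == M:  # Nyquist cosine has full mass
                    funcs[-1] = np.cos(w * x) / np.sqrt(2 * L)
                else:
                    funcs.append(np.sin(w * x) / np.sqrt(L))
            k += 1
        E = np.stack(funcs[:len(lambdas)])
        return cls(lambdas, E, grid, basis="fourier")


def q_wiener_increment(q: QSpec, dt: float, rng: np.random.Generator,
                       n: Optional[int] = None) -> np.ndarray:
    """Karhunen–Loève increment ``ΔW = Σ_k sqrt(λ_k) ξ_k e_k``, ξ_k ~ N(0, dt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    k = len(q.eigenvalues)
    shape = (k,) if n is None else (n, k)
    xi = rng.normal(0.0, np.sqrt(dt), size=shape)
    E = q.eigenfunctions.reshape(k, -1)
    out = (xi * np.sqrt(q.eigenvalues)) @ E
    new_shape = q.grid.field_shape if n is None else (n,) + q.grid.field_shape
    return out.reshape(new_shape)


def q_half_apply(q: QSpec, f: np.ndarray) -> np.ndarray:
    """Apply ``Q^{1/2}`` spectrally: scale eigen-coefficients by sqrt(λ_k)."""
    k = len(q.eigenvalues)
    E = q.eigenfunctions.reshape(k, -1)
    coeffs = E @ f.ravel() * q.grid.cell_volume
    out = (coeffs * np.sqrt(q.eigenvalues)) @ E
    return out.reshape(q.grid.field_shape)


def colored_covariance(phi: SmoothingKernel, q: QSpec) -> np.ndarray:
    """Stationary spatial covariance ``c = Q^{1/2}φ ⋆ (Q^{1/2}φ)~`` of the
    smoothed Q-noise; reduces to ``φ ⋆ φ̃`` when all retained λ_k = 1 and the
    basis is complete."""
    grid = phi.grid
    g = q_half_apply(q, phi.values)
    flip = np.roll(np.flip(g), 1, axis=tuple(range(grid.dimension)))
    return convolve(g, flip, grid)


# ---------------------------------------------------------------------------
# Reproducible noise streams
# ---------------------------------------------------------------------------

class NoiseReplay:
    """Counter-based reproducible white-noise stream.

    Each time step draws from a Philox generator keyed by the run seed with
    the step index placed in the counter block, so any step can be recomputed
    independently and the same draws can feed different solver code paths.
    """

    def __init__(self, grid: GridSpec, dt: float, n_steps: int, seed: int):
        if dt <= 0 or n_steps < 0:
            raise ValueError("dt must be positive and n_steps nonnegative")
        self.grid, self.dt, self.n_steps, self.seed = grid, dt, n_steps, int(seed)

    def increment(self, step: int) -> WhiteNoiseIncrement:
        if not (0 <= step < self.n_steps):
            raise IndexError("step out of range")
        bitgen = np.random.Philox(key=self.seed, counter=[0, 0, step, 0])
        rng = np.random.Generator(bitgen)
        return white_noise_increments(self.grid, self.dt, rng)

    def increments_array(self) -> np.ndarray:
        """All increments, shape ``(n_steps, *field_shape)``."""
        return np.stack([self.increment(k).values for k in range(self.n_steps)])


def coarsen_increments(values: np.ndarray, factor: int) -> np.ndarray:
    """Sum fine-step white-noise increments into coarse-step increments."""
    n = values.shape[0]
    if n % factor:
        raise ValueError("number of steps must be divisible by factor")
    return values.reshape(n // factor, factor, *values.shape[1:]).sum(axis=1)
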