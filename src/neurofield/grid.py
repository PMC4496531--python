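"""Periodic truncated spatial lattice on which all fields live.

The continuum model is posed on R^N; numerically every field is sampled on a
node-centred uniform lattice covering the half-open box [-L, L)^N with
periodic wrap-around.  Displacements between nodes are therefore themselves
lattice vectors, which is what lets homogeneous kernels and smoothing kernels
act by circular (FFT) convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Uniform periodic lattice on ``[-L, L)^N``.

    Parameters
    ----------
    dimension
        Spatial dimension ``N`` (1 or 2).
    half_width
        Half the box side ``L`` (space units).
    points_per_axis
        Number of nodes ``M`` per axis; spacing is ``h = 2L/M``.
    """

    dimension: int
    half_width: float
    points_per_axis: int
    periodic: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.points_per_axis < 4:
            raise ValueError("points_per_axis must be at least 4")
        if not self.periodic:
            raise ValueError("only periodic grids are supported")

    @property
    def spacing(self) -> float:
        return 2.0 * self.half_width / self.points_per_axis

    @property
    def cell_volume(self) -> float:
        return self.spacing ** self.dimension

    @property
    def n_nodes(self) -> int:
        return self.points_per_axis ** self.dimension

    @property
    def field_shape(self) -> tuple[int, ...]:
        return (self.points_per_axis,) * self.dimension

    @property
    def axis(self) -> np.ndarray:
        """Node coordinates along one axis, ``-L, -L+h, ..., L-h``."""
        return -self.half_width + self.spacing * np.arange(self.points_per_axis)

    def coords(self) -> np.ndarray:
        """All node coordinates, shape ``(n_nodes, N)`` in C order."""
        axes = np.meshgrid(*([self.axis] * self.dimension), indexing="ij")
        return np.stack([a.ravel() for a in axes], axis=-1)

    def mesh(self) -> tuple[np.ndarray, ...]:
        """Meshgrid of node coordinates, each of shape ``field_shape``."""
        return tuple(np.meshgrid(*([self.axis] * self.dimension), indexing="ij"))

    def displacement_mesh(self) -> tuple[np.ndarray, ...]:
        """Signed periodic displacements, same layout as :meth:`mesh`.

        Identical coordinates to the node mesh: the centred axis doubles as
        the set of representative displacements in ``[-L, L)``.
        """
        return self.mesh()

    def wrap(self, d: np.ndarray) -> np.ndarray:
        """Map displacements into the representative interval ``[-L, L)``."""
        L = self.half_width
        return (np.asarray(d) + L) % (2 * L) - L

    def frequency_axis(self) -> np.ndarray:
        """DFT frequencies (cycles per space unit), centred (fftshifted)."""
        return np.fft.fftshift(np.fft.fftfreq(self.points_per_axis, d=self.spacing))


# ---------------------------------------------------------------------------
# Fourier helpers using the analyst's convention  F f(xi) = ∫ e^{-2πi x·ξ} f(x) dx
# ---------------------------------------------------------------------------

def forward_ft(f: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Quadrature approximation of the continuum Fourier transform.

    ``f`` is sampled on the centred node mesh; the result is returned on the
    centred frequency mesh (:meth:`GridSpec.frequency_axis` per axis).
    """
    shifted = np.fft.ifftshift(f)
    F = np.fft.fftn(shifted) * grid.cell_volume
    return np.fft.fftshift(F)


def inverse_ft(F: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Inverse of :func:`forward_ft` on the same grid."""
    shifted = np.fft.ifftshift(F)
    f = np.fft.ifftn(shifted) / grid.cell_volume
    return np.fft.fftshift(f)


def circular_convolve(f: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Plain circular convolution of two centred fields (no cell-volume factor).

    ``out(x_m) = sum_n f(x_n) g(x_m - x_n)`` with periodic wrap-around.
    """
    F = np.fft.fftn(np.fft.ifftshift(f))
    G = np.fft.fftn(np.fft.ifftshift(g))
    out = np.fft.ifftn(F * G)
    return np.fft.fftshift(out).real


def convolve(f: np.ndarray, g: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Riemann-sum approximation of the continuum convolution ``f ⋆ g``."""
    return circular_convolve(f, g) * grid.cell_volume
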