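"""Numerical verification of kernel admissibility conditions.

The well-posedness theory for the stochastic neural field equation rests on
integrability conditions on the connectivity kernel:

* C1:  ``∫∫ |w(x,y)|^2 dx dy < ∞``  (Hilbert–Schmidt drift),
* C2:  ``x ↦ ||w(x,·)||_L1`` lies in ``L^2``,
* C2': ``sup_x ||w(x,·)||_L1 <= C_w`` (uniform L1 bound),
* C1': ``∫ |w(x,y)| ρ(x) dx <= Λ ρ(y)`` for a positive integrable weight ρ,
* C3': ``||w(x,·) − w(x̃,·)||_L1 <= L_w |x − x̃|^α`` (L1 shift modulus).

All integrals over R^N must be truncated numerically, so each check returns a
three-way verdict (pass / fail / inconclusive) derived from the behaviour of
the truncated estimates as the truncation radius doubles: increments that
shrink geometrically indicate a convergent tail, increments that persist or
grow indicate divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .grid import GridSpec, circular_convolve
from .kernels import Kernel

PASS, FAIL, INCONCLUSIVE = "pass", "fail", "inconclusive"

# increment-ratio thresholds under radius doubling (see docs/methods.md)
_RATIO_CONVERGENT = 0.75
_RATIO_DIVERGENT = 0.95


@dataclass
class ConditionReport:
    condition_id: str
    truncation_radii: list
    estimates: list
    verdict: str
    constants: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "condition_id": self.condition_id,
            "truncation_radii": [float(r) for r in self.truncation_radii],
            "estimates": [float(e) for e in self.estimates],
            "verdict": self.verdict,
            "constants": {k: float(v) for k, v in self.constants.items()},
            "notes": list(self.notes),
        }


def default_radii(kernel: Kernel) -> np.ndarray:
    """Dyadic truncation radii ``{4, 8, 16, 32}`` kernel length scales."""
    return np.array([4.0, 8.0, 16.0, 32.0]) * kernel.length_scale


def _classify(radii, estimates, tol) -> tuple[str, list]:
    """Three-way verdict from truncated estimates at increasing radii."""
    est = np.asarray(estimates, dtype=float)
    notes = []
    if np.allclose(est, 0.0, atol=1e-300):
        return PASS, ["all truncated estimates are zero"]
    if len(est) >= 2:
        rel = abs(est[-1] - est[-2]) / max(abs(est[-1]), 1e-300)
        if rel < tol:
            return PASS, [f"relative change {rel:.2e} below tol {tol:.0e}"]
    if len(est) >= 3:
        d_prev = est[-2] - est[-3]
        d_last = est[-1] - est[-2]
        if abs(d_prev) < 1e-300:
            return (PASS, ["increments vanished"]) if abs(d_last) < 1e-300 \
                else (INCONCLUSIVE, ["non-monotone increments"])
        ratio = d_last / d_prev
        notes.append(f"increment ratio {ratio:.3f} under radius doubling")
        if 0 <= ratio <= _RATIO_CONVERGENT:
            return PASS, notes + ["geometrically shrinking tail"]
        if ratio >= _RATIO_DIVERGENT:
            return FAIL, notes + ["persistent or growing increments (divergence)"]
        return INCONCLUSIVE, notes
    return INCONCLUSIVE, notes + ["too few radii to classify"]


def _axis(radius: float, h: float) -> np.ndarray:
    """Midpoint-rule nodes covering [-R, R] with spacing h."""
    n = max(4, int(np.ceil(2.0 * radius / h)))
    return -radius + (np.arange(n) + 0.5) * (2.0 * radius / n)


def _resolution(kernel: Kernel, resolution: Optional[float]) -> float:
    return kernel.length_scale / 4.0 if resolution is None else resolution


def check_C1(kernel: Kernel, radii: Optional[Sequence[float]] = None,
             tol: float = 1e-4, resolution: Optional[float] = None) -> ConditionReport:
    """Truncated estimate of the double integral ``∫∫ |w(x,y)|^2 dx dy``."""
    if kernel.dimension != 1:
        raise NotImplementedError("C1 double-integral check implemented for N=1")
    radii = default_radii(kernel) if radii is None else np.asarray(radii, float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    h = _resolution(kernel, resolution)
    estimates = []
    for R in radii:
        ax = _axis(R, h)
        step = ax[1] - ax[0]
        pts = ax[:, None]
        W = kernel(pts[:, None, :], pts[None, :, :])
        estimates.append(float(np.sum(W ** 2) * step ** 2))
    verdict, notes = _classify(radii, estimates, tol)
    return ConditionReport("C1", list(radii), estimates, verdict, {}, notes)


def check_C2(kernel: Kernel, radii: Optional[Sequence[float]] = None,
             tol: float = 1e-4, resolution: Optional[float] = None) -> ConditionReport:
    """Truncated estimate of ``∫ (∫ |w(x,y)| dy)^2 dx``."""
    if kernel.dimension != 1:
        raise NotImplementedError("C2 check implemented for N=1")
    radii = default_radii(kernel) if radii is None else np.asarray(radii, float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    h = _resolution(kernel, resolution)
    estimates = []
    for R in radii:
        ax = _axis(R, h)
        step = ax[1] - ax[0]
        pts = ax[:, None]
        W = np.abs(kernel(pts[:, None, :], pts[None, :, :]))
        inner = W.sum(axis=1) * step          # ||w(x,·)||_L1 truncated
        estimates.append(float(np.sum(inner ** 2) * step))
    verdict, notes = _classify(radii, estimates, tol)
    return ConditionReport("C2", list(radii), estimates, verdict, {}, notes)


def check_C2prime(kernel: Kernel, radii: Optional[Sequence[float]] = None,
                  tol: float = 1e-4, resolution: Optional[float] = None) -> ConditionReport:
    """Truncated estimate of ``sup_x ||w(x,·)||_L1``.

    The sup is taken over quadrature nodes and midpoints inside each radius;
    this is a lower bound of the true sup, reported as C_w on a pass.
    """
    if kernel.dimension != 1:
        raise NotImplementedError("C2' check implemented for N=1")
    radii = default_radii(kernel) if radii is None else np.asarray(radii, float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    h = _resolution(kernel, resolution)
    estimates = []
    for R in radii:
        ax = _axis(R, h)
        step = ax[1] - ax[0]
        xs = np.concatenate([ax, ax[:-1] + step / 2.0])[:, None]
        pts = ax[:, None]
        W = np.abs(kernel(xs[:, None, :], pts[None, :, :]))
        estimates.append(float(np.max(W.sum(axis=1) * step)))
    verdict, notes = _classify(radii, estimates, tol)
    constants = {"C_w": estimates[-1]} if verdict == PASS else {}
    return ConditionReport("C2'", list(radii), estimates, verdict, constants, notes)


def check_C1prime(kernel: Kernel, rho, Lambda: Optional[float] = None,
                  tol: float = 1e-6) -> ConditionReport:
    """Certify a supplied weight pair ``(ρ, Λ)`` for condition C1'.

    Computes ``max_y (∫ |w(x,y)| ρ(x) dx) / (Λ ρ(y))`` on ρ's grid; the check
    passes iff the ratio is at most ``1 + tol``.  The checker certifies a
    given pair only — it does not search for a weight.
    """
    grid = rho.grid
    Lam = rho.Lambda if Lambda is None else Lambda
    if Lam is None or Lam <= 0:
        raise ValueError("a positive Lambda is required")
    vals = np.asarray(rho.values, dtype=float)
    if np.any(vals <= 0):
        raise ValueError("rho must be strictly positive on the grid")
    if kernel.homogeneous and kernel.profile is not None:
        v = np.abs(kernel.profile_on_grid(grid))
        integral = circular_convolve(v, vals) * grid.cell_volume
    else:
        W = np.abs(kernel.matrix(grid))
        integral = (W.T @ vals.ravel()).reshape(grid.field_shape) * grid.cell_volume
    ratios = integral / (Lam * vals)
    ratio = float(np.max(ratios))
    verdict = PASS if ratio <= 1.0 + tol else FAIL
    return ConditionReport("C1'", [grid.half_width], [ratio], verdict,
                           {"Lambda": Lam, "ratio": ratio},
                           [f"max_y ratio = {ratio:.3e}"])


def check_C3prime(kernel: Kernel, probe_pairs: Optional[Sequence] = None,
                  tol: float = 0.1, radius: Optional[float] = None,
                  resolution: Optional[float] = None) -> ConditionReport:
    """Estimate the L1 shift-modulus exponent of the kernel.

    Computes ``m(δ) = ||w(x,·) − w(x+δ,·)||_L1`` at dyadic separations and
    regresses ``log m`` on ``log δ``; reports the slope ``alpha_hat`` and the
    constant ``L_w = max m(δ)/δ^alpha_hat``.  Passes iff the slope lies in
    ``(0, 1]`` within the stated tolerance band.
    """
    if kernel.dimension != 1:
        raise NotImplementedError("C3' check implemented for N=1")
    h = _resolution(kernel, resolution)
    R = 40.0 * kernel.length_scale if radius is None else radius
    if probe_pairs is None:
        base = kernel.length_scale
        seps = base * 2.0 ** np.arange(-6, -1)   # dyadic separations
        probe_pairs = [(0.0, s) for s in seps]
    ax = _axis(R, h)
    step = ax[1] - ax[0]
    seps, moduli = [], []
    pts = ax[:, None]
    for x, xt in probe_pairs:
        row = kernel(np.array([x]), pts) - kernel(np.array([xt]), pts)
        m = float(np.sum(np.abs(row)) * step)
        seps.append(abs(xt - x))
        moduli.append(m)
    seps = np.asarray(seps)
    moduli = np.asarray(moduli)
    if np.all(moduli == 0.0):
        return ConditionReport("C3'", list(seps), list(moduli), PASS,
                               {"L_w": 0.0}, ["constant kernel: zero modulus"])
    pos = (seps > 0) & (moduli > 0)
    if pos.sum() < 2:
        return ConditionReport("C3'", list(seps), list(moduli), INCONCLUSIVE,
                               {}, ["not enough positive separations"])
    A = np.vstack([np.log(seps[pos]), np.ones(pos.sum())]).T
    slope, intercept = np.linalg.lstsq(A, np.log(moduli[pos]), rcond=None)[0]
    L_w = float(np.max(moduli[pos] / seps[pos] ** slope))
    ok = (slope > tol / 10) and (slope <= 1.0 + tol)
    return ConditionReport("C3'", list(seps), list(moduli),
                           PASS if ok else FAIL,
                           {"alpha_hat": float(slope), "L_w": L_w},
                           [f"log-log slope {slope:.4f}"])


def counterexample_kernel() -> Kernel:
    """Separable kernel ``w(x,y) = (1+|x|)^{-1} (1+|y|)^{-1}``.

    Square-integrable over the plane (C1 holds) yet its inner L1 norm
    diverges for every ``x``, so C2 and C2' fail — the canonical example of a
    kernel for which the plain-L^2 formulation is ill-posed.
    """
    def evaluate(x, y):
        xs = np.asarray(x)[..., 0]
        ys = np.asarray(y)[..., 0]
        return 1.0 / ((1.0 + np.abs(xs)) * (1.0 + np.abs(ys)))

    return Kernel(evaluate=evaluate, dimension=1, homogeneous=False,
                  symmetric=True, analytic_l1=None, profile=None,
                  length_scale=1.0, name="separable_counterexample")
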