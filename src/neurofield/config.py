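"""JSON-serializable simulation configuration (pydantic schema).

A run is described by grid, kernel, gain, diffusion and smoothing-noise
blocks plus integrator settings; :func:`build` turns a validated config into
the live objects the solver consumes.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import kernels as K
from .grid import GridSpec
from .noise import SmoothingKernel, gaussian_smoothing, indicator_smoothing


class GridConfig(BaseModel):
    dimension: int = 1
    half_width: float = 10.0
    points_per_axis: int = 128


class KernelConfig(BaseModel):
    type: Literal["gaussian", "mexican_hat", "long_range", "pva",
                  "exponential", "zero"]
    K: float = 1.0
    beta: float = 1.0
    K1: float = 2.0
    K2: float = 1.0
    beta1: float = 1.0
    beta2: float = 2.0
    eps_lr: float = 0.1
    chi: float = 0.0
    beta_lr: float = 1.0
    beta_theta: float = 0.3
    n_pinwheels: int = 4
    orientation_seed: int = 0
    local: Optional["KernelConfig"] = None
    longrange: Optional["KernelConfig"] = None


class GainConfig(BaseModel):
    type: Literal["sigmoid", "constant", "zero"] = "sigmoid"
    value: float = 0.0


class DiffusionConfig(BaseModel):
    type: Literal["linear", "constant", "tanh", "zero"] = "constant"
    value: float = 1.0
    scale: float = 1.0


class PhiConfig(BaseModel):
    type: Literal["gaussian", "indicator", "zero"] = "gaussian"
    beta: float = 1.0
    amplitude: float = 1.0
    half_width: float = 0.5


class InitialConfig(BaseModel):
    type: Literal["constant", "bump", "random"] = "constant"
    value: float = 0.0
    amplitude: float = 1.0
    width: float = 1.0
    std: float = 1.0


class RunConfig(BaseModel):
    grid: GridConfig = Field(default_factory=GridConfig)
    kernel: KernelConfig = Field(default_factory=lambda: KernelConfig(type="gaussian"))
    gain: GainConfig = Field(default_factory=GainConfig)
    diffusion: DiffusionConfig = Field(default_factory=DiffusionConfig)
    phi: PhiConfig = Field(default_factory=PhiConfig)
    initial: InitialConfig = Field(default_factory=InitialConfig)
    time_horizon: float = 1.0
    dt: float = 1e-2
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.dt <= 0 or self.time_horizon < 0:
            raise ValueError("dt must be positive and time_horizon nonnegative")
        return self


def build_kernel(kc: KernelConfig, grid: GridSpec) -> K.Kernel:
    if kc.type == "gaussian":
        return K.gaussian_kernel(kc.K, kc.beta, grid.dimension)
    if kc.type == "mexican_hat":
        return K.mexican_hat_kernel(kc.K1, kc.K2, kc.beta1, kc.beta2, grid.dimension)
    if kc.type == "exponential":
        return K.exponential_kernel(kc.beta, grid.dimension)
    if kc.type == "zero":
        return K.zero_kernel(grid.dimension)
    if kc.type == "long_range":
        theta = K.orientation_map_synthetic(grid, kc.n_pinwheels, kc.orientation_seed)
        return K.long_range_kernel(kc.eps_lr, kc.chi, kc.beta_lr, kc.beta_theta, theta)
    if kc.type == "pva":
        if kc.local is None or kc.longrange is None:
            raise ValueError("pva kernel needs 'local' and 'longrange' blocks")
        return K.pva_kernel(build_kernel(kc.local, grid),
                            build_kernel(kc.longrange, grid))
    raise ValueError(f"unknown kernel type {kc.type}")


def build_phi(pc: PhiConfig, grid: GridSpec) -> SmoothingKernel:
    if pc.type == "gaussian":
        return gaussian_smoothing(grid, pc.beta, pc.amplitude)
    if pc.type == "indicator":
        return indicator_smoothing(grid, pc.half_width)
    from .noise import zero_smoothing
    return zero_smoothing(grid)


def build(rc: RunConfig) -> dict:
    grid = GridSpec(rc.grid.dimension, rc.grid.half_width, rc.grid.points_per_axis)
    gain = {"sigmoid": K.sigmoid_gain,
            "constant": lambda: K.constant_gain(rc.gain.value),
            "zero": lambda: K.constant_gain(0.0)}[rc.gain.type]()
    diffusion = {"linear": lambda: K.linear_diffusion(rc.diffusion.value),
                 "constant": lambda: K.constant_diffusion(rc.diffusion.value),
                 "tanh": lambda: K.bounded_diffusion(rc.diffusion.value, rc.diffusion.scale),
                 "zero": lambda: K.constant_diffusion(0.0)}[rc.diffusion.type]()
    return {"grid": grid, "kernel": build_kernel(rc.kernel, grid),
            "gain": gain, "diffusion": diffusion,
            "phi": build_phi(rc.phi, grid)}


def initial_condition(rc: RunConfig, grid: GridSpec) -> np.ndarray:
    ic = rc.initial
    if ic.type == "constant":
        return np.full(grid.field_shape, ic.value)
    if ic.type == "bump":
        mesh = np.stack(grid.mesh(), axis=-1)
        r2 = np.sum(mesh ** 2, axis=-1)
        return ic.value + ic.amplitude * np.exp(-r2 / (2 * ic.width ** 2))
    rng = np.random.default_rng(rc.seed + 10 ** 6)
    return rng.normal(ic.value, ic.std, size=grid.field_shape)
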