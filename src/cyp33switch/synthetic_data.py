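"""Seeded generators emulating the study's assay observations.

Each generator runs the corresponding forward model from :mod:`.assays` and
adds additive Gaussian noise at instrument-scale defaults (titration
σ = 0.005 ppm; ITC σ = 2% of the largest injection heat; PPIase σ = 1% of
the signal amplitude).  The same seed always produces bit-identical output,
and generator parameters travel with the data (``meta``/file headers) so
recovery tests never hard-code them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assays import (ITCThermogram, ProgressCurve, TitrationSeries,
                     S_CIS0_DEFAULT, itc_heats, ppiase_kobs, predict_shift)

__all__ = [
    "NoiseModel", "TitrationDesign", "ITCDesign", "PPIaseDesign",
    "gen_titration", "gen_itc", "gen_ppiase",
]

SIGMA_TITRATION = 0.005    # ppm
SIGMA_ITC_FRAC = 0.02      # fraction of max |heat|
SIGMA_PPIASE_FRAC = 0.01   # fraction of signal amplitude

#: enzyme grid of the coupled assay, μM (5–40 nM) plus an uncatalyzed blank
ENZYME_GRID_DEFAULT = (0.0, 0.005, 0.010, 0.020, 0.040)

#: default protein-observed reporter shifts, ppm (amide proton)
DELTA_FREE_DEFAULT = 8.30
DELTA_BOUND_DEFAULT = 8.10


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian observation noise."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, values: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        return np.asarray(values, dtype=float) + rng.normal(0.0, self.sigma,
                                                            size=np.shape(values))


@dataclass(frozen=True)
class TitrationDesign:
    p_total: float = 100.0                       # μM
    equivalents: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0,
                                      2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)

    @property
    def l_totals(self) -> np.ndarray:
        return self.p_total * np.asarray(self.equivalents)

    def widened(self, max_equivalents: float = 40.0) -> "TitrationDesign":
        """Extend the ligand range (used for weak binders)."""
        eq = np.unique(np.concatenate([
            np.asarray(self.equivalents),
            np.linspace(10.0, max_equivalents, 7),
        ]))
        return TitrationDesign(p_total=self.p_total, equivalents=tuple(eq))


@dataclass(frozen=True)
class ITCDesign:
    cell_volume: float = 200.0       # μL
    cell_conc: float = 50.0          # μM
    syringe_conc: float = 500.0      # μM
    n_injections: int = 20
    injection_volume: float = 2.0    # μL

    @property
    def injection_volumes(self) -> np.ndarray:
        return np.full(self.n_injections, self.injection_volume)


@dataclass(frozen=True)
class PPIaseDesign:
    enzyme_grid: tuple[float, ...] = ENZYME_GRID_DEFAULT   # μM
    substrate_cis0: float = S_CIS0_DEFAULT                 # μM
    t_end: float = 120.0                                   # s
    dt: float = 0.5                                        # s
    amplitude: float = 0.3       # absorbance span of full conversion
    k0: float = 0.02             # s⁻¹ uncatalyzed cis→trans background

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + self.dt / 2, self.dt)


def gen_titration(kd: float, delta_free: float = DELTA_FREE_DEFAULT,
                  delta_bound: float = DELTA_BOUND_DEFAULT,
                  design: TitrationDesign | None = None,
                  sigma: float = SIGMA_TITRATION, seed: int = 0) -> TitrationSeries:
    """Synthetic fast-exchange titration: forward model + Gaussian noise."""
    design = design or TitrationDesign()
    l = design.l_totals
    clean = np.array([predict_shift(design.p_total, li, kd, delta_free, delta_bound)
                      for li in l])
    obs = NoiseModel(sigma=sigma, seed=seed).apply(clean)
    return TitrationSeries(
        p_total=design.p_total, l_totals=l, observed_shifts=obs,
        delta_free=delta_free,
        meta={"kd": kd, "delta_free": delta_free, "delta_bound": delta_bound,
              "sigma": sigma, "seed": seed},
    )


def gen_itc(n: float, kd: float, dh: float,
            design: ITCDesign | None = None,
            sigma_frac: float = SIGMA_ITC_FRAC, seed: int = 0) -> ITCThermogram:
    """Synthetic incremental-injection thermogram with 2%-of-max noise."""
    design = design or ITCDesign()
    clean = itc_heats(n, kd, dh, design.cell_volume, design.cell_conc,
                      design.syringe_conc, design.injection_volumes)
    sigma = sigma_frac * float(np.max(np.abs(clean))) if clean.size else 0.0
    heats = NoiseModel(sigma=sigma, seed=seed).apply(clean)
    return ITCThermogram(
        cell_volume=design.cell_volume, cell_conc=design.cell_conc,
        syringe_conc=design.syringe_conc,
        injection_volumes=design.injection_volumes, heats=heats,
        meta={"n": n, "kd": kd, "dH": dh, "sigma": sigma, "seed": seed},
    )


def gen_ppiase(k0: float, turnover: float,
               design: PPIaseDesign | None = None,
               sigma_frac: float = SIGMA_PPIASE_FRAC,
               seed: int = 0) -> list[ProgressCurve]:
    """Synthetic coupled-assay progress curves across the enzyme grid."""
    design = design or PPIaseDesign()
    t = design.times
    curves = []
    for i, e in enumerate(design.enzyme_grid):
        k = ppiase_kobs(k0, turnover, e, design.substrate_cis0)
        clean = design.amplitude * (1.0 - np.exp(-k * t))
        sig = NoiseModel(sigma=sigma_frac * design.amplitude,
                         seed=seed * 1009 + i).apply(clean)
        curves.append(ProgressCurve(
            enzyme_conc=e, substrate_cis0=design.substrate_cis0,
            times=t, signal=sig,
            meta={"k0": k0, "turnover": turnover, "k_obs": k,
                  "sigma": sigma_frac * design.amplitude, "seed": seed},
        ))
    return curves
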