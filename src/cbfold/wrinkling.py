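"""Elastic bilayer wrinkling baseline.

A stiff film of thickness ``t`` and stiffness ``E_o`` on a softer substrate
of stiffness ``E_i`` wrinkles, under differential growth, at the wavelength

    lambda = 2 pi t (E_o / (3 E_i))^(1/3)

so a system of length ``l`` develops ``n = l / lambda`` folds; on a circle
of radius R the planar relation is applied with l = 2 pi R.  Inverting for
the stiffness ratio that yields a prescribed fold count,

    E_o / E_i = 3 (R / (n t))^3,

shows that three folds on the semicircular E16.5 cerebellum (six on the full
circle) with R/t = 16 would require a film roughly 57 times stiffer than the
core -- far beyond the ~1.05 bulk-modulus ratio measured acoustically, which
is the quantitative case against wrinkling as the folding mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class BilayerParams:
    """Film/substrate parameters: thickness t (um), stiffnesses E_o and E_i
    (any common unit), and system length l (um) or radius R (um, l = 2 pi R)."""

    t: float
    E_o: float
    E_i: float
    l: float | None = None
    R: float | None = None

    def __post_init__(self):
        if self.t <= 0 or self.E_o <= 0 or self.E_i <= 0:
            raise ValueError("thickness and stiffnesses must be positive")
        if self.l is None and self.R is None:
            raise ValueError("give the system length l or the radius R")
        if self.l is not None and self.l <= 0:
            raise ValueError("l must be positive")
        if self.R is not None and self.R <= 0:
            raise ValueError("R must be positive")
        if self.l is not None and self.R is not None:
            if not math.isclose(self.l, 2.0 * math.pi * self.R, rel_tol=1e-9):
                raise ValueError("l and R are inconsistent (need l = 2 pi R)")

    @property
    def length(self) -> float:
        return self.l if self.l is not None else 2.0 * math.pi * self.R


def wrinkle_wavelength(params: BilayerParams) -> float:
    """Wrinkling wavelength lambda = 2 pi t (E_o / (3 E_i))^(1/3), in um."""
    return 2.0 * math.pi * params.t * (params.E_o / (3.0 * params.E_i)) ** (1.0 / 3.0)


def fold_number(params: BilayerParams) -> float:
    """Number of folds n = l / lambda (l = 2 pi R in circular geometry)."""
    return params.length / wrinkle_wavelength(params)


def required_stiffness_ratio(n: float, R_over_t: float) -> float:
    """Film/substrate stiffness ratio needed for ``n`` folds on a circle with
    radius ``R_over_t`` film thicknesses: E_o/E_i = 3 (R_over_t / n)^3."""
    if n <= 0 or R_over_t <= 0:
        raise ValueError("n and R_over_t must be positive")
    return 3.0 * (R_over_t / n) ** 3


def wrinkling_report(
    t: float = 30.0,
    R_over_t: float = 16.0,
    stiffness_ratios=(1.05, 3.0, 10.0, 50.0, 56.9),
    target_folds: float = 6.0,
) -> pd.DataFrame:
    """Tabulate lambda and n over a stiffness-ratio grid, plus the ratio
    required for the target fold count."""
    rows = []
    for ratio in stiffness_ratios:
        p = BilayerParams(t=t, E_o=ratio, E_i=1.0, R=R_over_t * t)
        rows.append(
            {
                "stiffness_ratio": ratio,
                "wavelength_um": wrinkle_wavelength(p),
                "fold_number": fold_number(p),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["required_ratio_for_target"] = required_stiffness_ratio(target_folds, R_over_t)
    df.attrs["target_folds"] = target_folds
    df.attrs["R_over_t"] = R_over_t
    return df
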