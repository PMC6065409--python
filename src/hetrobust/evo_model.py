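"""Linear tumor-evolution model of mutant allele frequencies.

The model assumes that every driver mutation triggers a selective sweep.
Mutations predating the last sweep are clonal and sit at allele frequency
0.5 (heterozygous, pure diploid tumor); mutations arising afterwards evolve
neutrally and follow the classic 1/f tail.  The mixture is controlled by a
single parameter ``w``, the *neutral fraction*: the fraction of all somatic
mutations that arose after the last sweep.

The allele-frequency CDF is

    P(F <= f) = 0                            for f < f_min
              = (nu/2) (1/f_min - 1/f)       for f_min <= f < 0.5
              = 1                            at f = 0.5

with ``nu = 2 w f_min / (1 - 2 f_min)``; ``f_min`` is the minimum
measurable allele frequency (detection floor).  The clonal atom at 0.5
carries mass ``1 - w``.

The MATH heterogeneity score of this distribution has a closed form,
piecewise in ``w`` with boundaries at 1/2 and 1/2 + dw:

    MATH = 148.26 * { 0                              w <= 1/2
                    { 1/(2 phi) - 1                  1/2 < w <= 1/2 + dw
                    { (sqrt(nu^2 + phi^2) - nu)/phi  w > 1/2 + dw

where phi = nu f_min / (nu - f_min) is the distribution median in the
neutral regime, and dw = (sqrt(1 + 32 f_min^2) - 1) / (16 f_min).
The 148.26 prefactor is 100 (percentage) times 1.4826 (the
normal-consistency constant of the scaled MAD).
"""

from __future__ import annotations

import math as _math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EvoModelParams",
    "ClosedFormIntermediates",
    "closed_form_intermediates",
    "neutral_fraction_from_times",
    "af_cdf",
    "sample_afs",
    "math_closed_form",
    "add_read_noise",
    "degeneracy_surface",
    "MATH_PREFACTOR",
]

#: 100 (percentage) x 1.4826 (scaled-MAD normal-consistency constant)
MATH_PREFACTOR = 148.26


@dataclass(frozen=True)
class EvoModelParams:
    """Parameters of the linear-evolution AF model.

    w : neutral fraction in [0, 1].
    f_min : minimum measurable allele frequency, in (0, 0.5).
    n_snvs : number of SNVs drawn per simulated sample.
    read_depth : sequencing depth N used by the Gaussian noise model.
    t1, t2 : optional times (cell cycles) before/after the last sweep;
        when given they determine w via ``neutral_fraction_from_times``.
    seed : RNG seed for sampling.
    """

    w: float
    f_min: float = 0.1
    n_snvs: int = 300
    read_depth: int = 100
    t1: float | None = None
    t2: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must be in [0, 1], got {self.w}")
        if not 0.0 < self.f_min < 0.5:
            raise ValueError(f"f_min must be in (0, 0.5), got {self.f_min}")
        if self.n_snvs < 1:
            raise ValueError("n_snvs must be >= 1")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")


@dataclass(frozen=True)
class ClosedFormIntermediates:
    """Intermediate quantities of the closed-form MATH expression."""

    nu: float
    phi: float
    delta_w: float


def closed_form_intermediates(w: float, f_min: float) -> ClosedFormIntermediates:
    """Compute nu, phi and the branch half-width dw for given (w, f_min)."""
    nu = 2.0 * w * f_min / (1.0 - 2.0 * f_min)
    if nu == f_min:
        phi = _math.inf  # median limit as nu -> f_min from above
    else:
        phi = nu * f_min / (nu - f_min)
    delta_w = (_math.sqrt(1.0 + 32.0 * f_min**2) - 1.0) / (16.0 * f_min)
    return ClosedFormIntermediates(nu=nu, phi=phi, delta_w=delta_w)


def neutral_fraction_from_times(t1: float, t2: float) -> float:
    """Neutral fraction under exponential growth: w = 2^t2 / (t1 + 2^t2).

    Times are in cell cycles.  t1 = 0 gives w = 1 for any t2 (no clonal
    mutations accumulate before a sweep that happens immediately).
    """
    if t1 < 0 or t2 < 0:
        raise ValueError("t1 and t2 must be non-negative")
    pow2 = 2.0**t2
    return pow2 / (t1 + pow2)


def af_cdf(f, params: EvoModelParams):
    """Model CDF P(F <= f); accepts a scalar or array of f in [0, 0.5].

    Raises for f > 0.5: the model support ends at one half.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f > 0.5) or np.any(f < 0.0):
        raise ValueError("allele frequency must lie in [0, 0.5]")
    nu = closed_form_intermediates(params.w, params.f_min).nu
    out = np.zeros_like(f)
    neutral = (f >= params.f_min) & (f < 0.5)
    with np.errstate(divide="ignore"):
        out[neutral] = (nu / 2.0) * (1.0 / params.f_min - 1.0 / f[neutral])
    out[f == 0.5] = 1.0
    return out if out.ndim else float(out)


def sample_afs(params: EvoModelParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``params.n_snvs`` allele frequencies by inverse-CDF sampling.

    A uniform u < w lands in the neutral tail, where the CDF inverts to
    f = 1 / (1/f_min - 2u/nu); otherwise the draw is the clonal atom 0.5.
    Deterministic for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    u = rng.uniform(size=params.n_snvs)
    afs = np.full(params.n_snvs, 0.5)
    if params.w > 0:
        nu = closed_form_intermediates(params.w, params.f_min).nu
        neutral = u < params.w
        afs[neutral] = 1.0 / (1.0 / params.f_min - 2.0 * u[neutral] / nu)
    return afs


def math_closed_form(w: float, f_min: float = 0.1) -> float:
    """Closed-form MATH score (percent) of the model AF distribution.

    Zero throughout the clonal regime w <= 1/2 (more than half the mass
    sits on the clonal atom, so the MAD vanishes).  For w > 1/2 the median
    moves into the neutral tail (at phi) and the score grows with w, with
    a branch switch at w = 1/2 + dw where the MAD changes analytic form.
    Continuous at both branch boundaries.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must be in [0, 1], got {w}")
    ci = closed_form_intermediates(w, f_min)
    if w <= 0.5:
        return 0.0
    if w <= 0.5 + ci.delta_w:
        return MATH_PREFACTOR * (1.0 / (2.0 * ci.phi) - 1.0)
    return MATH_PREFACTOR * (_math.sqrt(ci.nu**2 + ci.phi**2) - ci.nu) / ci.phi


def add_read_noise(
    afs: np.ndarray,
    read_depth: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    clip: tuple[float, float] = (1e-3, 1.0 - 1e-3),
    refilter_f_min: float | None = None,
) -> np.ndarray:
    """Gaussian sequencing-noise model: f -> N(f, f(1-f)/N), clipped.

    Approximates binomial read sampling at depth ``read_depth``; draws are
    clipped into ``clip`` (rather than resampled) for determinism.  By
    default the measurement floor is NOT re-applied after noising; pass
    ``refilter_f_min`` to drop noised values below the floor again.
    """
    if read_depth < 1:
        raise ValueError("read_depth must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    afs = np.asarray(afs, dtype=float)
    sd = np.sqrt(afs * (1.0 - afs) / read_depth)
    noised = np.clip(rng.normal(afs, sd), clip[0], clip[1])
    if refilter_f_min is not None:
        noised = noised[noised >= refilter_f_min]
    return noised


def degeneracy_surface(t1_grid, t2_grid, f_min: float = 0.1):
    """Evaluate (w, MATH) over a (t1, t2) grid.

    Distinct histories (t1, t2) with equal w give bitwise-identical MATH:
    the score does not uniquely determine the evolutionary trajectory.
    Returns two arrays of shape (len(t1_grid), len(t2_grid)).
    """
    t1_grid = np.asarray(t1_grid, dtype=float)
    t2_grid = np.asarray(t2_grid, dtype=float)
    if t1_grid.size == 0 or t2_grid.size == 0:
        raise ValueError("grids must be non-empty")
    w = np.empty((t1_grid.size, t2_grid.size))
    math_grid = np.empty_like(w)
    for i, t1 in enumerate(t1_grid):
        for j, t2 in enumerate(t2_grid):
            w[i, j] = neutral_fraction_from_times(t1, t2)
            math_grid[i, j] = math_closed_form(w[i, j], f_min)
    return w, math_grid
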