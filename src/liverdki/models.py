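"""Forward signal models and parameter estimation for multi-b DWI.

Two signal representations are used for liver diffusion data:

* the kurtosis (non-Gaussian) model
  ``S(b) = S0 * exp(-b*D + b^2 * D^2 * K / 6)``,
  with corrected diffusivity ``D`` (mm^2/s, reported as MD at lesion level)
  and apparent kurtosis ``K`` (unitless, reported as MK), and
* the mono-exponential model ``S(b) = S0 * exp(-b*ADC)``, fitted from the
  b = 0 and b = 800 s/mm^2 points only.

Fitting is log-linear (quadratic-in-b least squares), exact on noiseless
data, with an optional signal-domain non-linear refinement.  Estimates are
kept inside a physiological box (``D`` in (1e-6, 5e-3) mm^2/s, ``K`` in
[0, 3]); any clamp is flagged, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .scheme import ADC_B_VALUE, AcquisitionScheme

# Physiological constraint box for liver tissue.
D_MIN = 1e-6  # mm^2/s
D_MAX = 5e-3  # mm^2/s
K_MAX = 3.0

#: relative noise floor: signals <= 0 are clipped to NOISE_FLOOR_FRACTION * S(0)
NOISE_FLOOR_FRACTION = 1e-6


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DKIParams:
    """Kurtosis-model parameters of one voxel or ROI.

    ``s0`` is the non-diffusion-weighted signal (arbitrary units, > 0),
    ``d`` the corrected diffusivity in mm^2/s (> 0) and ``k`` the apparent
    kurtosis (unitless, within [0, K_MAX]).
    """

    s0: float
    d: float
    k: float

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise ValueError(f"s0 must be > 0, got {self.s0}")
        if not self.d > 0:
            raise ValueError(f"d must be > 0, got {self.d}")
        if not 0 <= self.k <= K_MAX:
            raise ValueError(f"k must lie in [0, {K_MAX}], got {self.k}")


@dataclass(frozen=True)
class ADCParams:
    """Mono-exponential model parameters (apparent diffusion coefficient)."""

    s0: float
    adc: float

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise ValueError(f"s0 must be > 0, got {self.s0}")
        if not self.adc > 0:
            raise ValueError(f"adc must be > 0, got {self.adc}")


# ---------------------------------------------------------------------------
# Forward models
# ---------------------------------------------------------------------------


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return b


def dki_forward(params: DKIParams, b) -> np.ndarray | float:
    """Kurtosis-model signal ``S0 * exp(-b*D + b^2*D^2*K/6)`` at weighting b.

    ``b`` may be a scalar or array (s/mm^2); negative b is rejected.
    """
    barr = _check_b(b)
    s = params.s0 * np.exp(-barr * params.d + barr**2 * params.d**2 * params.k / 6.0)
    return float(s) if np.isscalar(b) else s


def adc_forward(params: ADCParams, b) -> np.ndarray | float:
    """Mono-exponential signal ``S0 * exp(-b*ADC)`` at weighting b."""
    barr = _check_b(b)
    s = params.s0 * np.exp(-barr * params.adc)
    return float(s) if np.isscalar(b) else s


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ADCFit:
    """Two-point ADC estimate with validity flag.

    ``adc <= 0`` (no attenuation, or signal increase with b) marks the fit
    invalid rather than clamping; ``flags`` lists the reasons.
    """

    s0: float
    adc: float
    valid: bool
    flags: tuple[str, ...] = ()

    @property
    def params(self) -> ADCParams:
        if not self.valid:
            raise ValueError(f"invalid ADC fit (flags={self.flags})")
        return ADCParams(self.s0, self.adc)


@dataclass(frozen=True)
class DKIFit:
    """Kurtosis-model estimate with validity and clamp bookkeeping."""

    s0: float
    d: float
    k: float
    valid: bool
    clamped: bool = False
    flags: tuple[str, ...] = ()

    @property
    def params(self) -> DKIParams:
        if not self.valid:
            raise ValueError(f"invalid DKI fit (flags={self.flags})")
        return DKIParams(self.s0, self.d, self.k)


# ---------------------------------------------------------------------------
# Scalar fits
# ---------------------------------------------------------------------------


def fit_adc_two_point(s_at_b0: float, s_at_b1: float, b1: float) -> ADCFit:
    """Closed-form ADC from signals at b = 0 and one nonzero b.

    ``adc = ln(S(0) / S(b1)) / b1``.  Non-positive signals raise; a
    non-positive ADC (``S(b1) >= S(0)``) is flagged invalid, not clamped.
    """
    if b1 <= 0:
        raise ValueError("b1 must be > 0")
    if s_at_b0 <= 0 or s_at_b1 <= 0:
        raise ValueError(
            f"signals must be positive for the log-domain ADC fit "
            f"(got S(0)={s_at_b0}, S(b1)={s_at_b1})"
        )
    adc = float(np.log(s_at_b0 / s_at_b1) / b1)
    valid = adc > 0
    flags = () if valid else ("nonpositive_adc",)
    return ADCFit(s0=float(s_at_b0), adc=adc, valid=valid, flags=flags)


def _clamp_dk(d: float, k: float) -> tuple[float, float, bool, tuple[str, ...]]:
    flags: list[str] = []
    if d > D_MAX:
        d = D_MAX
        flags.append("clamped_d_high")
    elif d < D_MIN:
        d = D_MIN
        flags.append("clamped_d_low")
    if k < 0:
        k = 0.0
        flags.append("clamped_k_low")
    elif k > K_MAX:
        k = K_MAX
        flags.append("clamped_k_high")
    return d, k, bool(flags), tuple(flags)


def fit_dki_loglinear(signals: Sequence[float], scheme: AcquisitionScheme) -> DKIFit:
    """Log-domain quadratic least-squares fit of the kurtosis model.

    Fits ``ln S(b) = c0 - c1*b + c2*b^2`` (unweighted) over the scheme and
    maps ``S0 = exp(c0)``, ``D = c1``, ``K = 6*c2/D^2``.  Exact on noiseless
    data.  Signals <= 0 are clipped to a small fraction of S(0) and flagged;
    a non-positive fitted diffusivity marks the voxel invalid.
    """
    s = np.asarray(signals, dtype=float)
    if s.shape != (len(scheme),):
        raise ValueError(f"expected {len(scheme)} signals, got shape {s.shape}")
    if not scheme.supports_kurtosis_fit:
        raise ValueError("kurtosis fit needs at least 3 b-values")

    flags: list[str] = []
    if s[0] <= 0:
        return DKIFit(np.nan, np.nan, np.nan, valid=False, flags=("nonpositive_s0",))
    floor = NOISE_FLOOR_FRACTION * s[0]
    if np.any(s <= 0):
        s = np.maximum(s, floor)
        flags.append("noise_floor")

    b = scheme.b
    design = np.column_stack([np.ones_like(b), -b, b**2])
    coef, *_ = np.linalg.lstsq(design, np.log(s), rcond=None)
    c0, c1, c2 = coef
    s0 = float(np.exp(c0))
    d = float(c1)
    if d <= 0:
        return DKIFit(s0, d, np.nan, valid=False, flags=tuple(flags) + ("nonphysical_d",))
    k = float(6.0 * c2 / d**2)
    d, k, clamped, clamp_flags = _clamp_dk(d, k)
    return DKIFit(s0, d, k, valid=True, clamped=clamped, flags=tuple(flags) + clamp_flags)


def _dki_objective(s0: float, d: float, k: float, s: np.ndarray, b: np.ndarray) -> float:
    model = s0 * np.exp(-b * d + b**2 * d**2 * k / 6.0)
    return float(np.sum((s - model) ** 2))


def fit_dki_nls(
    signals: Sequence[float],
    scheme: AcquisitionScheme,
    init: DKIFit | DKIParams,
    max_nfev: int = 200,
) -> DKIFit:
    """Signal-domain non-linear refinement of a kurtosis fit.

    Box-constrained least squares on ``sum_b (S_obs - S_model)^2`` starting
    from ``init`` (typically the log-linear estimate).  Returns the start
    point, flagged, whenever the optimiser does not improve the objective.
    """
    s = np.asarray(signals, dtype=float)
    if s.shape != (len(scheme),):
        raise ValueError(f"expected {len(scheme)} signals, got shape {s.shape}")
    b = scheme.b

    x0 = np.array(
        [init.s0, np.clip(init.d, D_MIN, D_MAX), np.clip(init.k, 0.0, K_MAX)], dtype=float
    )
    init_fit = (
        init
        if isinstance(init, DKIFit)
        else DKIFit(init.s0, init.d, init.k, valid=True)
    )
    obj0 = _dki_objective(*x0, s, b)

    def residuals(x: np.ndarray) -> np.ndarray:
        return x[0] * np.exp(-b * x[1] + b**2 * x[1] ** 2 * x[2] / 6.0) - s

    lower = [1e-12, D_MIN, 0.0]
    upper = [np.inf, D_MAX, K_MAX]
    try:
        res = least_squares(residuals, x0, bounds=(lower, upper), max_nfev=max_nfev)
    except Exception:
        return DKIFit(
            init_fit.s0, init_fit.d, init_fit.k, init_fit.valid,
            init_fit.clamped, init_fit.flags + ("nls_failed",),
        )
    obj1 = _dki_objective(*res.x, s, b)
    if not res.success or obj1 > obj0:
        return DKIFit(
            init_fit.s0, init_fit.d, init_fit.k, init_fit.valid,
            init_fit.clamped, init_fit.flags + ("nls_no_improvement",),
        )
    s0, d, k = (float(v) for v in res.x)
    d, k, clamped, clamp_flags = _clamp_dk(d, k)
    return DKIFit(s0, d, k, valid=True, clamped=clamped, flags=clamp_flags)


# ---------------------------------------------------------------------------
# Voxel-wise maps
# ---------------------------------------------------------------------------


@dataclass
class ParameterMaps:
    """Per-voxel parameter maps sharing one grid and voxel spacing.

    Voxels outside the fit-validity masks (or outside the input mask) hold
    NaN — missing values are never silently zero.  ``valid`` marks voxels
    where both the kurtosis and the ADC fit are physical.
    """

    s0: np.ndarray
    md: np.ndarray
    mk: np.ndarray
    adc: np.ndarray
    valid: np.ndarray
    spacing: tuple[float, ...]
    clamped: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = self.s0.shape
        for name in ("md", "mk", "adc", "valid"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"map '{name}' shape {arr.shape} != grid {shape}")
        if len(self.spacing) != self.s0.ndim:
            raise ValueError("spacing length must match grid dimensionality")
        if self.clamped is None:
            self.clamped = np.zeros(shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.s0.shape


def fit_parameter_maps(
    volume: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray | None = None,
    spacing: tuple[float, ...] | None = None,
    refine: bool = False,
    adc_b: float = ADC_B_VALUE,
) -> ParameterMaps:
    """Voxel-wise ADC and kurtosis fits over a 4-D (or 3-D planar) stack.

    ``volume`` has the b-dimension last and must match the scheme length;
    ``mask`` restricts fitting (voxels outside are missing in the output).
    The kurtosis fit is the vectorised log-linear solve; ``refine=True``
    runs the non-linear refinement per masked voxel.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.shape[-1] != len(scheme):
        raise ValueError(
            f"last axis ({vol.shape[-1]}) must equal scheme length ({len(scheme)})"
        )
    grid = vol.shape[:-1]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} != spatial grid {grid}")
    if spacing is None:
        spacing = (1.0,) * len(grid)

    b = scheme.b
    i_b1 = scheme.index_of(adc_b)
    sig = vol[mask]  # (nvox, nb)
    nvox = sig.shape[0]

    s0_map = np.full(grid, np.nan)
    md_map = np.full(grid, np.nan)
    mk_map = np.full(grid, np.nan)
    adc_map = np.full(grid, np.nan)
    valid_map = np.zeros(grid, dtype=bool)
    clamped_map = np.zeros(grid, dtype=bool)
    if nvox == 0:
        return ParameterMaps(s0_map, md_map, mk_map, adc_map, valid_map, tuple(spacing), clamped_map)

    pos_b0 = sig[:, 0] > 0
    floor = np.where(pos_b0, NOISE_FLOOR_FRACTION * sig[:, 0], np.nan)
    clipped = np.maximum(sig, floor[:, None])

    # -- kurtosis model, one lstsq for every voxel ----------------------
    design = np.column_stack([np.ones_like(b), -b, b**2])
    with np.errstate(invalid="ignore", divide="ignore"):
        logs = np.log(np.where(pos_b0[:, None], clipped, np.nan))
    coef = np.full((3, nvox), np.nan)
    coef[:, pos_b0] = np.linalg.lstsq(design, logs[pos_b0].T, rcond=None)[0]
    s0 = np.exp(coef[0])
    d = coef[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        k = 6.0 * coef[2] / d**2
    dki_valid = pos_b0 & (d > 0)
    clamped = dki_valid & ((d < D_MIN) | (d > D_MAX) | (k < 0) | (k > K_MAX))
    d = np.clip(d, D_MIN, D_MAX)
    k = np.clip(k, 0.0, K_MAX)

    # -- two-point ADC ---------------------------------------------------
    pos_pair = pos_b0 & (sig[:, i_b1] > 0)
    adc = np.full(nvox, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        adc[pos_pair] = np.log(sig[pos_pair, 0] / sig[pos_pair, i_b1]) / b[i_b1]
    adc_valid = pos_pair & (adc > 0)

    if refine:
        idx = np.flatnonzero(dki_valid)
        for i in idx:
            init = DKIFit(float(s0[i]), float(d[i]), float(k[i]), valid=True)
            ref = fit_dki_nls(clipped[i], scheme, init)
            s0[i], d[i], k[i] = ref.s0, ref.d, ref.k
            clamped[i] |= ref.clamped

    valid = dki_valid & adc_valid
    s0_map[mask] = np.where(dki_valid, s0, np.nan)
    md_map[mask] = np.where(dki_valid, d, np.nan)
    mk_map[mask] = np.where(dki_valid, k, np.nan)
    adc_map[mask] = np.where(adc_valid, adc, np.nan)
    valid_map[mask] = valid
    clamped_map[mask] = clamped
    return ParameterMaps(s0_map, md_map, mk_map, adc_map, valid_map, tuple(spacing), clamped_map)
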