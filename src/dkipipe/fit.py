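"""Per-voxel tensor estimation by linearized least squares.

The DKI signal equation is linear in the 21 tensor components once the
kurtosis term is re-parameterized as the composite B = MD^2 * W: the
unknown vector is x = [ln S0, D (6), B (15)] and the design matrix rows
are the corresponding monomials in b and the gradient direction.  After
the linear solve, MD is computed from the fitted D and W is recovered as
B / MD^2.  Separating D from W requires at least two distinct nonzero
b-values (shells).

The default weighting is signal-weighted least squares: an ordinary fit
provides predicted signals whose squares become row weights in one
refinement pass, counteracting the heteroscedasticity introduced by the
log transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import (
    D_COMPONENT_INDICES,
    D_MULTIPLICITY,
    FLAG_CLIPPED_SIGNAL,
    FLAG_DEGENERATE_MD,
    GradientScheme,
    DiffusionTensor,
    KurtosisTensor,
    TensorPair,
    W_COMPONENT_INDICES,
    W_MULTIPLICITY,
)

__all__ = ["DesignMatrix", "FitOptions", "build_design_matrix", "fit_voxel", "fit_volume"]

N_PARAMS = 22  # ln S0 + 6 D components + 15 W composites


@dataclass(frozen=True)
class DesignMatrix:
    """Linearized DKI design: measurements x 22 (intercept, D, B columns)."""

    matrix: np.ndarray
    scheme: GradientScheme

    @property
    def condition_number(self) -> float:
        s = np.linalg.svd(self.matrix, compute_uv=False)
        return float(s[0] / s[-1]) if s[-1] > 0 else np.inf


@dataclass(frozen=True)
class FitOptions:
    """Solver options for the linear tensor fit.

    weighting      'wls' (signal-weighted, default) or 'ols'.
    signal_floor   positive clip for nonpositive signals before the log;
                   if None, 1e-6 times the voxel's maximum signal.
    min_mean_diffusivity
                   MD^2 below this is treated as degenerate: W cannot be
                   rescaled and is reported as flagged zeros.
    max_condition  design-matrix conditioning guard.
    """

    weighting: str = "wls"
    signal_floor: float | None = None
    min_mean_diffusivity: float = 1e-12
    max_condition: float = 1e8

    def __post_init__(self) -> None:
        if self.weighting not in ("wls", "ols"):
            raise ValueError("weighting must be 'wls' or 'ols'")
        if self.signal_floor is not None and not self.signal_floor > 0:
            raise ValueError("signal_floor must be positive")


def build_design_matrix(scheme: GradientScheme) -> DesignMatrix:
    """Build the measurements x 22 design for the linearized signal model.

    Off-diagonal / repeated-index columns carry their combinatorial
    multiplicities (2 for D12-type terms; 4, 6 and 12 for the kurtosis
    index patterns) so the canonical independent components are recovered
    directly from the solution vector.

    Raises if fewer than two distinct nonzero b-values are present: with a
    single shell the b and b^2 terms are collinear and D and W cannot be
    separated.
    """
    b = scheme.bvalues
    n = scheme.directions
    if np.unique(b[b > 0]).size < 2:
        raise ValueError(
            "underdetermined scheme: need >= 2 distinct nonzero b-values to separate D and W"
        )
    scheme.validate_for_fitting()

    cols = [np.ones_like(b)]
    for mult, (i, j) in zip(D_MULTIPLICITY, D_COMPONENT_INDICES):
        cols.append(-b * mult * n[:, i] * n[:, j])
    for mult, (i, j, k, l) in zip(W_MULTIPLICITY, W_COMPONENT_INDICES):
        cols.append((b * b / 6.0) * mult * n[:, i] * n[:, j] * n[:, k] * n[:, l])
    a = np.column_stack(cols)
    a[scheme.b0_mask, 1:] = 0.0  # direction is meaningless at b=0
    return DesignMatrix(matrix=a, scheme=scheme)


def _prepare_log_signals(
    signals: np.ndarray, signal_floor: float | None
) -> tuple[np.ndarray, np.ndarray]:
    """Clip nonpositive signals to the floor and take the log.

    Returns (log-signals, clipped-mask) with shapes matching the input.
    """
    s = np.asarray(signals, dtype=float)
    if signal_floor is None:
        peak = np.max(s, axis=-1, keepdims=True)
        floor = 1e-6 * np.where(peak > 0, peak, 1.0)
    else:
        floor = np.full(s.shape[:-1] + (1,), signal_floor)
    clipped = s < floor
    return np.log(np.where(clipped, floor, s)), clipped


def _solve_batch(
    design: np.ndarray, log_s: np.ndarray, weighting: str
) -> np.ndarray:
    """Solve the linear system for a batch of voxels.

    log_s has shape (V, M); returns parameter array (V, 22).
    """
    pinv = np.linalg.pinv(design)
    x = log_s @ pinv.T  # ordinary LS for every voxel at once
    if weighting == "wls":
        # one refinement pass: weights = squared predicted signals
        pred = x @ design.T
        w = np.exp(2.0 * np.clip(pred, -700, 700))
        aw = design[None, :, :] * w[:, :, None]  # (V, M, 22)
        ata = np.einsum("vmp,mq->vpq", aw, design)
        atb = np.einsum("vmp,vm->vp", aw, log_s)
        try:
            x = np.linalg.solve(ata, atb[..., None])[..., 0]
        except np.linalg.LinAlgError:
            x = np.stack(
                [np.linalg.lstsq(a, b, rcond=None)[0] for a, b in zip(ata, atb)]
            )
    return x


def _params_to_pairs(
    x: np.ndarray, clipped_any: np.ndarray, min_md: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split solution vectors into (s0, D6, W15, flags) arrays."""
    s0 = np.exp(x[:, 0])
    d6 = x[:, 1:7]
    bcomp = x[:, 7:22]
    md = d6[:, :3].sum(axis=1) / 3.0
    md2 = md * md
    degenerate = md2 < min_md
    w15 = np.zeros_like(bcomp)
    ok = ~degenerate
    w15[ok] = bcomp[ok] / md2[ok, None]
    flags = np.zeros(x.shape[0], dtype=np.int32)
    flags[clipped_any] |= FLAG_CLIPPED_SIGNAL
    flags[degenerate] |= FLAG_DEGENERATE_MD
    return s0, d6, w15, flags


def fit_voxel(
    signals: np.ndarray,
    scheme: GradientScheme,
    options: FitOptions = FitOptions(),
    design: DesignMatrix | None = None,
) -> TensorPair:
    """Estimate one voxel's TensorPair from its measured signals."""
    s = np.asarray(signals, dtype=float).ravel()
    if s.size != scheme.n_measurements:
        raise ValueError("signal count does not match the gradient scheme")
    if not np.any(s[scheme.b0_mask] > 0):
        raise ValueError("no positive b=0 signal; cannot anchor S0")
    if design is None:
        design = build_design_matrix(scheme)
    if design.condition_number > options.max_condition:
        raise ValueError("design matrix is rank deficient or ill conditioned")
    log_s, clipped = _prepare_log_signals(s[None, :], options.signal_floor)
    x = _solve_batch(design.matrix, log_s, options.weighting)
    s0, d6, w15, flags = _params_to_pairs(
        x, clipped.any(axis=-1), options.min_mean_diffusivity
    )
    return TensorPair(
        D=DiffusionTensor(d6[0]),
        W=KurtosisTensor(w15[0]),
        s0=float(s0[0]),
        fit_flags=int(flags[0]),
    )


def fit_volume(
    volume: np.ndarray,
    mask: np.ndarray,
    scheme: GradientScheme,
    options: FitOptions = FitOptions(),
) -> dict[str, np.ndarray]:
    """Fit every in-mask voxel of a 4-D volume (x, y, z, measurement).

    Returns a dict of maps on the input grid: 'D' (..., 6), 'W' (..., 15),
    's0' (...), 'flags' (...).  Out-of-mask voxels are exact zeros, which
    downstream zero-pruning relies on.
    """
    vol = np.asarray(volume, dtype=float)
    msk = np.asarray(mask).astype(bool)
    if vol.ndim != 4 or vol.shape[-1] != scheme.n_measurements:
        raise ValueError("volume must be 4-D with last axis matching the scheme")
    if msk.shape != vol.shape[:3]:
        raise ValueError("mask grid does not match volume grid")

    grid = vol.shape[:3]
    out = {
        "D": np.zeros(grid + (6,)),
        "W": np.zeros(grid + (15,)),
        "s0": np.zeros(grid),
        "flags": np.zeros(grid, dtype=np.int32),
    }
    if not msk.any():
        warnings.warn("empty ROI mask: nothing to fit", stacklevel=2)
        return out

    design = build_design_matrix(scheme)
    if design.condition_number > options.max_condition:
        raise ValueError("design matrix is rank deficient or ill conditioned")

    sig = vol[msk]  # (V, M)
    log_s, clipped = _prepare_log_signals(sig, options.signal_floor)
    x = _solve_batch(design.matrix, log_s, options.weighting)
    s0, d6, w15, flags = _params_to_pairs(
        x, clipped.any(axis=-1), options.min_mean_diffusivity
    )
    out["D"][msk] = d6
    out["W"][msk] = w15
    out["s0"][msk] = s0
    out["flags"][msk] = flags
    return out
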