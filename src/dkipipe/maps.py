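"""Scalar biomarker maps derived from fitted tensors: MD, FA, MK.

MD is the trace of the diffusion tensor over 3; FA the standard
normalized eigenvalue dispersion; MK the uniform average of the
directional kurtosis over a deterministic, antipodally symmetric set of
unit directions (a Fibonacci hemisphere lattice mirrored through the
origin).  The exact closed-form MK integral is deliberately not used —
the directional average is reproducible, and converges rapidly because
the integrand is a smooth even function on the sphere.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .model import (
    FLAG_DEGENERATE_MD,
    DiffusionTensor,
    TensorPair,
)

__all__ = [
    "mean_diffusivity",
    "fractional_anisotropy",
    "mean_kurtosis",
    "sphere_directions",
    "scalar_maps_volume",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def mean_diffusivity(D: DiffusionTensor) -> float:
    """Trace/3, equal to the mean of the eigenvalues. Units mm^2/s."""
    return D.mean_diffusivity


def fractional_anisotropy(D: DiffusionTensor) -> float:
    """FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, in [0, 1]."""
    lam = np.linalg.eigvalsh(D.to_matrix())
    norm = np.linalg.norm(lam)
    if norm == 0:
        raise ValueError("FA is undefined for the zero tensor")
    return float(np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / norm)


@lru_cache(maxsize=16)
def _hemisphere_lattice(half: int, refine: int) -> np.ndarray:
    i = np.arange(half)
    z = (i + 0.5) / half  # stratified in (0, 1): upper hemisphere
    theta = _GOLDEN_ANGLE * i
    r = np.sqrt(1.0 - z * z)
    h = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # fixed-step electrostatic repulsion between all points and all
    # antipodes; deterministic, smooths the lattice's equator seam
    for _ in range(refine):
        diff = h[:, None, :] - h[None, :, :]
        d2 = (diff**2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        anti = h[:, None, :] + h[None, :, :]
        d2a = (anti**2).sum(-1)
        np.fill_diagonal(d2a, np.inf)
        force = (diff / d2[..., None] ** 1.5).sum(1) + (anti / d2a[..., None] ** 1.5).sum(1)
        h = h + (0.1 / half) * force
        h /= np.linalg.norm(h, axis=1, keepdims=True)
    h.setflags(write=False)
    return h


def sphere_directions(n: int, refine: int = 100) -> np.ndarray:
    """Deterministic, approximately uniform, antipodally symmetric directions.

    Places n/2 points on the upper hemisphere by a Fibonacci spiral,
    relaxes them with a fixed number of electrostatic-repulsion steps
    (interacting with the mirrored set as well, so the relaxed set stays
    balanced) and returns the points together with their antipodes.
    n must be even and >= 2.
    """
    if n < 2 or n % 2:
        raise ValueError("n must be an even integer >= 2")
    half = n // 2
    if half > 1024:
        refine = 0  # dense lattices are already uniform; relaxation is O(n^2)
    pts = _hemisphere_lattice(half, refine)
    return np.vstack([pts, -pts])


def mean_kurtosis(
    tensors: TensorPair, n_directions: int = 256, md_tol: float = 1e-12
) -> float:
    """Directional average of the apparent kurtosis K(n) over the sphere.

    Vectorized over the direction set; requires a non-degenerate mean
    diffusivity (flagged voxels propagate their flag as an error).
    """
    if n_directions < 60:
        raise ValueError("n_directions must be >= 60 for a stable directional average")
    if tensors.fit_flags & FLAG_DEGENERATE_MD:
        raise ValueError("voxel flagged degenerate mean diffusivity; MK undefined")
    md = tensors.D.mean_diffusivity
    if md * md <= md_tol * md_tol:
        raise ValueError("mean diffusivity is degenerate; MK undefined")
    n = sphere_directions(n_directions)
    dm = tensors.D.to_matrix()
    wa = tensors.W.to_array()
    dn = np.einsum("mi,mj,ij->m", n, n, dm)
    if np.any(np.abs(dn) <= md_tol):
        raise ValueError("directional diffusivity degenerate along a sample direction")
    wn = np.einsum("mi,mj,mk,ml,ijkl->m", n, n, n, n, wa)
    return float(np.mean((md * md) / (dn * dn) * wn))


def _direction_monomials(n: np.ndarray):
    """Multiplicity-weighted direction monomials for the canonical 6- and
    15-component orderings, shapes (M, 6) and (M, 15)."""
    from .model import (
        D_COMPONENT_INDICES,
        D_MULTIPLICITY,
        W_COMPONENT_INDICES,
        W_MULTIPLICITY,
    )

    m2 = np.stack(
        [mult * n[:, i] * n[:, j] for mult, (i, j) in zip(D_MULTIPLICITY, D_COMPONENT_INDICES)],
        axis=1,
    )
    m4 = np.stack(
        [
            mult * n[:, i] * n[:, j] * n[:, k] * n[:, l]
            for mult, (i, j, k, l) in zip(W_MULTIPLICITY, W_COMPONENT_INDICES)
        ],
        axis=1,
    )
    return m2, m4


def scalar_maps_volume(
    tensor_maps: dict[str, np.ndarray],
    mask: np.ndarray,
    n_directions: int = 256,
) -> dict[str, np.ndarray]:
    """Vectorized MD / FA / MK maps from fitted tensor maps.

    ``tensor_maps`` is the dict returned by ``fit_volume``; out-of-mask
    voxels are zeros.  Degenerate voxels (MD ~ 0) get NaN for FA and MK.
    """
    msk = np.asarray(mask).astype(bool)
    d6 = tensor_maps["D"][msk]  # (V, 6)
    w15 = tensor_maps["W"][msk]  # (V, 15)

    md = d6[:, :3].sum(axis=1) / 3.0

    # FA via batched eigendecomposition of the 3x3 expansions
    dm = np.zeros((d6.shape[0], 3, 3))
    dm[:, 0, 0], dm[:, 1, 1], dm[:, 2, 2] = d6[:, 0], d6[:, 1], d6[:, 2]
    dm[:, 0, 1] = dm[:, 1, 0] = d6[:, 3]
    dm[:, 0, 2] = dm[:, 2, 0] = d6[:, 4]
    dm[:, 1, 2] = dm[:, 2, 1] = d6[:, 5]
    lam = np.linalg.eigvalsh(dm)
    norm = np.linalg.norm(lam, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5) * np.linalg.norm(lam - lam.mean(axis=1, keepdims=True), axis=1) / norm
    fa[norm == 0] = np.nan

    # MK: directional average using multiplicity-weighted monomials
    n = sphere_directions(n_directions)
    m2, m4 = _direction_monomials(n)
    dn = d6 @ m2.T  # (V, M) directional diffusivities
    wn = w15 @ m4.T
    with np.errstate(divide="ignore", invalid="ignore"):
        mk = np.mean((md[:, None] ** 2) / (dn**2) * wn, axis=1)
    mk[np.abs(md) < 1e-12] = np.nan

    out = {}
    for name, vals in (("MD", md), ("FA", fa), ("MK", mk)):
        grid = np.zeros(msk.shape)
        grid[msk] = vals
        out[name] = grid
    return out
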