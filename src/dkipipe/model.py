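"""Tensor types and the DKI forward signal model.

The diffusion-weighted signal in diffusion kurtosis imaging is modelled
by the fourth-order cumulant expansion

    ln S(b, n) = ln S0 - b * sum_ij n_i n_j D_ij
                 + (b^2 * MD^2 / 6) * sum_ijkl n_i n_j n_k n_l W_ijkl

where ``b`` is the diffusion weighting (s/mm^2), ``n`` a unit gradient
direction, ``D`` the symmetric order-2 diffusion tensor (mm^2/s),
``MD = tr(D)/3`` the mean diffusivity and ``W`` the fully symmetric
order-4, dimensionless kurtosis tensor.  Symmetry leaves 6 independent
components in ``D`` and 15 in ``W``; this module fixes the canonical
component ordering used throughout the package.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "D_COMPONENT_INDICES",
    "W_COMPONENT_INDICES",
    "D_MULTIPLICITY",
    "W_MULTIPLICITY",
    "GradientScheme",
    "DiffusionTensor",
    "KurtosisTensor",
    "TensorPair",
    "predict_log_signal",
    "directional_diffusivity",
    "directional_kurtosis",
    "count_independent_components",
    "isotropic_kurtosis_tensor",
]

# Canonical ordering of the independent components (0-based indices).
D_COMPONENT_INDICES: tuple[tuple[int, int], ...] = (
    (0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2),
)
W_COMPONENT_INDICES: tuple[tuple[int, int, int, int], ...] = (
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1),
    (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
)


def _multiplicity(idx: tuple[int, ...]) -> int:
    """Number of distinct orderings of an index multiset."""
    counts = [idx.count(v) for v in set(idx)]
    m = math.factorial(len(idx))
    for c in counts:
        m //= math.factorial(c)
    return m


D_MULTIPLICITY = np.array([_multiplicity(i) for i in D_COMPONENT_INDICES])
W_MULTIPLICITY = np.array([_multiplicity(i) for i in W_COMPONENT_INDICES])


def count_independent_components(order: int, dimension: int) -> int:
    """Number of independent components of a fully symmetric tensor.

    Equals the number of index multisets, C(dimension + order - 1, order):
    6 for an order-2 tensor in 3-D, 15 for an order-4 tensor in 3-D, so a
    DKI signal carries 21 independent tensor components.
    """
    if order < 0 or dimension < 1:
        raise ValueError("order must be >= 0 and dimension >= 1")
    return math.comb(dimension + order - 1, order)


def enumerate_index_orbits(order: int, dimension: int) -> list[tuple[int, ...]]:
    """Sorted-representative enumeration of index-permutation orbits.

    Brute-force companion to :func:`count_independent_components`.
    """
    return sorted(
        {tuple(sorted(t)) for t in itertools.product(range(dimension), repeat=order)}
    )


@dataclass(frozen=True)
class GradientScheme:
    """Acquisition geometry: b-values and unit gradient directions.

    Parameters
    ----------
    bvalues : (M,) array
        Diffusion weighting per measurement, s/mm^2, all >= 0.
    directions : (M, 3) array
        Unit direction vectors; arbitrary (ignored) for b=0 entries.
    """

    bvalues: np.ndarray
    directions: np.ndarray
    _shell_ids: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float).ravel()
        d = np.asarray(self.directions, dtype=float)
        if d.shape == (3, b.size) and d.shape[0] != d.shape[1]:
            d = d.T
        if d.shape != (b.size, 3):
            raise ValueError(f"directions shape {d.shape} does not match {b.size} b-values")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(d, axis=1)
        bad = (b > 0) & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            raise ValueError(
                f"{bad.sum()} direction(s) with b>0 are not unit vectors (norm tol 1e-6)"
            )
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", d)
        # shells indexed by sorted unique b-value
        _, ids = np.unique(b, return_inverse=True)
        object.__setattr__(self, "_shell_ids", ids.astype(int))

    @property
    def shell_ids(self) -> np.ndarray:
        return self._shell_ids

    @property
    def n_measurements(self) -> int:
        return self.bvalues.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    def validate_for_fitting(self) -> None:
        """Require at least one b=0 entry (anchors the absolute signal)."""
        if not np.any(self.b0_mask):
            raise ValueError("scheme has no b=0 measurement; absolute-signal fit impossible")

    @classmethod
    def from_bval_bvec(cls, bval_path, bvec_path) -> "GradientScheme":
        """Read an FSL-style gradient table (whitespace-delimited).

        The bvec file holds three rows (x, y, z components).
        """
        b = np.loadtxt(bval_path).ravel()
        v = np.atleast_2d(np.loadtxt(bvec_path))
        if v.shape[0] == 3:
            v = v.T
        # FSL writes (0,0,0) for b=0 rows; substitute a placeholder unit vector
        zero = np.linalg.norm(v, axis=1) == 0
        v = v.copy()
        v[zero] = (1.0, 0.0, 0.0)
        return cls(bvalues=b, directions=v)

    def to_bval_bvec(self, bval_path, bvec_path) -> None:
        np.savetxt(bval_path, self.bvalues[None, :], fmt="%.1f")
        v = self.directions.copy()
        v[self.b0_mask] = 0.0
        np.savetxt(bvec_path, v.T, fmt="%.8f")


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric order-2 diffusion tensor, mm^2/s.

    Stored as the canonical 6-vector [D11, D22, D33, D12, D13, D23].
    """

    components: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float).ravel()
        if c.size != 6:
            raise ValueError("DiffusionTensor needs exactly 6 components")
        object.__setattr__(self, "components", c)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "DiffusionTensor":
        m = np.asarray(m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("expected a 3x3 matrix")
        if not np.allclose(m, m.T, atol=1e-12 + 1e-9 * np.abs(m).max()):
            raise ValueError("matrix is not symmetric")
        return cls(np.array([m[i, j] for i, j in D_COMPONENT_INDICES]))

    def to_matrix(self) -> np.ndarray:
        m = np.zeros((3, 3))
        for comp, (i, j) in zip(self.components, D_COMPONENT_INDICES):
            m[i, j] = comp
            m[j, i] = comp
        return m

    @property
    def mean_diffusivity(self) -> float:
        return float(self.components[:3].sum() / 3.0)


@dataclass(frozen=True)
class KurtosisTensor:
    """Fully symmetric order-4 kurtosis tensor, dimensionless.

    Stored as the canonical 15-vector
    [W1111, W2222, W3333, W1112, W1113, W1222, W2223, W1333, W2333,
     W1122, W1133, W2233, W1123, W1223, W1233].
    """

    components: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.components, dtype=float).ravel()
        if c.size != 15:
            raise ValueError("KurtosisTensor needs exactly 15 components")
        object.__setattr__(self, "components", c)

    @classmethod
    def from_array(cls, w: np.ndarray) -> "KurtosisTensor":
        w = np.asarray(w, dtype=float)
        if w.shape != (3, 3, 3, 3):
            raise ValueError("expected a 3x3x3x3 array")
        for perm in itertools.permutations(range(4)):
            if not np.allclose(w, np.transpose(w, perm), atol=1e-12 + 1e-9 * np.abs(w).max()):
                raise ValueError("array is not fully symmetric")
        return cls(np.array([w[idx] for idx in W_COMPONENT_INDICES]))

    def to_array(self) -> np.ndarray:
        w = np.zeros((3, 3, 3, 3))
        for comp, idx in zip(self.components, W_COMPONENT_INDICES):
            for perm in set(itertools.permutations(idx)):
                w[perm] = comp
        return w


# Per-voxel fit-quality flags (bit field).
FLAG_CLIPPED_SIGNAL = 1
FLAG_DEGENERATE_MD = 2
FLAG_KURTOSIS_RANGE = 4


@dataclass(frozen=True)
class TensorPair:
    """A voxel's diffusion tensor, kurtosis tensor and unweighted signal."""

    D: DiffusionTensor
    W: KurtosisTensor
    s0: float = 1.0
    fit_flags: int = 0

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise ValueError("s0 must be positive")


def isotropic_kurtosis_tensor(kurtosis: float) -> KurtosisTensor:
    """Isotropic W with constant directional kurtosis ``kurtosis``.

    W_ijkl = (K/3) (d_ij d_kl + d_ik d_jl + d_il d_jk); contracted with any
    unit direction four times it yields exactly K (for isotropic D).
    """
    d = np.eye(3)
    w = (kurtosis / 3.0) * (
        np.einsum("ij,kl->ijkl", d, d)
        + np.einsum("ik,jl->ijkl", d, d)
        + np.einsum("il,jk->ijkl", d, d)
    )
    return KurtosisTensor.from_array(w)


def _as_unit(direction: np.ndarray) -> np.ndarray:
    n = np.asarray(direction, dtype=float).ravel()
    if n.size != 3:
        raise ValueError("direction must be a 3-vector")
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("zero-vector direction")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    return n


def directional_diffusivity(D: DiffusionTensor, direction: np.ndarray) -> float:
    """Apparent diffusivity along a unit direction: the quadratic form n^T D n."""
    n = _as_unit(direction)
    return float(n @ D.to_matrix() @ n)


def directional_kurtosis(
    tensors: TensorPair, direction: np.ndarray, md_tol: float = 1e-12
) -> float:
    """Apparent kurtosis along a unit direction.

    K(n) = (MD^2 / D(n)^2) * sum_ijkl n_i n_j n_k n_l W_ijkl.
    """
    n = _as_unit(direction)
    dn = directional_diffusivity(tensors.D, n)
    if abs(dn) <= md_tol:
        raise ValueError("directional diffusivity is degenerate for this direction")
    md = tensors.D.mean_diffusivity
    wn = float(np.einsum("i,j,k,l,ijkl->", n, n, n, n, tensors.W.to_array()))
    return (md * md) / (dn * dn) * wn


def predict_log_signal(tensors: TensorPair, scheme: GradientScheme) -> np.ndarray:
    """Forward model: per-measurement ln S(b, n) for one voxel."""
    b = scheme.bvalues
    n = scheme.directions
    Dm = tensors.D.to_matrix()
    Wa = tensors.W.to_array()
    md = tensors.D.mean_diffusivity
    quad = np.einsum("mi,mj,ij->m", n, n, Dm)
    quart = np.einsum("mi,mj,mk,ml,ijkl->m", n, n, n, n, Wa)
    ln_s = np.log(tensors.s0) - b * quad + (b * b * md * md / 6.0) * quart
    # the weighting terms vanish identically at b=0 regardless of direction
    ln_s[scheme.b0_mask] = np.log(tensors.s0)
    return ln_s
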