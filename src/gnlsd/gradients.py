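"""Gradient-coil-tensor algebra.

Scanner gradient coils produce fields that deviate from the ideal linear
gradient away from the isocenter.  The deviation is summarised per voxel by a
3x3 coil tensor ``L(r)`` mapping the imposed gradient vector onto the
effective one, ``g_eff = L g``, so that the diffusion weighting actually
experienced is the effective b-matrix ``B_eff = L B L^T``.  This module holds
the small linear-algebra layer: coil tensors, b-matrices, acquisition schemes,
and the mono-exponential signal-deviation model that identifies the b-value
at which gradient nonlinearity perturbs the signal the most.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoilTensor",
    "bmatrix_from_bvec",
    "AcquisitionScheme",
    "effective_gradient",
    "effective_bmatrix",
    "effective_bval_dir",
    "mean_effective_bval",
    "signal_deviation",
    "bval_max_deviation",
    "canonical_hemisphere",
]


def canonical_hemisphere(v: np.ndarray) -> np.ndarray:
    """Flip antipodally symmetric direction(s) so the first nonzero component
    is positive.  Works on a single 3-vector or an (..., 3) array."""
    v = np.asarray(v, dtype=float)
    out = v.copy()
    flat = out.reshape(-1, 3)
    for row in flat:
        for c in row:
            if c != 0.0:
                if c < 0.0:
                    row *= -1.0
                break
    return out.reshape(v.shape)


@dataclass(frozen=True)
class CoilTensor:
    """A 3x3 linear map from imposed to effective gradients.

    Parameters
    ----------
    L : (3, 3) array
        The full coil tensor; identity for a perfectly linear gradient system.
    position : (3,) array, optional
        Scanner-space coordinates (mm) the tensor applies to.
    """

    L: np.ndarray
    position: np.ndarray | None = None

    def __post_init__(self):
        L = np.asarray(self.L, dtype=float)
        if L.shape != (3, 3):
            raise ValueError(f"coil tensor must be 3x3, got {L.shape}")
        if not np.all(np.isfinite(L)):
            raise ValueError("coil tensor entries must be finite")
        object.__setattr__(self, "L", L)

    @classmethod
    def from_deviation(cls, dL, position=None) -> "CoilTensor":
        """Build from the relative deviation ``dL = L - I``.

        Accepts a 3x3 matrix, a length-3 diagonal, or a scalar (isotropic)."""
        dL = np.asarray(dL, dtype=float)
        if dL.ndim == 0:
            dL = np.eye(3) * float(dL)
        elif dL.shape == (3,):
            dL = np.diag(dL)
        elif dL.shape != (3, 3):
            raise ValueError("deviation must be scalar, length-3 or 3x3")
        return cls(np.eye(3) + dL, position)

    @classmethod
    def identity(cls) -> "CoilTensor":
        return cls(np.eye(3))

    @property
    def deviation(self) -> np.ndarray:
        """dL = L - I."""
        return self.L - np.eye(3)

    @property
    def frobenius_deviation(self) -> float:
        """Frobenius norm of dL; zero for an ideal coil."""
        return float(np.linalg.norm(self.deviation))

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.deviation) <= tol))


def bmatrix_from_bvec(bval: float, direction: np.ndarray) -> np.ndarray:
    """Rank-1 b-matrix ``b * g g^T`` for a single pulsed-gradient direction."""
    g = np.asarray(direction, dtype=float)
    n = np.linalg.norm(g)
    if bval < 0:
        raise ValueError("b-value must be non-negative")
    if bval == 0 or n == 0:
        return np.zeros((3, 3))
    g = g / n
    return bval * np.outer(g, g)


def _check_symmetric(B: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    if B.shape != (3, 3):
        raise ValueError(f"b-matrix must be 3x3, got {B.shape}")
    if not np.allclose(B, B.T, atol=tol * max(1.0, np.abs(B).max())):
        raise ValueError("b-matrix must be symmetric")
    return 0.5 * (B + B.T)


def effective_gradient(coil: CoilTensor, g: np.ndarray) -> np.ndarray:
    """Effective gradient vector ``g_eff = L g``."""
    g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("gradient vector must be finite")
    return coil.L @ g


def effective_bmatrix(coil: CoilTensor, B: np.ndarray) -> np.ndarray:
    """Effective b-matrix ``B_eff = L B L^T`` (symmetric PSD in, symmetric
    PSD out)."""
    B = _check_symmetric(B)
    Be = coil.L @ B @ coil.L.T
    return 0.5 * (Be + Be.T)


def effective_bval_dir(B_eff: np.ndarray) -> tuple[float, np.ndarray | None]:
    """Effective b-value and unit direction of a (near rank-1) b-matrix.

    Returns ``(trace(B_eff), principal eigenvector)`` with the direction
    canonicalized to the positive hemisphere.  For a zero b-matrix the
    direction is undefined and ``None`` is returned.
    """
    B_eff = _check_symmetric(B_eff)
    b_eff = float(np.trace(B_eff))
    if b_eff <= 0.0:
        return 0.0, None
    w, v = np.linalg.eigh(B_eff)
    g = v[:, np.argmax(w)]
    return b_eff, canonical_hemisphere(g / np.linalg.norm(g))


@dataclass
class AcquisitionScheme:
    """Diffusion sampling scheme: per-measurement b-value and unit direction.

    ``directions`` rows with ``bvals == 0`` may be zero vectors (b0 volumes).
    The rank-1 imposed b-matrices are derived on construction.
    """

    directions: np.ndarray
    bvals: np.ndarray
    bmatrices: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        b = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        if d.shape[0] != b.shape[0] or d.shape[1] != 3:
            raise ValueError(
                f"directions {d.shape} inconsistent with bvals {b.shape}"
            )
        dw = b > 0
        norms = np.linalg.norm(d[dw], axis=1)
        if dw.any() and np.any(np.abs(norms - 1.0) > 1e-8):
            # tolerate unnormalized input but insist it is nonzero
            if np.any(norms == 0):
                raise ValueError("zero direction with nonzero b-value")
            d = d.copy()
            d[dw] = d[dw] / norms[:, None]
        self.directions = d
        self.bvals = b
        if self.bmatrices is None:
            self.bmatrices = np.array(
                [bmatrix_from_bvec(bi, gi) for bi, gi in zip(b, d)]
            )
        else:
            self.bmatrices = np.asarray(self.bmatrices, dtype=float)
            if self.bmatrices.shape != (len(b), 3, 3):
                raise ValueError("bmatrices must be (m, 3, 3)")

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def dwi_mask(self) -> np.ndarray:
        """Boolean mask of diffusion-weighted (b > 0) measurements."""
        return self.bvals > 0

    @property
    def b0_mask(self) -> np.ndarray:
        return ~self.dwi_mask

    def effective(self, coil: CoilTensor) -> "AcquisitionScheme":
        """The scheme as experienced under ``coil``: effective b-matrices,
        b-values and unit directions."""
        Beff = np.einsum("ab,mbc,dc->mad", coil.L, self.bmatrices, coil.L)
        beff = np.trace(Beff, axis1=1, axis2=2)
        dirs = np.zeros_like(self.directions)
        for i in range(len(self)):
            if beff[i] > 0:
                g = coil.L @ self.directions[i]
                dirs[i] = canonical_hemisphere(g / np.linalg.norm(g))
        return AcquisitionScheme(dirs, beff, Beff)


def mean_effective_bval(scheme: AcquisitionScheme, coil: CoilTensor) -> float:
    """Shell-averaged effective b-value ``(1/m) sum_i trace(L B_i L^T)`` over
    the diffusion-weighted measurements."""
    dw = scheme.dwi_mask
    if not dw.any():
        raise ValueError("scheme has no diffusion-weighted measurements")
    Beff = np.einsum("ab,mbc,dc->mad", coil.L, scheme.bmatrices[dw], coil.L)
    return float(np.mean(np.trace(Beff, axis1=1, axis2=2)))


def signal_deviation(b, D: float, dL: float):
    """Mono-exponential signal change caused by a relative gradient deviation.

    ``dS = exp(-b L^2 D) - exp(-b D)`` with ``L = 1 + dL``; the b-value scales
    quadratically with the gradient amplitude, hence the ``L^2``.
    """
    b = np.asarray(b, dtype=float)
    if D <= 0:
        raise ValueError("diffusivity must be positive")
    L = 1.0 + dL
    return np.exp(-b * L * L * D) - np.exp(-b * D)


def bval_max_deviation(D: float, dL: float) -> float:
    """Imposed b-value at which ``|signal_deviation|`` is largest.

    Closed form ``b* = -log(1/L^2) / (D (L^2 - 1))`` from setting the
    derivative of the mono-exponential difference to zero.
    """
    if D <= 0:
        raise ValueError("diffusivity must be positive")
    if dL == 0:
        raise ValueError("deviation dL must be nonzero")
    L2 = (1.0 + dL) ** 2
    return float(np.log(L2) / (D * (L2 - 1.0)))
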