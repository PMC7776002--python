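"""FOD peak extraction and angular-deviation metrics.

FOD maxima are found by evaluating the order-8 SH representation on a dense
symmetric seed mesh (icosphere), picking mesh-local maxima, and refining each
candidate by Newton ascent in the local tangent plane until the on-sphere
gradient norm falls below 1e-6.  Directions are antipodally symmetric, so all
outputs are canonicalized to the hemisphere with positive first nonzero
component and angular errors are computed as arccos(|a.b|) in [0, 90] deg.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from . import sh
from .gradients import canonical_hemisphere
from .simulate import get_directions

__all__ = [
    "PeakSet",
    "constraint_mesh",
    "seed_mesh",
    "fit_sh_to_fod",
    "extract_peaks",
    "peaks_batch",
    "primary_peaks_batch",
    "angular_deviation",
    "match_peaks_to_truth",
    "normalize_peaks",
]

GRAD_TOL = 1e-6
MERGE_DEG = 5.0


@dataclass(frozen=True)
class PeakSet:
    """Extracted FOD maxima: hemisphere-canonical unit directions with
    amplitudes sorted in descending order."""

    directions: np.ndarray
    amplitudes: np.ndarray
    normalized_amplitudes: np.ndarray | None = None

    def __post_init__(self):
        d = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        a = np.asarray(self.amplitudes, dtype=float).reshape(-1)
        if len(d) != len(a):
            raise ValueError("directions/amplitudes length mismatch")
        order = np.argsort(-a)
        object.__setattr__(self, "directions", canonical_hemisphere(d[order]))
        object.__setattr__(self, "amplitudes", a[order])
        if self.normalized_amplitudes is not None:
            na = np.asarray(self.normalized_amplitudes, dtype=float).reshape(-1)
            object.__setattr__(self, "normalized_amplitudes", na[order])

    def __len__(self) -> int:
        return len(self.amplitudes)


@lru_cache(maxsize=1)
def constraint_mesh() -> np.ndarray:
    """The 300-direction hemisphere set shared by the dRL dictionary and the
    CSD constraint mesh."""
    return get_directions(300)


@lru_cache(maxsize=1)
def seed_mesh():
    """Dense symmetric seed mesh for peak finding: subdivided icosahedron
    (2562 vertices over the full sphere, ~1281 unique orientations) plus a
    padded vertex-neighbor index table for local-maximum detection."""
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=4)
    verts = np.asarray(mesh.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    nmax = max(len(nb) for nb in mesh.vertex_neighbors)
    nbr = np.empty((len(verts), nmax), dtype=np.int64)
    for i, nb in enumerate(mesh.vertex_neighbors):
        # pad short rows with a duplicated real neighbor (never the vertex
        # itself, which would veto it as a local maximum)
        row = list(nb) + [nb[0]] * (nmax - len(nb))
        nbr[i] = row
    return verts, nbr


def _order_from_ncoeffs(nc: int) -> int:
    order = int(round((-3 + np.sqrt(1 + 8 * nc)) / 2))
    if sh.n_coeffs(order) != nc:
        raise ValueError(f"{nc} is not a valid even-SH coefficient count")
    return order


def fit_sh_to_fod(f: np.ndarray, dirs: np.ndarray | None = None,
                  order: int = 8) -> np.ndarray:
    """Least-squares SH coefficients of FOD dictionary amplitudes.

    ``f`` may be (n,) or (n, R); ``dirs`` defaults to the 300-direction
    dictionary.  Raises on rank deficiency (too few dictionary directions).
    """
    if dirs is None:
        dirs = constraint_mesh()
    B = sh.sh_basis(order, dirs)
    if B.shape[0] < B.shape[1] or np.linalg.matrix_rank(B) < B.shape[1]:
        raise np.linalg.LinAlgError(
            f"{B.shape[0]} dictionary directions cannot support an order-"
            f"{order} SH fit ({B.shape[1]} coefficients)")
    coeffs, *_ = np.linalg.lstsq(B, np.asarray(f, dtype=float), rcond=None)
    return coeffs


def _amplitudes(coeffs2d: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Per-row amplitude: row i of ``dirs`` evaluated with row i of
    ``coeffs2d``."""
    order = _order_from_ncoeffs(coeffs2d.shape[1])
    B = sh.sh_basis(order, dirs)
    return np.einsum("ki,ki->k", B, coeffs2d)


def _tangent_frames(d: np.ndarray):
    ref = np.where(np.abs(d[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    return e1, e2


def refine_peaks(coeffs: np.ndarray, dirs0: np.ndarray, grad_tol: float = GRAD_TOL,
                 max_iter: int = 60) -> np.ndarray:
    """Newton ascent of SH amplitude on the sphere, vectorized over points.

    ``coeffs`` is (K, nc) (one coefficient row per seed) and ``dirs0`` (K, 3).
    Iterates in the local tangent plane with finite-difference gradient and
    Hessian, backtracking on the amplitude, until the tangential gradient
    norm is below ``grad_tol``.
    """
    c = np.atleast_2d(np.asarray(coeffs, dtype=float))
    d = np.atleast_2d(np.asarray(dirs0, dtype=float)).copy()
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    K = len(d)
    if len(c) == 1 and K > 1:
        c = np.repeat(c, K, axis=0)
    hg, hh = 1e-5, 1e-3

    def norm_eval(pts):
        pts = pts / np.linalg.norm(pts, axis=-1, keepdims=True)
        flat = pts.reshape(-1, 3)
        reps = flat.shape[0] // K
        cc = np.tile(c, (reps, 1)) if reps > 1 else c
        return _amplitudes(cc, flat).reshape(pts.shape[:-1])

    active = np.ones(K, dtype=bool)
    for _ in range(max_iter):
        e1, e2 = _tangent_frames(d)
        probes = np.stack([
            d,
            d + hg * e1, d - hg * e1, d + hg * e2, d - hg * e2,
            d + hh * e1, d - hh * e1, d + hh * e2, d - hh * e2,
            d + hh * (e1 + e2), d + hh * (e1 - e2),
            d - hh * (e1 - e2), d - hh * (e1 + e2),
        ])
        v = norm_eval(probes)
        f0 = v[0]
        g = np.stack([(v[1] - v[2]) / (2 * hg), (v[3] - v[4]) / (2 * hg)], axis=1)
        gnorm = np.linalg.norm(g, axis=1)
        active = gnorm > grad_tol
        if not active.any():
            break
        h11 = (v[5] - 2 * f0 + v[6]) / hh ** 2
        h22 = (v[7] - 2 * f0 + v[8]) / hh ** 2
        h12 = (v[9] - v[10] - v[11] + v[12]) / (4 * hh ** 2)
        det = h11 * h22 - h12 ** 2
        newton_ok = (det > 0) & (h11 < 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            s1 = np.where(newton_ok, -(h22 * g[:, 0] - h12 * g[:, 1]) / det, g[:, 0])
            s2 = np.where(newton_ok, -(h11 * g[:, 1] - h12 * g[:, 0]) / det, g[:, 1])
        step = np.stack([s1, s2], axis=1)
        snorm = np.linalg.norm(step, axis=1)
        cap = np.minimum(1.0, 0.3 / np.maximum(snorm, 1e-30))
        step *= (cap * active)[:, None]
        # backtracking: halve until the amplitude does not decrease
        t = np.ones(K)
        for _bt in range(12):
            cand = d + (t[:, None] * step[:, 0:1]) * e1 + (t[:, None] * step[:, 1:2]) * e2
            fc = norm_eval(cand[None, ...])[0]
            worse = active & (fc < f0 - 1e-14)
            if not worse.any():
                break
            t[worse] *= 0.5
        d = cand / np.linalg.norm(cand, axis=1, keepdims=True)
    return d


def extract_peaks(sh_coeffs: np.ndarray, amp_threshold: float = 0.1,
                  max_peaks: int | None = None,
                  min_sep_deg: float = MERGE_DEG) -> PeakSet:
    """Locate FOD maxima of one SH coefficient vector.

    Seeds at strict local maxima of the dense mesh, refines by on-sphere
    ascent, merges antipodal/near-duplicate peaks (< ``min_sep_deg`` apart)
    and discards peaks below ``amp_threshold`` times the largest amplitude.
    Returns an empty PeakSet when nothing survives (e.g. isotropic FODs,
    where no strict mesh maximum exists).
    """
    c = np.asarray(sh_coeffs, dtype=float).reshape(-1)
    verts, nbr = seed_mesh()
    order = _order_from_ncoeffs(len(c))
    vals = sh.sh_basis(order, verts) @ c
    nbr_max = vals[nbr].max(axis=1)
    cand = np.where(vals > nbr_max)[0]
    if len(cand) == 0:
        return PeakSet(np.empty((0, 3)), np.empty(0))
    refined = refine_peaks(c[None, :], verts[cand])
    amps = _amplitudes(np.repeat(c[None, :], len(refined), axis=0), refined)
    return _merge_and_threshold(refined, amps, amp_threshold, max_peaks, min_sep_deg)


def _merge_and_threshold(dirs, amps, amp_threshold, max_peaks, min_sep_deg) -> PeakSet:
    keep = amps > 0
    dirs, amps = canonical_hemisphere(dirs[keep]), amps[keep]
    if len(amps) == 0:
        return PeakSet(np.empty((0, 3)), np.empty(0))
    order = np.argsort(-amps)
    sel_d, sel_a = [], []
    cos_merge = np.cos(np.deg2rad(min_sep_deg))
    for i in order:
        if any(abs(dirs[i] @ sd) >= cos_merge for sd in sel_d):
            continue
        sel_d.append(dirs[i])
        sel_a.append(amps[i])
    sel_d, sel_a = np.array(sel_d), np.array(sel_a)
    keep = sel_a >= amp_threshold * sel_a.max()
    sel_d, sel_a = sel_d[keep], sel_a[keep]
    if max_peaks is not None:
        sel_d, sel_a = sel_d[:max_peaks], sel_a[:max_peaks]
    return PeakSet(sel_d, sel_a)


@lru_cache(maxsize=4)
def _mesh_basis(order: int) -> np.ndarray:
    verts, _ = seed_mesh()
    return sh.sh_basis(order, verts)


def primary_peaks_batch(coeffs: np.ndarray, chunk: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Primary FOD peak for each row of an (R, nc) SH coefficient batch.

    Returns ``(directions (R, 3), amplitudes (R,))``; the Monte Carlo fast
    path (mesh argmax seed + vectorized Newton refinement).
    """
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    order = _order_from_ncoeffs(coeffs.shape[1])
    verts, _ = seed_mesh()
    B = _mesh_basis(order)
    R = len(coeffs)
    seeds = np.empty((R, 3))
    for lo in range(0, R, chunk):
        hi = min(lo + chunk, R)
        vals = coeffs[lo:hi] @ B.T
        seeds[lo:hi] = verts[np.argmax(vals, axis=1)]
    refined = refine_peaks(coeffs, seeds)
    amps = _amplitudes(coeffs, refined)
    return canonical_hemisphere(refined), amps


def peaks_batch(coeffs: np.ndarray, n_peaks: int = 2, amp_threshold: float = 0.1,
                min_sep_deg: float = MERGE_DEG, chunk: int = 1000,
                n_candidates: int = 6) -> list[PeakSet]:
    """Up to ``n_peaks`` FOD maxima per row of an (R, nc) coefficient batch.

    Mesh-local maxima are detected per replicate, the strongest candidates
    refined in one vectorized ascent, then merged/thresholded per replicate.
    """
    coeffs = np.atleast_2d(np.asarray(coeffs, dtype=float))
    order = _order_from_ncoeffs(coeffs.shape[1])
    verts, nbr = seed_mesh()
    B = _mesh_basis(order)
    R = len(coeffs)
    cand_idx = np.empty((R, n_candidates), dtype=np.int64)
    for lo in range(0, R, chunk):
        hi = min(lo + chunk, R)
        vals = coeffs[lo:hi] @ B.T
        nbr_max = vals[:, nbr].max(axis=2)
        is_max = vals > nbr_max
        ranked = np.argsort(np.where(is_max, -vals, np.inf), axis=1)[:, :n_candidates]
        # pad replicates with fewer maxima by repeating their global argmax
        fallback = np.argmax(vals, axis=1)
        counts = is_max.sum(axis=1)
        for r in range(hi - lo):
            k = min(counts[r], n_candidates)
            row = ranked[r].copy()
            row[k:] = fallback[r]
            cand_idx[lo + r] = row
    flat_dirs = verts[cand_idx.reshape(-1)]
    flat_coeffs = np.repeat(coeffs, n_candidates, axis=0)
    refined = refine_peaks(flat_coeffs, flat_dirs)
    amps = _amplitudes(flat_coeffs, refined)
    refined = refined.reshape(R, n_candidates, 3)
    amps = amps.reshape(R, n_candidates)
    return [
        _merge_and_threshold(refined[r], amps[r], amp_threshold, n_peaks, min_sep_deg)
        for r in range(R)
    ]


def angular_deviation(a: np.ndarray, b: np.ndarray) -> float | np.ndarray:
    """Angle between fiber axes in degrees, antipodally symmetric: in [0, 90]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero vector has no direction")
    cos = np.abs(np.sum(a * b, axis=-1) / (na * nb))
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def match_peaks_to_truth(peaks: PeakSet, truths: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Assign extracted peaks to ground-truth orientations.

    Uses an optimal one-to-one assignment minimizing total angular deviation;
    each peak matches at most one truth.  Returns ``(deviations_deg, flags)``
    with NaN deviation and flag=True for truths left unmatched (peak-detection
    failure).
    """
    from scipy.optimize import linear_sum_assignment

    truths = np.atleast_2d(np.asarray(truths, dtype=float))
    nt = len(truths)
    dev = np.full(nt, np.nan)
    flags = np.ones(nt, dtype=bool)
    if len(peaks) == 0:
        return dev, flags
    cost = np.array([[angular_deviation(t, p) for p in peaks.directions]
                     for t in truths])
    rows, cols = linear_sum_assignment(cost)
    for r, c in zip(rows, cols):
        dev[r] = cost[r, c]
        flags[r] = False
    return dev, flags


def normalize_peaks(peaks: PeakSet, reference_amplitude: float) -> PeakSet:
    """Scale peak amplitudes by the method-specific reference (the mean
    primary-peak amplitude of single fibers without gradient deviation)."""
    if reference_amplitude <= 0:
        raise ValueError("reference amplitude must be positive")
    return replace(peaks, normalized_amplitudes=peaks.amplitudes / reference_amplitude)
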