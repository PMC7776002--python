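"""Synthetic diffusion-MRI signal generation.

Provides the building blocks of the Monte Carlo experiments: multi-tensor
signal models for single and crossing fiber populations, Rician noise,
electrostatic-repulsion gradient direction sets, the standard experiment
configurations (Simulations I-V), and a parametric whole-volume phantom with
a spatially varying coil-tensor field.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .gradients import AcquisitionScheme, CoilTensor, canonical_hemisphere

__all__ = [
    "FiberConfig",
    "NoiseModel",
    "PhantomSpec",
    "tensor_signal",
    "add_rician_noise",
    "generate_directions",
    "get_directions",
    "make_scheme",
    "SimulationCell",
    "ScenarioConfig",
    "scenario",
    "build_phantom",
    "rng_for",
]

# Tensor eigenvalues of a coherent white-matter fiber population (mm^2/s):
# axial 1.7e-3, radial 0.2e-3.
DEFAULT_EIGENVALUES = (1.7e-3, 0.2e-3, 0.2e-3)

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


def rng_for(master_seed: int, *keys: int) -> np.random.Generator:
    """Independent substream generator: one master seed per experiment,
    deterministic per-(replicate/stage) substreams via spawn keys."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, keys)]))


@dataclass(frozen=True)
class FiberConfig:
    """One or more coherent fiber populations in a voxel.

    ``fractions`` are signal fractions (non-negative, summing to 1);
    ``eigenvalues`` are (axial, radial, radial) diffusivities in mm^2/s shared
    by all populations.
    """

    orientations: np.ndarray
    fractions: np.ndarray = None  # type: ignore[assignment]
    eigenvalues: tuple[float, float, float] = DEFAULT_EIGENVALUES

    def __post_init__(self):
        o = np.atleast_2d(np.asarray(self.orientations, dtype=float))
        o = o / np.linalg.norm(o, axis=1, keepdims=True)
        object.__setattr__(self, "orientations", o)
        f = self.fractions
        if f is None:
            f = np.full(len(o), 1.0 / len(o))
        f = np.atleast_1d(np.asarray(f, dtype=float))
        if len(f) != len(o):
            raise ValueError("one fraction per fiber population required")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-8:
            raise ValueError("fractions must be non-negative and sum to 1")
        object.__setattr__(self, "fractions", f)
        ax, r1, r2 = self.eigenvalues
        if not (ax >= r1 >= 0 and r1 == r2):
            raise ValueError("eigenvalues must satisfy axial >= radial >= 0, equal radials")

    def tensors(self) -> np.ndarray:
        """(k, 3, 3) diffusion tensors, axially symmetric about each
        orientation: D = radial*I + (axial - radial) * e e^T."""
        ax, rad, _ = self.eigenvalues
        e = self.orientations
        return rad * np.eye(3) + (ax - rad) * np.einsum("ki,kj->kij", e, e)


@dataclass(frozen=True)
class NoiseModel:
    """Rician noise level relative to the b=0 signal: sigma = S0 / snr."""

    snr: float
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("SNR must be positive")


def tensor_signal(config: FiberConfig, bmatrices: np.ndarray, S0: float = 1.0) -> np.ndarray:
    """Noise-free multi-tensor signal ``S = S0 * sum_k f_k exp(-B : D_k)``.

    ``bmatrices`` is (..., 3, 3); the Frobenius inner product with each
    population tensor gives the log-attenuation.
    """
    B = np.asarray(bmatrices, dtype=float)
    D = config.tensors()  # (k,3,3)
    att = np.einsum("...ij,kij->...k", B, D)
    return S0 * np.einsum("k,...k->...", config.fractions, np.exp(-att))


def add_rician_noise(S, model: NoiseModel, S0: float = 1.0, rng=None):
    """Rician-corrupted magnitude signal ``sqrt((S+n1)^2 + n2^2)`` with
    n1, n2 ~ N(0, sigma^2), sigma = S0/snr."""
    if model.snr <= 0:
        raise ValueError("SNR must be positive")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    S = np.asarray(S, dtype=float)
    sigma = S0 / model.snr
    n1 = rng.normal(0.0, sigma, S.shape)
    n2 = rng.normal(0.0, sigma, S.shape)
    return np.sqrt((S + n1) ** 2 + n2 ** 2)


# ---------------------------------------------------------------------------
# Gradient direction sets
# ---------------------------------------------------------------------------

def _antipodal_energy_grad(X: np.ndarray):
    """Electrostatic energy of the antipodal point set {+-x_i} (constant
    self-term dropped) and its gradient with respect to the unit vectors."""
    n = len(X)
    d = X[:, None, :] - X[None, :, :]
    s = X[:, None, :] + X[None, :, :]
    rd = np.linalg.norm(d, axis=-1)
    rs = np.linalg.norm(s, axis=-1)
    np.fill_diagonal(rd, np.inf)
    iu = np.triu_indices(n, 1)
    energy = np.sum(1.0 / rd[iu] + 1.0 / rs[iu])
    gd = -d / rd[..., None] ** 3
    gs = -s / np.where(rs[..., None] == 0, np.inf, rs[..., None]) ** 3
    np.fill_diagonal(gs[..., 0], 0); np.fill_diagonal(gs[..., 1], 0); np.fill_diagonal(gs[..., 2], 0)
    grad = gd.sum(axis=1) + gs.sum(axis=1)
    return energy, grad


def generate_directions(n: int, hemisphere: bool = True, seed: int = 0,
                        maxiter: int = 1000) -> np.ndarray:
    """Electrostatic-repulsion direction set on the (hemi)sphere.

    Minimizes the Coulomb energy of the antipodally symmetrized point set so
    that directions are well spread for diffusion sampling.  Deterministic
    given ``seed``.
    """
    if n < 6:
        raise ValueError("need at least 6 directions")
    rng = np.random.default_rng(seed)
    X0 = rng.normal(size=(n, 3))
    X0 /= np.linalg.norm(X0, axis=1, keepdims=True)

    def fun(x):
        X = x.reshape(n, 3)
        r = np.linalg.norm(X, axis=1, keepdims=True)
        U = X / r
        e, gU = _antipodal_energy_grad(U)
        # chain rule through row normalization
        gX = (gU - U * np.sum(gU * U, axis=1, keepdims=True)) / r
        return e, gX.ravel()

    res = minimize(fun, X0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-10})
    U = res.x.reshape(n, 3)
    U /= np.linalg.norm(U, axis=1, keepdims=True)
    if hemisphere:
        U = canonical_hemisphere(U)
    # stable ordering: by polar angle then azimuth
    order = np.lexsort((np.arctan2(U[:, 1], U[:, 0]), U[:, 2]))
    return U[order]


def get_directions(n: int) -> np.ndarray:
    """Hemisphere direction set: shipped fixture for n in {60, 90, 300},
    generated on the fly otherwise."""
    if n in (60, 90, 300):
        ref = importlib.resources.files("gnlsd") / "data" / f"dirs{n:03d}.txt"
        with importlib.resources.as_file(ref) as path:
            return np.loadtxt(path)
    return generate_directions(n)


def make_scheme(bval: float, n_dirs: int = 60, n_b0: int = 1) -> AcquisitionScheme:
    """Single-shell scheme: ``n_b0`` b=0 volumes followed by ``n_dirs``
    hemisphere directions at ``bval``."""
    dirs = get_directions(n_dirs)
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    return AcquisitionScheme(directions, bvals)


# ---------------------------------------------------------------------------
# Standard Monte Carlo scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationCell:
    """One fully resolved Monte Carlo condition: fiber configuration, coil
    tensor, acquisition, noise level and replicate count."""

    label: str
    fibers: FiberConfig
    coil: CoilTensor
    bval: float
    n_dirs: int
    snr: float
    n_reps: int


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    cells: tuple[SimulationCell, ...]
    master_seed: int = 0
    noise_on_b0: bool = True
    n_b0: int = 1

    def scheme(self, cell: SimulationCell) -> AcquisitionScheme:
        return make_scheme(cell.bval, cell.n_dirs, self.n_b0)


_SIM_I_DEV = (-0.13, -0.14, -0.05)


def _single(axis: np.ndarray) -> FiberConfig:
    return FiberConfig(axis[None, :])


def scenario(sim_id: str, reps: int | None = None, snr: float | None = None,
             seed: int = 0) -> ScenarioConfig:
    """Standard experiment configurations.

    I   : single fibers along x/y/z, b=3000, 60 dirs, dL=diag(-.13,-.14,-.05), SNR 30
    II  : as I at b=2000 and b=1000, plus the opposite-sign deviation for the
          x fiber
    III : y fiber, 90 dirs, b=3000, single-axis deviations in {0,-0.1,-0.2}
    IV  : as I across SNR in {10,20,30,40,50}
    V   : crossing fibers at {90,75,60,45} degrees, isotropic dL = +-0.15
    """
    sim_id = str(sim_id).upper()
    n_reps = 10_000 if reps is None else int(reps)
    base_snr = 30.0 if snr is None else float(snr)
    dev = CoilTensor.from_deviation(np.array(_SIM_I_DEV))
    axes = {"x": _X, "y": _Y, "z": _Z}
    cells: list[SimulationCell] = []
    if sim_id == "I":
        for name, ax in axes.items():
            cells.append(SimulationCell(f"fiber-{name}", _single(ax), dev,
                                        3000.0, 60, base_snr, n_reps))
    elif sim_id == "II":
        for b in (2000.0, 1000.0):
            for name, ax in axes.items():
                cells.append(SimulationCell(f"fiber-{name}-b{int(b)}", _single(ax),
                                            dev, b, 60, base_snr, n_reps))
        pos = CoilTensor.from_deviation(-np.array(_SIM_I_DEV))
        for b in (3000.0, 2000.0, 1000.0):
            cells.append(SimulationCell(f"fiber-x-b{int(b)}-posdev", _single(_X),
                                        pos, b, 60, base_snr, n_reps))
    elif sim_id == "III":
        cells.append(SimulationCell("baseline", _single(_Y), CoilTensor.identity(),
                                    3000.0, 90, base_snr, n_reps))
        for ai, name in enumerate("xyz"):
            for mag in (-0.1, -0.2):
                dl = np.zeros(3)
                dl[ai] = mag
                cells.append(SimulationCell(
                    f"dev-{name}{mag:+.1f}", _single(_Y),
                    CoilTensor.from_deviation(dl), 3000.0, 90, base_snr, n_reps))
    elif sim_id == "IV":
        for s in (10.0, 20.0, 30.0, 40.0, 50.0):
            for name, ax in axes.items():
                cells.append(SimulationCell(f"fiber-{name}-snr{int(s)}", _single(ax),
                                            dev, 3000.0, 60, s, n_reps))
    elif sim_id == "V":
        for sign, tag in ((-0.15, "neg"), (0.15, "pos")):
            coil = CoilTensor.from_deviation(sign * np.ones(3))
            for ang in (90.0, 75.0, 60.0, 45.0):
                half = np.deg2rad(ang) / 2
                o = np.array([[np.cos(half), np.sin(half), 0.0],
                              [np.cos(half), -np.sin(half), 0.0]])
                cells.append(SimulationCell(
                    f"cross-{int(ang)}-{tag}", FiberConfig(o, [0.5, 0.5]),
                    coil, 3000.0, 60, base_snr, n_reps))
    else:
        raise ValueError(f"unknown simulation id {sim_id!r}; expected I..V")
    return ScenarioConfig(f"Simulation {sim_id}", tuple(cells), master_seed=seed)


# ---------------------------------------------------------------------------
# Parametric phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Whole-volume phantom with a smooth coil-tensor field.

    The diagonal coil deviation grows quadratically with normalized distance
    from the grid isocenter and reaches ``corner_deviation`` (per axis) at the
    corners; the single-fiber orientation field rotates smoothly across the
    volume.  ``snr=None`` disables noise.
    """

    shape: tuple[int, int, int] = (20, 20, 10)
    # anisotropic per-axis gains: an isotropic deviation would only rescale
    # b and never tilt effective directions
    corner_deviation: tuple[float, float, float] = (-0.15, -0.10, -0.05)
    snr: float | None = 30.0
    eigenvalues: tuple[float, float, float] = DEFAULT_EIGENVALUES

    def normalized_coords(self) -> np.ndarray:
        """Per-voxel coordinates scaled to [-1, 1] per axis, 0 at isocenter."""
        axes = [
            (np.arange(s) - (s - 1) / 2.0) / ((s - 1) / 2.0) if s > 1 else np.zeros(s)
            for s in self.shape
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def coil_field(self) -> np.ndarray:
        """(X, Y, Z, 3, 3) coil tensor field L(r); identity at the isocenter,
        deviation magnitude monotone in distance from it."""
        r = self.normalized_coords()
        q = np.mean(r ** 2, axis=-1)  # 0 at isocenter, 1 at corners
        dl = q[..., None] * np.asarray(self.corner_deviation)
        field = np.zeros(self.shape + (3, 3))
        idx = np.arange(3)
        field[..., idx, idx] = 1.0 + dl
        return field

    def orientation_field(self) -> np.ndarray:
        """(X, Y, Z, 3) ground-truth fiber orientation, rotating smoothly
        in-plane with position (hemisphere-canonical)."""
        r = self.normalized_coords()
        alpha = (np.pi / 3.0) * r[..., 0]
        gamma = (np.pi / 6.0) * r[..., 1]
        v = np.stack([
            np.cos(alpha) * np.cos(gamma),
            np.sin(alpha) * np.cos(gamma),
            np.sin(gamma),
        ], axis=-1)
        return canonical_hemisphere(v)


def build_phantom(spec: PhantomSpec, scheme: AcquisitionScheme,
                  rng: np.random.Generator | None = None,
                  noise_on_b0: bool = True):
    """Simulate a DWI volume under the phantom's local effective b-matrices.

    Returns ``(signal volume (X,Y,Z,m), truth orientations (X,Y,Z,3),
    coil field (X,Y,Z,3,3))``.
    """
    coil = spec.coil_field()
    truth = spec.orientation_field()
    if coil.shape[:3] != spec.shape or truth.shape[:3] != spec.shape:
        raise ValueError("phantom field shapes inconsistent with grid")
    m = len(scheme)
    vol = np.zeros(spec.shape + (m,))
    B = scheme.bmatrices
    for idx in np.ndindex(spec.shape):
        L = coil[idx]
        Beff = np.einsum("ab,mbc,dc->mad", L, B, L)
        cfg = FiberConfig(truth[idx][None, :], eigenvalues=spec.eigenvalues)
        vol[idx] = tensor_signal(cfg, Beff)
    if spec.snr is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        noisy = add_rician_noise(vol, NoiseModel(spec.snr), S0=1.0, rng=rng)
        if not noise_on_b0:
            noisy[..., scheme.b0_mask] = vol[..., scheme.b0_mask]
        vol = noisy
    return vol, truth, coil
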