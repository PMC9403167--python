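"""Synthetic training corpus for the perturbation-prediction network.

Scenes emulate the simulation study the network is meant for: a breast-like
semi-infinite background with a single absorbing lesion (sphere or
spherical-harmonic-perturbed "irregular" shape), an optional tilted
chest-wall slab of elevated absorption beneath the tissue, and a smooth
random background-absorption field standing in for anatomical
heterogeneity.  Property ranges:

=====================  ==================
target radius          0.375 - 1.5 cm
target center depth    0.6 - 2.7 cm (fully below the surface)
target mua             0.08 - 0.30 cm^-1
target musp            4 - 8 cm^-1
background mua         0.01 - 0.06 cm^-1
background musp        4 - 8 cm^-1
chest wall depth       1.6 - 5 cm
chest wall tilt        -10 - 10 deg
chest wall mua         0.1 - 0.2 cm^-1
=====================  ==================

A training sample pairs the *noisy* lesion-side measurement (2% Gaussian
amplitude noise, 0.02 rad phase noise) with the noise-free matched
perturbation -- the quantity a perfectly matched reference measurement
would deliver.  Mismatch scenarios place the reference-side chest wall
shallower than the lesion side, the situation that corrupts measured
perturbations in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import (
    DEFAULT_VOLUME_BOUNDS,
    FDMeasurement,
    OpticalProperties,
    ProbeGeometry,
)
from .forward import born_perturbation, simulate_homogeneous, simulate_with_inclusions
from .perturbation import (
    Perturbation,
    compute_perturbation,
    normalize_for_network,
)

# Sampling ranges (cm, cm^-1, deg)
TARGET_RADIUS_RANGE = (0.375, 1.5)
TARGET_DEPTH_RANGE = (0.6, 2.7)
TARGET_MUA_RANGE = (0.08, 0.30)
TARGET_MUSP_RANGE = (4.0, 8.0)
TARGET_LATERAL_RANGE = (-1.0, 1.0)  # x, along the probe axis
TARGET_Y_RANGE = (-0.25, 0.25)  # lesions are centered in the US scan plane
BACKGROUND_MUA_RANGE = (0.01, 0.06)
BACKGROUND_MUSP_RANGE = (4.0, 8.0)
CHEST_WALL_DEPTH_RANGE = (1.6, 5.0)
CHEST_WALL_TILT_RANGE = (-10.0, 10.0)
CHEST_WALL_MUA_RANGE = (0.1, 0.2)
CHEST_WALL_MUSP_RANGE = (4.0, 8.0)
CHEST_WALL_PROBABILITY = 0.5
HETERO_AMPLITUDE_FRACTION = 0.2  # max |delta mua| as a fraction of background mua

TARGET_VOXEL_CM = 0.2
WALL_VOXEL_CM = 0.5
HETERO_VOXEL_CM = 0.8


@dataclass
class TargetSpec:
    shape: str  # "sphere" | "perturbed-ellipsoid"
    center: tuple[float, float, float]
    radius: float
    mua: float
    musp: float
    # low-order real-spherical-harmonic radial modulation coefficients
    # (l, m, a_lm) for the irregular shape; empty for spheres
    harmonics: tuple = ()


@dataclass
class ChestWall:
    present: bool
    depth: float = 3.0
    tilt_deg: float = 0.0
    mua: float = 0.15
    musp: float = 6.0


@dataclass
class Scene:
    background: OpticalProperties
    target: TargetSpec
    chest_wall: ChestWall
    hetero_amplitude: float  # max |delta mua| of the smooth background field
    hetero_seed: int

    def to_dict(self) -> dict:
        d = asdict(self)
        d["background"] = {
            "mua": self.background.mua,
            "musp": self.background.musp,
            "refractive_index": self.background.refractive_index,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scene":
        bg = OpticalProperties(**d["background"])
        tgt = TargetSpec(**{**d["target"],
                            "center": tuple(d["target"]["center"]),
                            "harmonics": tuple(map(tuple, d["target"]["harmonics"]))})
        return cls(
            background=bg,
            target=tgt,
            chest_wall=ChestWall(**d["chest_wall"]),
            hetero_amplitude=d["hetero_amplitude"],
            hetero_seed=d["hetero_seed"],
        )


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sample_scene(rng_seed) -> Scene:
    """Draw one random scene from the corpus property ranges.

    All continuous fields are uniform over their range; the target is fully
    below the surface (center depth > radius, by rejection); irregular
    shapes carry an l<=2 spherical-harmonic radial modulation.
    """
    rng = _rng(rng_seed)
    background = OpticalProperties(
        mua=rng.uniform(*BACKGROUND_MUA_RANGE),
        musp=rng.uniform(*BACKGROUND_MUSP_RANGE),
    )
    while True:
        radius = rng.uniform(*TARGET_RADIUS_RANGE)
        depth = rng.uniform(*TARGET_DEPTH_RANGE)
        if depth - radius > 0.05:  # keep the target strictly buried
            break
    shape = "sphere" if rng.random() < 0.5 else "perturbed-ellipsoid"
    harmonics: tuple = ()
    if shape == "perturbed-ellipsoid":
        harmonics = tuple(
            (l, m, float(rng.uniform(-0.25, 0.25)))
            for l in (1, 2)
            for m in range(-l, l + 1)
        )
    target = TargetSpec(
        shape=shape,
        center=(
            float(rng.uniform(*TARGET_LATERAL_RANGE)),
            float(rng.uniform(*TARGET_Y_RANGE)),
            float(depth),
        ),
        radius=float(radius),
        mua=float(rng.uniform(*TARGET_MUA_RANGE)),
        musp=float(rng.uniform(*TARGET_MUSP_RANGE)),
        harmonics=harmonics,
    )
    if rng.random() < CHEST_WALL_PROBABILITY:
        wall = ChestWall(
            present=True,
            depth=float(rng.uniform(*CHEST_WALL_DEPTH_RANGE)),
            tilt_deg=float(rng.uniform(*CHEST_WALL_TILT_RANGE)),
            mua=float(rng.uniform(*CHEST_WALL_MUA_RANGE)),
            musp=float(rng.uniform(*CHEST_WALL_MUSP_RANGE)),
        )
    else:
        wall = ChestWall(present=False)
    return Scene(
        background=background,
        target=target,
        chest_wall=wall,
        hetero_amplitude=float(
            rng.uniform(0.0, HETERO_AMPLITUDE_FRACTION) * background.mua
        ),
        hetero_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _harmonic_radius(target: TargetSpec, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Direction-dependent radius of an irregular target."""
    from scipy.special import sph_harm_y

    r = np.full_like(theta, target.radius, dtype=float)
    for l, m, a in target.harmonics:
        ylm = sph_harm_y(int(l), abs(int(m)), theta, phi)
        basis = np.sqrt(2) * (ylm.imag if m < 0 else ylm.real) if m != 0 else ylm.real
        r += target.radius * a * basis
    return np.clip(r, 0.3 * target.radius, 2.0 * target.radius)


def voxelize_target(
    scene: Scene, voxel: float = TARGET_VOXEL_CM
) -> tuple[np.ndarray, float, np.ndarray]:
    """Voxelize the lesion: (centers (n,3), voxel volume cm^3, delta_mua (n,))."""
    t = scene.target
    c = np.asarray(t.center)
    rmax = 2.0 * t.radius if t.harmonics else t.radius
    ax = [np.arange(c[i] - rmax + voxel / 2, c[i] + rmax, voxel) for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    rel = pts - c
    d = np.linalg.norm(rel, axis=1)
    cosang = np.divide(rel[:, 2], d, out=np.ones_like(d), where=d > 0)
    theta = np.arccos(np.clip(cosang, -1, 1))
    phi = np.arctan2(rel[:, 1], rel[:, 0]) % (2 * np.pi)
    if t.harmonics:
        inside = d <= _harmonic_radius(t, theta, phi)
    else:
        inside = d <= t.radius
    inside &= pts[:, 2] > 0
    centers = pts[inside]
    dmua = np.full(centers.shape[0], t.mua - scene.background.mua)
    return centers, voxel**3, dmua


def chest_wall_voxels(
    scene: Scene,
    bounds=DEFAULT_VOLUME_BOUNDS,
    voxel: float = WALL_VOXEL_CM,
    depth_override: float | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Voxelize the chest wall slab: membership is z >= depth + tan(tilt)*x."""
    w = scene.chest_wall
    if not w.present:
        return np.empty((0, 3)), voxel**3, np.empty(0)
    depth = w.depth if depth_override is None else depth_override
    ax = [np.arange(b[0] + voxel / 2, b[1], voxel) for b in bounds]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    plane = depth + np.tan(np.deg2rad(w.tilt_deg)) * pts[:, 0]
    inside = (pts[:, 2] >= plane) & (pts[:, 2] > 0)
    centers = pts[inside]
    dmua = np.full(centers.shape[0], w.mua - scene.background.mua)
    return centers, voxel**3, dmua


def heterogeneity_voxels(
    scene: Scene,
    bounds=DEFAULT_VOLUME_BOUNDS,
    voxel: float = HETERO_VOXEL_CM,
    correlation_cm: float = 1.5,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Smooth Gaussian-random delta-mua field over the breast tissue region.

    White noise on a coarse grid is low-pass filtered to the requested
    correlation length and rescaled so max|delta mua| equals the scene's
    heterogeneity amplitude.  The field is confined above the chest wall.
    """
    if scene.hetero_amplitude <= 0:
        return np.empty((0, 3)), voxel**3, np.empty(0)
    rng = np.random.default_rng(scene.hetero_seed)
    ax = [np.arange(b[0] + voxel / 2, b[1], voxel) for b in bounds]
    shape = tuple(len(a) for a in ax)
    fld = gaussian_filter(rng.standard_normal(shape), sigma=correlation_cm / voxel)
    peak = np.abs(fld).max()
    if peak > 0:
        fld *= scene.hetero_amplitude / peak
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    vals = fld.ravel()
    keep = pts[:, 2] > 0
    if scene.chest_wall.present:
        plane = scene.chest_wall.depth + np.tan(
            np.deg2rad(scene.chest_wall.tilt_deg)
        ) * pts[:, 0]
        keep &= pts[:, 2] < plane
    return pts[keep], voxel**3, vals[keep]


def scene_inclusions(
    scene: Scene,
    include_target: bool = True,
    wall_depth_override: float | None = None,
    bounds=DEFAULT_VOLUME_BOUNDS,
) -> list[tuple[np.ndarray, float, np.ndarray]]:
    """Inclusion triples (centers, voxel volume, delta_mua) for the forward model."""
    inc = []
    if include_target:
        inc.append(voxelize_target(scene))
    inc.append(chest_wall_voxels(scene, bounds, depth_override=wall_depth_override))
    inc.append(heterogeneity_voxels(scene, bounds))
    return [i for i in inc if i[0].shape[0] > 0]


def simulate_scene(
    scene: Scene,
    geometry: ProbeGeometry,
    include_target: bool = True,
    wall_depth_override: float | None = None,
) -> FDMeasurement:
    """Noise-free lesion-side (or reference-side) measurement of a scene.

    Uses the exponential (Rytov) composition of the Born kernel: lesion and
    chest-wall contrasts in the corpus are strong enough that the linear
    composition would produce non-physical measurements (amplitude sign
    flips, relative perturbations below -1), while the exponential form
    keeps the matched perturbation within the physical [-1, 0] real-part
    range and lets structures shared by lesion and reference sides cancel
    in their ratio.
    """
    inc = scene_inclusions(scene, include_target, wall_depth_override)
    if not inc:
        return simulate_homogeneous(geometry, scene.background)
    return simulate_with_inclusions(
        geometry, scene.background, inc, composition="rytov"
    )


def _scene_measurement_pair(
    scene: Scene,
    geometry: ProbeGeometry,
    wall_depth_override: float | None = None,
) -> tuple[FDMeasurement, FDMeasurement]:
    """(lesion-side, reference-side) measurements sharing one Born evaluation.

    Equivalent to two `simulate_scene` calls but computes the chest-wall and
    heterogeneity sums once; the Rytov composition makes the shared factors
    identical on both sides by construction.
    """
    meas0 = simulate_homogeneous(geometry, scene.background)
    total_shared = np.zeros(geometry.n_pairs, dtype=complex)
    for centers, vols, dmua in scene_inclusions(
        scene, include_target=False, wall_depth_override=wall_depth_override
    ):
        total_shared += born_perturbation(
            geometry, scene.background, centers, vols, dmua, U0=meas0.U
        )
    centers, vols, dmua = voxelize_target(scene)
    p_target = born_perturbation(
        geometry, scene.background, centers, vols, dmua, U0=meas0.U
    )
    Ul = meas0.with_U(meas0.U * np.exp(p_target + total_shared))
    Ur = meas0.with_U(meas0.U * np.exp(total_shared))
    return Ul, Ur


def add_measurement_noise(
    meas: FDMeasurement,
    noise_fraction: float,
    rng,
    phase_sigma_rad: float = 0.02,
) -> FDMeasurement:
    """Multiplicative Gaussian amplitude noise + additive Gaussian phase noise."""
    if noise_fraction == 0:
        return meas
    rng = _rng(rng)
    n = meas.U.size
    amp = meas.amplitude * (1.0 + noise_fraction * rng.standard_normal(n))
    amp = np.abs(amp)  # 2% noise essentially never flips sign; guard anyway
    ph = np.angle(meas.U) + phase_sigma_rad * rng.standard_normal(n)
    return meas.with_U(amp * np.exp(1j * ph))


@dataclass
class TrainingSample:
    """One supervised pair: noisy lesion-side input, matched perturbation target."""

    x: np.ndarray  # (252,) normalized network input
    y: np.ndarray  # (252,) matched perturbation, real parts then imaginary
    scene: Scene
    seed: int
    Ul: FDMeasurement = field(repr=False, default=None)
    matched: Perturbation = field(repr=False, default=None)


def make_training_sample(
    scene: Scene,
    geometry: ProbeGeometry,
    noise_fraction: float = 0.02,
    rng_seed=0,
) -> TrainingSample:
    """Simulate one scene into a supervised sample.

    The lesion side carries target + chest wall + heterogeneity and the
    measurement noise; the matched reference shares background, wall and
    heterogeneity exactly and is noise-free, so the target label is the
    ideal matched perturbation.
    """
    rng = _rng(rng_seed)
    seed = int(rng.integers(0, 2**31 - 1))
    Ul_clean, Ur = _scene_measurement_pair(scene, geometry)
    Ul = add_measurement_noise(Ul_clean, noise_fraction, np.random.default_rng(seed))
    matched = compute_perturbation(Ul_clean, Ur)
    x = normalize_for_network(Ul).to_vector()
    return TrainingSample(
        x=x, y=matched.to_vector(), scene=scene, seed=seed, Ul=Ul, matched=matched
    )


def make_mismatch_pair(
    scene: Scene,
    geometry: ProbeGeometry,
    chest_wall_shift_cm: float = 1.0,
    noise_fraction: float = 0.02,
    rng_seed=0,
) -> tuple[FDMeasurement, FDMeasurement, FDMeasurement]:
    """Lesion-side measurement plus mismatched and matched references.

    The mismatched reference has its chest wall shallower by
    ``chest_wall_shift_cm`` than the lesion side -- the clinically
    problematic configuration in which measured perturbations shift in
    the positive direction and the target fails to reconstruct.
    """
    if not scene.chest_wall.present:
        raise ValueError("mismatch scenario requires a chest wall")
    shifted = scene.chest_wall.depth - chest_wall_shift_cm
    if shifted < scene.target.center[2] + scene.target.radius:
        import warnings

        warnings.warn("shifted chest wall is shallower than the target bottom")
    rng = _rng(rng_seed)
    Ul_clean, Ur_matched = _scene_measurement_pair(scene, geometry)
    Ul = add_measurement_noise(Ul_clean, noise_fraction, rng)
    Ur_mismatched = simulate_scene(
        scene, geometry, include_target=False, wall_depth_override=shifted
    )
    return Ul, Ur_mismatched, Ur_matched


@dataclass
class Corpus:
    """Stacked supervised corpus (inputs X, targets Y, per-sample scenes)."""

    X: np.ndarray  # (n, 252)
    Y: np.ndarray  # (n, 252)
    scenes: list
    seeds: np.ndarray

    def __len__(self) -> int:
        return self.X.shape[0]


def split_sizes(n_total: int, train_fraction: float = 0.8) -> tuple[int, int]:
    """Train/validation sizes: floor(train_fraction * n) and the remainder."""
    n_train = int(np.floor(train_fraction * n_total))
    return n_train, n_total - n_train


def build_corpus(
    n_total: int,
    geometry: ProbeGeometry,
    train_fraction: float = 0.8,
    noise_fraction: float = 0.02,
    rng_seed=0,
) -> tuple[Corpus, Corpus]:
    """Generate a corpus of ``n_total`` scenes and split train/validation.

    The split is random, disjoint, with ``floor(train_fraction * n)``
    training samples; everything is a pure function of the seed.
    """
    if n_total < 2:
        raise ValueError("need at least 2 samples to split")
    rng = _rng(rng_seed)
    X = np.empty((n_total, 2 * geometry.n_pairs))
    Y = np.empty_like(X)
    scenes, seeds = [], np.empty(n_total, dtype=np.int64)
    for i in range(n_total):
        scene = sample_scene(rng)
        s = make_training_sample(scene, geometry, noise_fraction, rng)
        X[i], Y[i] = s.x, s.y
        scenes.append(scene)
        seeds[i] = s.seed
    n_train, _ = split_sizes(n_total, train_fraction)
    perm = rng.permutation(n_total)
    tr, va = perm[:n_train], perm[n_train:]
    mk = lambda idx: Corpus(
        X=X[idx], Y=Y[idx], scenes=[scenes[j] for j in idx], seeds=seeds[idx]
    )
    return mk(tr), mk(va)
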