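"""Synthetic thigh-phantom generator.

Generates 2-D MR-like slices of a thigh cross-section: a bright
subcutaneous-fat ring enclosing a darker muscle compartment, a dark(er)
bone disc inside the muscle, and — in the "hard" domain — bright fatty
infiltration blobs scattered through the muscle at a controllable area
fraction.  The essential statistical property is that the two domains share
one geometry (ground-truth shape) distribution and differ only in intensity
content: infiltration is generated at exactly the subcutaneous-fat gray
level, so the two tissues cannot be separated by thresholding.  Ground-truth
muscle masks include the infiltrated regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_TISSUE_LEVELS = {
    "background": 0.05,
    "bone": 0.15,
    "muscle": 0.35,
    "subcutaneous_fat": 0.85,
    "infiltration": 0.85,
}


@dataclass
class PhantomConfig:
    """Generation parameters for one phantom study.

    ``infiltration_fraction`` is the target fraction of muscle area replaced
    by bright blobs; ``geometry_jitter`` is the relative variability of the
    ellipse axes and positions across subjects; ``noise_sd`` is additive
    Gaussian noise on the [0, 1] intensity scale.
    """

    image_size: int = 64
    infiltration_fraction: float = 0.0
    noise_sd: float = 0.03
    tissue_levels: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_LEVELS))
    geometry_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0.0 <= self.infiltration_fraction <= 1.0:
            raise ValueError("infiltration_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lv = self.tissue_levels
        if lv["infiltration"] != lv["subcutaneous_fat"]:
            raise ValueError("infiltration level must equal subcutaneous-fat level")
        if not lv["background"] < lv["muscle"] < lv["subcutaneous_fat"]:
            raise ValueError("tissue levels must satisfy background < muscle < fat")


@dataclass
class SubjectGeometry:
    """Jittered per-subject ellipse/disc parameters (pixel units)."""

    center: tuple[float, float]
    outer_axes: tuple[float, float]     # fat/outer thigh boundary semi-axes
    muscle_axes: tuple[float, float]
    bone_center: tuple[float, float]
    bone_radius: float


@dataclass
class PhantomSlice:
    image: np.ndarray                   # float in [0, 1]
    muscle_mask: np.ndarray             # bool; includes infiltrated regions
    fat_mask: np.ndarray
    bone_mask: np.ndarray
    infiltration_mask: np.ndarray
    realized_infiltration_fraction: float
    subject_id: str


@dataclass
class DomainDataset:
    slices: list[PhantomSlice]
    domain_label: str                   # "easy" or "hard"

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def n_subjects(self) -> int:
        return len({s.subject_id for s in self.slices})

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.slices:
            seen.setdefault(s.subject_id, None)
        return list(seen)


def sample_subject_geometry(config: PhantomConfig, rng: np.random.Generator) -> SubjectGeometry:
    s = float(config.image_size)
    j = config.geometry_jitter

    def jit(scale=1.0):
        return 1.0 + j * scale * rng.uniform(-1.0, 1.0)

    cx = s / 2 + 0.02 * s * rng.uniform(-1, 1)
    cy = s / 2 + 0.02 * s * rng.uniform(-1, 1)
    a_out = min(0.44 * s * jit(), 0.47 * s)
    b_out = min(0.40 * s * jit(), 0.47 * s)
    a_mus = 0.72 * a_out * jit(0.5)
    b_mus = 0.72 * b_out * jit(0.5)
    br = 0.08 * s * jit()
    # bone kept well inside the muscle ellipse
    bcx = cx + 0.08 * s * rng.uniform(-1, 1)
    bcy = cy + 0.08 * s * rng.uniform(-1, 1)
    return SubjectGeometry((cx, cy), (a_out, b_out), (a_mus, b_mus), (bcx, bcy), br)


def _ellipse_mask(size: int, center, axes) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = center[1], center[0]
    return ((yy - cy) / axes[1]) ** 2 + ((xx - cx) / axes[0]) ** 2 <= 1.0


def _disc_mask(size: int, center, radius) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - center[1]) ** 2 + (xx - center[0]) ** 2 <= radius ** 2


def generate_phantom_slice(config: PhantomConfig, geometry: SubjectGeometry,
                           slice_seed: int) -> PhantomSlice:
    """Render one slice: concentric fat ring / muscle / bone, plus blobs.

    Infiltration discs are accepted only if they lie fully inside the muscle
    mask, and placement stops once the realized area fraction is within the
    ±0.05 band around the target (or the muscle saturates).
    """
    rng = np.random.default_rng(slice_seed)
    size = config.image_size
    target = config.infiltration_fraction

    outer = _ellipse_mask(size, geometry.center, geometry.outer_axes)
    muscle_region = _ellipse_mask(size, geometry.center, geometry.muscle_axes)
    bone = _disc_mask(size, geometry.bone_center, geometry.bone_radius) & muscle_region
    fat = outer & ~muscle_region
    muscle = muscle_region & ~bone
    n_muscle = int(muscle.sum())
    if n_muscle == 0:
        raise ValueError("degenerate geometry: muscle region is empty")

    infil = np.zeros((size, size), dtype=bool)
    realized = 0.0
    attempts = 0
    max_attempts = 4000
    ys, xs = np.nonzero(muscle)
    while realized < target - 0.01 and attempts < max_attempts:
        attempts += 1
        i = rng.integers(len(ys))
        cy, cx = ys[i], xs[i]
        remaining = (target + 0.04 - realized) * n_muscle
        r_cap = max(1.5, np.sqrt(remaining / np.pi))
        r = rng.uniform(1.5, min(0.09 * size, r_cap))
        blob = _disc_mask(size, (cx, cy), r)
        if not blob.any() or not (blob <= muscle).all():
            continue
        new = infil | blob
        if new.sum() / n_muscle > target + 0.05:
            continue
        infil = new
        realized = infil.sum() / n_muscle

    lv = config.tissue_levels
    img = np.full((size, size), lv["background"], dtype=np.float64)
    img[fat] = lv["subcutaneous_fat"]
    img[muscle] = lv["muscle"]
    img[bone] = lv["bone"]
    img[infil] = lv["infiltration"]
    if config.noise_sd > 0:
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    return PhantomSlice(
        image=img,
        muscle_mask=muscle,
        fat_mask=fat,
        bone_mask=bone,
        infiltration_mask=infil,
        realized_infiltration_fraction=float(realized),
        subject_id="",
    )


def generate_domain_datasets(n_easy_subjects: int, n_hard_subjects: int,
                             slices_per_subject: int, config: PhantomConfig,
                             hard_fraction_range: tuple[float, float] = (0.2, 0.7),
                             easy_fraction_max: float = 0.02,
                             ) -> tuple[DomainDataset, DomainDataset]:
    """Generate unpaired easy/hard datasets sharing one geometry distribution.

    Easy slices carry (near-)zero infiltration; hard slices draw a target
    fraction uniformly from ``hard_fraction_range``.  Geometry is sampled per
    subject from the same distribution in both domains, so ground-truth shape
    statistics match across domains while intensity content differs.
    """
    if min(n_easy_subjects, n_hard_subjects, slices_per_subject) < 1:
        raise ValueError("all counts must be >= 1")
    root = np.random.SeedSequence(config.seed)
    easy_ss, hard_ss = root.spawn(2)

    def build(domain: str, n_subjects: int, ss: np.random.SeedSequence) -> DomainDataset:
        slices = []
        for si, sub_ss in enumerate(ss.spawn(n_subjects)):
            child = sub_ss.spawn(slices_per_subject + 1)
            geo_rng = np.random.default_rng(child[0])
            geometry = sample_subject_geometry(config, geo_rng)
            for k in range(slices_per_subject):
                if domain == "easy":
                    frac = geo_rng.uniform(0.0, easy_fraction_max)
                else:
                    frac = geo_rng.uniform(*hard_fraction_range)
                cfg_k = PhantomConfig(
                    image_size=config.image_size,
                    infiltration_fraction=float(frac),
                    noise_sd=config.noise_sd,
                    tissue_levels=config.tissue_levels,
                    geometry_jitter=config.geometry_jitter,
                    seed=config.seed,
                )
                seed_k = int(np.random.default_rng(child[k + 1]).integers(2 ** 31))
                sl = generate_phantom_slice(cfg_k, geometry, seed_k)
                sl.subject_id = f"{domain}{si:03d}"
                slices.append(sl)
        return DomainDataset(slices=slices, domain_label=domain)

    return build("easy", n_easy_subjects, easy_ss), build("hard", n_hard_subjects, hard_ss)
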