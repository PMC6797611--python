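"""Phantom data generators with known ground truth.

These generators emulate the inputs of the pipeline — a mirror-symmetric
integer-labeled parcellation, per-subject scalar maps with planted
subgroup structure, and 4D time series with planted connectivity hubs —
so every stage is testable without any external dataset.  Noise is
i.i.d. Gaussian per voxel: the simplest model sufficient to exercise
extraction, clustering, smoothing and the per-region t-tests.  Spatial
autocorrelation and hemodynamics are deliberately not simulated.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .atlas_model import AtlasArea, AtlasDefinition
from .volumes import LabelVolume, ScalarVolume, TimeSeriesVolume, ValidationError

_REGION_TAGS = ["FRO", "TEM", "PAR", "OCC", "INS", "LIM", "SUB", "CER"]


@dataclass
class PhantomSpec:
    """Geometry of a block-structured phantom parcellation."""

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_gross_regions: int = 2
    areas_per_region_per_hemisphere: int = 2
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    seed: int = 0

    @property
    def M(self) -> int:
        return 2 * self.n_gross_regions * self.areas_per_region_per_hemisphere


@dataclass
class GroupEffectSpec:
    """Planted subject-subgroup structure for scalar maps."""

    n_subjects: int
    n_clusters: int
    cluster_region_means: np.ndarray  # (n_clusters, M)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.cluster_region_means = np.asarray(self.cluster_region_means, dtype=float)
        if self.n_clusters > self.n_subjects:
            raise ValidationError("n_clusters cannot exceed n_subjects")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if self.cluster_region_means.shape[0] != self.n_clusters:
            raise ValidationError(
                "cluster_region_means must have one row per cluster"
            )


def make_phantom_atlas(spec: PhantomSpec) -> tuple[LabelVolume, AtlasDefinition]:
    """Block-structured mirror-symmetric parcellation.

    The left half of the x-axis carries the L areas; the right half is
    their mirror image.  Within a hemisphere, gross regions are bands
    along y and areas bands along z.  Every area must get at least 8
    voxels.  Leftover voxels (from non-divisible shapes) stay background.
    """
    nx, ny, nz = spec.grid_shape
    hx = nx // 2
    gy = ny // spec.n_gross_regions
    az = nz // spec.areas_per_region_per_hemisphere
    if hx < 1 or gy < 1 or az < 1 or hx * gy * az < 8:
        raise ValidationError(
            f"{spec.M} areas do not fit in grid {spec.grid_shape} with >= 8 voxels each"
        )
    grid = np.zeros(spec.grid_shape, dtype=np.int64)
    definition = AtlasDefinition()
    label = 0
    half = spec.M // 2
    for hemi_i, hemi in enumerate(("L", "R")):
        for g in range(spec.n_gross_regions):
            tag = _REGION_TAGS[g % len(_REGION_TAGS)] + (
                "" if g < len(_REGION_TAGS) else str(g)
            )
            for a in range(spec.areas_per_region_per_hemisphere):
                label += 1
                definition.add_area(
                    AtlasArea(label, f"{tag}_{a + 1}", tag, hemi)
                )
                ys = slice(g * gy, (g + 1) * gy)
                zs = slice(a * az, (a + 1) * az)
                if hemi == "L":
                    xs = slice(0, hx)
                else:
                    xs = slice(nx - hx, nx)
                grid[xs, ys, zs] = label
    # mirror exactness: R block at x is the reflection of the L block
    vol = LabelVolume(grid, spec.voxel_size, space_tag=f"phantom-seed{spec.seed}")
    assert definition.M == spec.M and half * 2 == spec.M
    return vol, definition


def make_subject_maps(
    atlas: LabelVolume,
    definition: AtlasDefinition,
    effects: GroupEffectSpec,
) -> tuple[list[ScalarVolume], np.ndarray]:
    """Scalar maps with planted cluster structure.

    Subject j belongs to planted cluster ``j mod n_clusters``; inside
    area i its voxels are ``cluster_region_means[c, i]`` plus i.i.d.
    Gaussian noise; background voxels are noise only.
    """
    if effects.cluster_region_means.shape[1] != definition.M:
        raise ValidationError(
            f"cluster_region_means has {effects.cluster_region_means.shape[1]} "
            f"regions, definition has {definition.M}"
        )
    rng = np.random.default_rng(effects.seed)
    planted = np.arange(effects.n_subjects) % effects.n_clusters
    region_masks = [atlas.grid == a.label for a in definition.areas]
    maps = []
    for j in range(effects.n_subjects):
        c = planted[j]
        vol = effects.noise_sd * rng.standard_normal(atlas.grid.shape)
        for i, mask in enumerate(region_masks):
            vol[mask] += effects.cluster_region_means[c, i]
        maps.append(
            ScalarVolume(vol, atlas.voxel_size, space_tag=f"sub-{j + 1:02d}")
        )
    return maps, planted


def make_synthetic_timeseries(
    grid_shape: tuple[int, int, int],
    T: int,
    hub_voxels: list[tuple[int, int, int]] = (),
    hub_strength: float = 0.8,
    tr_seconds: float = 2.2,
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0),
    seed: int = 0,
) -> TimeSeriesVolume:
    """4D noise with planted connectivity hubs.

    Each hub voxel carries a latent signal; its six face neighbors mix
    that signal in at ``hub_strength`` (correlation ≈ hub_strength with
    the hub), all other voxels are i.i.d. unit Gaussian noise.
    """
    if T < 10:
        raise ValidationError("need at least 10 time points")
    if not (0.0 <= hub_strength < 1.0):
        raise ValidationError("hub_strength must be in [0, 1)")
    rng = np.random.default_rng(seed)
    grid = rng.standard_normal((*grid_shape, T))
    shape = np.array(grid_shape)
    for hub in hub_voxels:
        hub = tuple(int(v) for v in hub)
        latent = rng.standard_normal(T)
        grid[hub] = latent
        if hub_strength > 0:
            for axis, delta in product(range(3), (-1, 1)):
                nb = np.array(hub)
                nb[axis] += delta
                if np.all((nb >= 0) & (nb < shape)):
                    noise = rng.standard_normal(T)
                    grid[tuple(nb)] = (
                        hub_strength * latent
                        + np.sqrt(1.0 - hub_strength**2) * noise
                    )
    return TimeSeriesVolume(
        grid, tr_seconds, None, voxel_size, space_tag=f"synth-seed{seed}"
    )
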