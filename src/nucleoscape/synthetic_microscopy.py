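"""Synthetic 3D confocal stacks of cell nuclei with exact ground truth.

Emulates the acquisitions quantified in nuclear-architecture studies of
scattering hepatic progenitor cells: an ellipsoidal DAPI-stained nucleus
(~250 um^3) containing bright chromocenters (pan-centromeric FISH channel),
H3K9me3 heterochromatin foci that co-localize with chromocenters, and small
locus FISH spots placed at controlled radial positions.  Every rendered
object is recorded in a ground-truth table so segmentation, volumetry and
radial positioning can be validated against known answers.

Geometry conventions
--------------------
Physical coordinates are (x, y, z) in micrometres.  Intensity arrays are
indexed ``[z, y, x]`` (z = optical sections, matching multi-page TIFF).
Voxel (i, j, k) along (x, y, z) occupies a half-open box whose centre is at
``((i + 0.5) dx, (j + 0.5) dy, (k + 0.5) dz)``; all physical outputs refer
to voxel centres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CHANNELS",
    "ResolutionError",
    "CONDITION_PRESETS",
    "condition_config",
    "VoxelGrid",
    "GenerationConfig",
    "GroundTruthTable",
    "sample_count",
    "sample_volumes",
    "sample_radial_fractions",
    "place_locus_spots",
    "generate_nuclei_dataset",
]

#: channel order used throughout: DAPI counterstain, pan-centromeric FISH
#: (chromocenters), H3K9me3 immunofluorescence (heterochromatin foci),
#: locus FISH (gene-position spots)
CHANNELS = ("dapi", "centromere", "h3k9me3", "locus")


class ResolutionError(ValueError):
    """Objects would be rendered below ~2 voxels diameter on some axis."""


#: chromocenter set points for the three emulated conditions: mean volume
#: (um^3) per chromocenter and mean count per nucleus.  Counts conserve the
#: total chromocenter material (~40 um^3 per nucleus) across conditions —
#: the disaggregation signature: blockade/stimulation splits heterochromatin
#: into more, smaller chromocenters at unchanged nuclear volume — and put
#: 5-10 elements per nucleus, matching the 500-1000 measured elements per
#: condition in ~100-nucleus experiments.
CONDITION_PRESETS = {
    "control": {"mean_volume": 8.0, "mean_count": 5.0},
    "antibody": {"mean_volume": 6.0, "mean_count": 40.0 / 6.0},
    "hgf": {"mean_volume": 4.0, "mean_count": 10.0},
}


def condition_config(condition: str, n_nuclei: int = 100, seed: int = 0,
                     **overrides) -> "GenerationConfig":
    """A :class:`GenerationConfig` at one condition's chromocenter set point.

    ``condition`` is ``"control"`` (untreated), ``"antibody"`` (integrin
    blockade) or ``"hgf"`` (HGF/SF1 stimulation); the chromocenter volume
    law is lognormal with the condition's mean and sd = 30% of the mean.
    """
    preset = CONDITION_PRESETS[condition]
    kwargs = dict(
        n_nuclei=n_nuclei,
        chromocenter_volume_law=(
            "lognormal", preset["mean_volume"], 0.3 * preset["mean_volume"]
        ),
        chromocenter_count_law=("poisson", preset["mean_count"]),
        seed=seed,
    )
    kwargs.update(overrides)
    return GenerationConfig(**kwargs)


@dataclass
class VoxelGrid:
    """A single-channel 3D intensity stack with physical voxel dimensions.

    Parameters
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Non-negative intensities in arbitrary units.
    voxel_size : (dx, dy, dz)
        Voxel edge lengths in micrometres.
    channel : str
        Channel label (one of :data:`CHANNELS` for generated data).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or min(self.intensities.shape) < 1:
            raise ValueError("intensities must be a 3D array with >=1 voxel per axis")
        if len(self.voxel_size) != 3 or any(d <= 0 for d in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (dx, dy, dz)")
        self.voxel_size = tuple(float(d) for d in self.voxel_size)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    def axis_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical centre coordinates along (x, y, z)."""
        nz, ny, nx = self.intensities.shape
        dx, dy, dz = self.voxel_size
        return (
            (np.arange(nx) + 0.5) * dx,
            (np.arange(ny) + 0.5) * dy,
            (np.arange(nz) + 0.5) * dz,
        )


# ---------------------------------------------------------------------------
# sampling laws (small tagged tuples so they serialize to YAML as lists)
# ---------------------------------------------------------------------------

def sample_count(law, rng: np.random.Generator) -> int:
    """Draw one object count from a named law.

    Supported: ``("poisson", mean)`` and ``("fixed", n)``.
    """
    name = law[0]
    if name == "poisson":
        return int(rng.poisson(float(law[1])))
    if name == "fixed":
        return int(law[1])
    raise ValueError(f"unknown count law {name!r}")


def sample_volumes(law, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` object volumes (um^3) from a named law.

    ``("lognormal", mean, sd)`` draws right-skewed positive volumes with the
    given arithmetic mean and standard deviation; ``("fixed", v)`` is a point
    mass.
    """
    name = law[0]
    if name == "fixed":
        return np.full(n, float(law[1]))
    if name == "lognormal":
        mean, sd = float(law[1]), float(law[2])
        if mean <= 0 or sd < 0:
            raise ValueError("lognormal volume law needs mean > 0, sd >= 0")
        if sd == 0:
            return np.full(n, mean)
        sigma2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)
    raise ValueError(f"unknown volume law {name!r}")


def sample_radial_fractions(law, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` radial fractions in [0, 1] from a named law.

    Supported laws:

    * ``("point", v)`` — all spots at fraction ``v``;
    * ``("uniform", lo, hi)`` — uniform on ``[lo, hi] ⊆ [0, 1]``;
    * ``("uniform_volume",)`` — uniform placement per unit volume, i.e. the
      fraction has CDF ``r**3`` (exact for any ellipsoid, as the affine image
      of the ball);
    * ``("beta", a, b)`` — Beta(a, b) distributed fraction.
    """
    name = law[0]
    if name == "point":
        v = float(law[1])
        if not 0.0 <= v <= 1.0:
            raise ValueError("point law must lie in [0, 1]")
        return np.full(n, v)
    if name == "uniform":
        lo, hi = float(law[1]), float(law[2])
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("uniform law support must be within [0, 1]")
        return rng.uniform(lo, hi, size=n)
    if name == "uniform_volume":
        return rng.random(n) ** (1.0 / 3.0)
    if name == "beta":
        return rng.beta(float(law[1]), float(law[2]), size=n)
    raise ValueError(f"unknown radial law {name!r}")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GenerationConfig:
    """Acquisition geometry and object statistics for one synthetic dataset.

    Defaults reproduce the study conditions being emulated: nuclei of
    ~250 um^3 imaged at 250 nm axial spacing, chromocenters whose mean
    volume is the untreated set point (8 um^3, sd 30% of the mean), and a
    few peripherally biased locus spots per nucleus.  ``chromocenter_count_law``
    defaults to Poisson(6) so that ~100 nuclei yield the 500-1000 measured
    elements per condition typical of such experiments while keeping the
    packed chromocenter volume fraction physically plausible.
    """

    nucleus_semiaxes: tuple[float, float, float] = (4.2, 4.0, 3.55)
    voxel_size: tuple[float, float, float] = (0.2, 0.2, 0.25)
    n_nuclei: int = 50
    chromocenter_count_law: tuple = ("poisson", 5.0)
    chromocenter_volume_law: tuple = ("lognormal", 8.0, 2.4)
    focus_channel_offset: tuple = ("gaussian", 0.1)
    locus_radial_law: tuple = ("uniform", 0.8, 1.0)
    locus_spots_per_nucleus: int = 2
    locus_spot_radius: float = 0.3
    psf_sigma: tuple[float, float, float] = (0.15, 0.15, 0.3)
    noise_model: tuple = ("poisson", 1.0)
    seed: int = 0
    # rendering details
    nucleus_volume_cv: float = 0.10
    amplitude: float = 200.0
    background: float = 5.0
    margin_um: float = 0.8
    min_gap_um: float = 0.5
    min_gap_axial_um: float = 0.9
    max_overlap_fraction: float = 0.05
    placement_attempts: int = 500

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if any(a <= 0 for a in self.nucleus_semiaxes):
            raise ValueError("nucleus semiaxes must be positive")
        if any(d <= 0 for d in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.n_nuclei < 0 or self.locus_spots_per_nucleus < 0:
            raise ValueError("counts must be non-negative")
        if self.locus_spot_radius <= 0:
            raise ValueError("locus spot radius must be positive")
        # refuse configurations whose expected objects fall below the sampling
        # limit (~2 voxels diameter on every axis): such objects cannot be
        # rendered or measured meaningfully.
        diam_limits = [2.0 * d for d in self.voxel_size]
        renders_chromocenters = not (
            self.chromocenter_count_law[0] == "fixed"
            and self.chromocenter_count_law[1] == 0
        ) and float(self.chromocenter_count_law[1]) > 0
        if renders_chromocenters:
            mean_v = float(self.chromocenter_volume_law[1])
            d_cc = 2.0 * sphere_radius(mean_v)
            if any(d_cc < lim for lim in diam_limits):
                raise ResolutionError(
                    f"mean chromocenter diameter {d_cc:.3f} um is below 2 voxels "
                    f"on some axis for voxel size {self.voxel_size}"
                )
        if self.locus_spots_per_nucleus > 0:
            d_spot = 2.0 * self.locus_spot_radius
            if any(d_spot < lim for lim in diam_limits):
                raise ResolutionError(
                    f"locus spot diameter {d_spot:.3f} um is below 2 voxels on "
                    f"some axis for voxel size {self.voxel_size}"
                )

    @property
    def nucleus_volume(self) -> float:
        """Mean ellipsoid volume implied by the semiaxes (um^3)."""
        a, b, c = self.nucleus_semiaxes
        return 4.0 / 3.0 * math.pi * a * b * c


def sphere_radius(volume: float) -> float:
    """Radius of the sphere with the given volume."""
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass
class GroundTruthTable:
    """Exact per-nucleus and per-object truth for one generated dataset.

    ``nuclei`` has one row per nucleus (id, true analytic volume, semiaxes,
    centre).  ``objects`` has one row per rendered object with its channel,
    true centre (um), analytic volume, voxelized volume (voxel count x voxel
    volume of the noise-free binary rendering), overlap flag, and — for locus
    spots — the true radial fraction.
    """

    nuclei: pd.DataFrame
    objects: pd.DataFrame
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "nuclei": self.nuclei.to_dict(orient="list"),
            "objects": self.objects.to_dict(orient="list"),
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthTable":
        return cls(
            nuclei=pd.DataFrame(d["nuclei"]),
            objects=pd.DataFrame(d["objects"]),
            warnings=list(d.get("warnings", [])),
        )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def ray_boundary_distance(direction: np.ndarray, semiaxes) -> float:
    """Distance from the ellipsoid centre to its surface along ``direction``."""
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    a, b, c = semiaxes
    return 1.0 / math.sqrt((u[0] / a) ** 2 + (u[1] / b) ** 2 + (u[2] / c) ** 2)


def _uniform_sphere_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    # a zero vector has probability zero; guard anyway
    norms[norms == 0] = 1.0
    return v / norms


def place_locus_spots(radial_law, n_spots: int, nucleus_geometry, seed) -> tuple[np.ndarray, np.ndarray]:
    """Place locus FISH spots at controlled radial fractions.

    The true radial fraction of each spot — its distance from the nucleus
    centre divided by the centre-to-boundary distance along the same ray —
    is drawn from ``radial_law``; the direction is uniform on the sphere.

    Parameters
    ----------
    radial_law : tuple
        Law over [0, 1], see :func:`sample_radial_fractions`.
    n_spots : int
        Number of spots.
    nucleus_geometry : (center, semiaxes)
        Ellipsoid centre (um, length 3) and semiaxes (um, length 3).
    seed : int or numpy.random.Generator

    Returns
    -------
    centers : ndarray, shape (n_spots, 3)
        Spot centres in physical (x, y, z) um.
    fractions : ndarray, shape (n_spots,)
        The true radial fraction of each spot.
    """
    if n_spots < 0:
        raise ValueError("n_spots must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    center, semiaxes = nucleus_geometry
    center = np.asarray(center, dtype=float)
    fractions = sample_radial_fractions(radial_law, n_spots, rng)
    dirs = _uniform_sphere_directions(n_spots, rng)
    centers = np.empty((n_spots, 3))
    for i in range(n_spots):
        t = ray_boundary_distance(dirs[i], semiaxes)
        centers[i] = center + fractions[i] * t * dirs[i]
    return centers, fractions


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _sphere_mask(grid_axes, center, radius) -> np.ndarray:
    """Boolean mask of voxels whose centres fall inside the sphere."""
    xs, ys, zs = grid_axes
    dx2 = (xs - center[0]) ** 2
    dy2 = (ys - center[1]) ** 2
    dz2 = (zs - center[2]) ** 2
    return (dz2[:, None, None] + dy2[None, :, None] + dx2[None, None, :]) <= radius**2


def _ellipsoid_mask(grid_axes, center, semiaxes) -> np.ndarray:
    xs, ys, zs = grid_axes
    ex = ((xs - center[0]) / semiaxes[0]) ** 2
    ey = ((ys - center[1]) / semiaxes[1]) ** 2
    ez = ((zs - center[2]) / semiaxes[2]) ** 2
    return (ez[:, None, None] + ey[None, :, None] + ex[None, None, :]) <= 1.0


def _project_into_ellipsoid(p, ero):
    """Pull a point back inside the (eroded) ellipsoid if it escaped."""
    q = np.asarray(p) / ero
    norm = math.sqrt(float(np.sum(q * q)))
    if norm > 1.0:
        p = p * (0.999 / norm)
    return p


def _place_spheres(radii, semiaxes, center, min_gap, min_gap_axial, attempts, rng):
    """Place spheres inside an ellipsoid with direction-dependent gaps.

    The required surface-to-surface gap interpolates from ``min_gap``
    (lateral separations) to ``min_gap_axial`` (separations along the
    optical axis), mirroring the elongated axial point-spread function: two
    objects need more z-clearance than xy-clearance to remain resolvable.
    Spheres are placed largest-first by rejection sampling inside the eroded
    ellipsoid; a pairwise repulsion relaxation then resolves residual
    conflicts, which matters at the high packing fractions chromocenters
    reach in small nuclei.  Objects still overlapping after relaxation are
    flagged.
    """
    n = len(radii)
    radii = np.asarray(radii, dtype=float)
    if n == 0:
        return np.zeros((0, 3)), np.zeros(0, dtype=bool), 0.0

    def gap_req(delta: np.ndarray, d: float) -> float:
        uz2 = (delta[2] / d) ** 2 if d > 0 else 1.0
        return min_gap + (min_gap_axial - min_gap) * uz2

    eros = np.maximum(np.asarray(semiaxes)[None, :] - radii[:, None], 1e-3)
    order = np.argsort(radii)[::-1]

    def one_configuration():
        centers = np.zeros((n, 3))
        placed: list[int] = []
        for idx in order:
            r = radii[idx]
            ero = eros[idx]
            best_pos, best_clear = None, -np.inf
            for _ in range(attempts):
                p = rng.uniform(-1.0, 1.0, size=3) * ero
                if float(np.sum((p / ero) ** 2)) > 1.0:
                    continue
                clear = np.inf
                for j in placed:
                    delta = centers[j] - p
                    d = float(np.linalg.norm(delta))
                    clear = min(clear, d - (radii[j] + r) - gap_req(delta, d))
                if clear >= 0.0:
                    best_pos, best_clear = p, clear
                    break
                if clear > best_clear:
                    best_pos, best_clear = p, clear
            centers[idx] = best_pos
            placed.append(idx)

        # pairwise repulsion relaxation (nucleus-local coordinates)
        for _ in range(400):
            moved = False
            for i in range(n):
                for j in range(i + 1, n):
                    delta = centers[j] - centers[i]
                    d = float(np.linalg.norm(delta))
                    if d < 1e-9:
                        delta = rng.normal(size=3)
                        d = float(np.linalg.norm(delta))
                    need = radii[i] + radii[j] + gap_req(delta, d)
                    if d >= need:
                        continue
                    push = 0.55 * (need - d) * delta / d
                    centers[i] -= push
                    centers[j] += push
                    moved = True
            for i in range(n):
                centers[i] = _project_into_ellipsoid(centers[i], eros[i])
            if not moved:
                break

        # residual shortfall against the blur-safe separation (not merely
        # sphere penetration: a positive but sub-blur gap also merges objects)
        depth = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                delta = centers[j] - centers[i]
                d = float(np.linalg.norm(delta))
                need = radii[i] + radii[j] + gap_req(delta, d)
                depth += max(need - d, 0.0)
        return centers, depth

    best_centers, best_depth = one_configuration()
    restarts = 0
    while best_depth > 1e-9 and restarts < 5:
        cand, depth = one_configuration()
        if depth < best_depth:
            best_centers, best_depth = cand, depth
        restarts += 1
    centers = best_centers

    overlapping = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centers[j] - centers[i]) < radii[i] + radii[j]:
                overlapping[i] = overlapping[j] = True
    return centers + np.asarray(center)[None, :], overlapping, best_depth


def _render_channel(mask, config, sigma_vox, rng) -> np.ndarray:
    """Turn a binary object mask into a blurred, noised intensity image."""
    img = np.where(mask, config.amplitude, 0.0).astype(np.float32)
    img += config.background
    if any(s > 0 for s in sigma_vox):
        img = ndimage.gaussian_filter(img, sigma=sigma_vox)
    model = config.noise_model
    if model is not None and model[0] != "none":
        if model[0] == "poisson":
            scale = float(model[1])
            img = rng.poisson(np.maximum(img, 0.0) * scale).astype(np.float32) / scale
        else:
            raise ValueError(f"unknown noise model {model[0]!r}")
    return img


def generate_nuclei_dataset(config: GenerationConfig):
    """Generate a dataset of multi-channel nuclear stacks with ground truth.

    Returns
    -------
    stacks : list of dict
        One entry per nucleus mapping channel name -> :class:`VoxelGrid`.
    truth : GroundTruthTable
        Exact truth for every nucleus and rendered object.  Deterministic for
        a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dx, dy, dz = config.voxel_size
    # z-axis PSF sigma pairs with the z voxel size
    sigma_vox = (
        config.psf_sigma[2] / dz,
        config.psf_sigma[1] / dy,
        config.psf_sigma[0] / dx,
    )

    nuclei_rows = []
    object_rows = []
    warnings: list[str] = []
    stacks: list[dict[str, VoxelGrid]] = []

    for nuc_id in range(config.n_nuclei):
        # per-nucleus size jitter around the mean ellipsoid volume
        if config.nucleus_volume_cv > 0:
            factor = -1.0
            while factor <= 0.1:  # truncate absurd draws
                factor = rng.normal(1.0, config.nucleus_volume_cv)
        else:
            factor = 1.0
        semiaxes = np.asarray(config.nucleus_semiaxes) * factor ** (1.0 / 3.0)
        nuc_volume = 4.0 / 3.0 * math.pi * float(np.prod(semiaxes))

        extent = semiaxes + config.margin_um
        shape = (
            max(int(math.ceil(2 * extent[2] / dz)), 1),
            max(int(math.ceil(2 * extent[1] / dy)), 1),
            max(int(math.ceil(2 * extent[0] / dx)), 1),
        )
        center = np.array(
            [shape[2] * dx / 2.0, shape[1] * dy / 2.0, shape[0] * dz / 2.0]
        )
        axes = (
            (np.arange(shape[2]) + 0.5) * dx,
            (np.arange(shape[1]) + 0.5) * dy,
            (np.arange(shape[0]) + 0.5) * dz,
        )

        nuclei_rows.append(
            {
                "nucleus_id": nuc_id,
                "volume_um3": nuc_volume,
                "semi_a": semiaxes[0],
                "semi_b": semiaxes[1],
                "semi_c": semiaxes[2],
                "center_x": center[0],
                "center_y": center[1],
                "center_z": center[2],
            }
        )

        # --- chromocenters (pan-centromeric channel) -----------------------
        # the drawn count is kept (it defines the condition); a volume
        # complement that cannot be packed at blur-safe separations is
        # redrawn (bounded retries) and residual conflicts are flagged per
        # object so merged detections remain attributable
        max_r = float(np.min(semiaxes)) - 0.1
        n_cc = sample_count(config.chromocenter_count_law, rng)
        best = None
        for _redraw in range(4):
            cc_volumes = sample_volumes(config.chromocenter_volume_law, n_cc, rng)
            cc_radii = np.minimum(
                np.array([sphere_radius(v) for v in cc_volumes]), max_r
            )
            cc_volumes = 4.0 / 3.0 * math.pi * cc_radii**3
            cc_centers, cc_overlap, depth = _place_spheres(
                cc_radii, semiaxes, center, config.min_gap_um,
                config.min_gap_axial_um, config.placement_attempts, rng,
            )
            if best is None or depth < best[-1]:
                best = (cc_volumes, cc_radii, cc_centers, cc_overlap, depth)
            if depth <= 1e-9:
                break
        cc_volumes, cc_radii, cc_centers, cc_overlap, _depth = best

        # --- H3K9me3 foci: chromocenters displaced by a small offset -------
        if config.focus_channel_offset[0] == "gaussian":
            off_sd = float(config.focus_channel_offset[1])
            offsets = rng.normal(0.0, off_sd, size=(n_cc, 3))
        elif config.focus_channel_offset[0] == "none":
            offsets = np.zeros((n_cc, 3))
        else:
            raise ValueError(
                f"unknown focus offset law {config.focus_channel_offset[0]!r}"
            )
        focus_centers = cc_centers + offsets

        # --- locus spots ----------------------------------------------------
        spot_centers, spot_fracs = place_locus_spots(
            config.locus_radial_law,
            config.locus_spots_per_nucleus,
            (center, semiaxes),
            rng,
        )

        # --- render ----------------------------------------------------------
        dapi_mask = _ellipsoid_mask(axes, center, semiaxes)
        cc_mask = np.zeros(shape, dtype=bool)
        focus_mask = np.zeros(shape, dtype=bool)
        spot_mask = np.zeros(shape, dtype=bool)

        voxel_volume = dx * dy * dz

        def _record(channel, pos, radius, analytic_v, union, **extra):
            m = _sphere_mask(axes, pos, radius)
            union |= m
            object_rows.append(
                {
                    "nucleus_id": nuc_id,
                    "channel": channel,
                    "x": pos[0],
                    "y": pos[1],
                    "z": pos[2],
                    "radius_um": radius,
                    "volume_um3": analytic_v,
                    "voxelized_volume_um3": int(m.sum()) * voxel_volume,
                    "overlapping": bool(extra.get("overlapping", False)),
                    "radial_fraction": extra.get("radial_fraction", np.nan),
                }
            )

        for i in range(n_cc):
            _record("centromere", cc_centers[i], cc_radii[i], cc_volumes[i],
                    cc_mask, overlapping=cc_overlap[i])
            _record("h3k9me3", focus_centers[i], cc_radii[i], cc_volumes[i],
                    focus_mask, overlapping=cc_overlap[i])
        spot_v = 4.0 / 3.0 * math.pi * config.locus_spot_radius**3
        for i in range(config.locus_spots_per_nucleus):
            _record("locus", spot_centers[i], config.locus_spot_radius, spot_v,
                    spot_mask, radial_fraction=spot_fracs[i])

        channel_masks = {
            "dapi": dapi_mask,
            "centromere": cc_mask,
            "h3k9me3": focus_mask,
            "locus": spot_mask,
        }
        stacks.append(
            {
                ch: VoxelGrid(
                    _render_channel(channel_masks[ch], config, sigma_vox, rng),
                    config.voxel_size,
                    channel=ch,
                )
                for ch in CHANNELS
            }
        )

    objects = pd.DataFrame(
        object_rows,
        columns=[
            "nucleus_id", "channel", "x", "y", "z", "radius_um", "volume_um3",
            "voxelized_volume_um3", "overlapping", "radial_fraction",
        ],
    )
    nuclei = pd.DataFrame(
        nuclei_rows,
        columns=[
            "nucleus_id", "volume_um3", "semi_a", "semi_b", "semi_c",
            "center_x", "center_y", "center_z",
        ],
    )
    if len(objects):
        cc = objects[objects.channel == "centromere"]
        if len(cc):
            frac = float(cc.overlapping.mean())
            if frac > config.max_overlap_fraction:
                warnings.append(
                    f"overlapping chromocenter fraction {frac:.3f} exceeds "
                    f"cap {config.max_overlap_fraction:.3f}"
                )
    return stacks, GroundTruthTable(nuclei=nuclei, objects=objects, warnings=warnings)
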