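"""Synthetic fluorescence scenes with exact planted ground truth.

Every generator here emulates one acquisition type the analysis pipelines
consume — actin ruffling movies, two-channel optogenetic protrusion movies,
3D PLA spot stacks, and EdU/DAPI nuclei fields — and returns, alongside the
noisy images, the exact ground truth (masks, ratios, spot centers, labels)
computed on the noiseless scene. This makes every downstream stage testable
offline against planted truth.

All generators are pure functions of their spec: the same spec (including
its ``seed``) yields bit-identical output. Ground truth is computed before
noise is applied, so the noise model never perturbs it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import Movie, Volume

__all__ = [
    "SceneSpec",
    "RuffleEvent",
    "RuffleSpec",
    "Fiber",
    "StaticStructureSpec",
    "ProtrusionSceneSpec",
    "SpotSceneSpec",
    "NucleiSceneSpec",
    "GroundTruth",
    "generate_ruffle_movie",
    "generate_protrusion_movie",
    "generate_spot_volume",
    "generate_nuclei_images",
    "plan_ruffle_events",
    "linear_growth_schedule",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Geometry, photometry and noise of a single-cell movie scene.

    Intensities are arbitrary units (AU). ``noise_sd`` is the sd of
    additive Gaussian read noise; ``shot_noise`` replaces each expected
    pixel value by a Poisson draw before read noise is added.
    """

    height: int = 128
    width: int = 128
    n_frames: int = 60
    frame_interval: float = 2.0
    cell_center: tuple[float, float] = (64.0, 64.0)
    cell_axes: tuple[float, float] = (40.0, 48.0)
    cell_intensity: float = 200.0
    background_intensity: float = 10.0
    noise_sd: float = 0.0
    shot_noise: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.height, self.width, self.n_frames) < 1:
            raise ValueError("all scene dimensions must be >= 1")
        if not self.cell_intensity > self.background_intensity >= 0:
            raise ValueError("need cell_intensity > background_intensity >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        cr, cc = self.cell_center
        ar, ac = self.cell_axes
        if not (cr - ar >= 0 and cr + ar < self.height and cc - ac >= 0 and cc + ac < self.width):
            raise ValueError("cell ellipse must lie fully inside the frame")


@dataclass
class RuffleEvent:
    """One transient bright edge region ('ruffle').

    The ruffle is rendered as a half-disk cap attached to the inside of the
    cell edge at ``edge_angle`` and occupying ``area_fraction_of_cell`` of
    the cell area. It exists from ``onset_frame`` for ``duration_frames``
    frames and slides along the edge by ``drift_px_per_frame`` of
    arc length per frame. ``amplitude`` is added on top of the cell
    intensity.
    """

    edge_angle: float
    area_fraction_of_cell: float
    onset_frame: int
    duration_frames: int
    amplitude: float
    drift_px_per_frame: float = 0.0


@dataclass
class RuffleSpec:
    events: list[RuffleEvent] = field(default_factory=list)

    def validate(self, scene: SceneSpec) -> None:
        for ev in self.events:
            if not 0 < ev.area_fraction_of_cell < 0.5:
                raise ValueError("area_fraction_of_cell must be in (0, 0.5)")
            if ev.onset_frame < 0 or ev.onset_frame + ev.duration_frames > scene.n_frames:
                raise ValueError("event must fit within the movie (onset + duration <= n_frames)")
            if ev.amplitude <= 0:
                raise ValueError("amplitude must be > 0")
        # simultaneous events must jointly stay under the half-cell bound
        load = np.zeros(scene.n_frames)
        for ev in self.events:
            load[ev.onset_frame : ev.onset_frame + ev.duration_frames] += ev.area_fraction_of_cell
        if np.any(load >= 0.5):
            t = int(np.argmax(load >= 0.5))
            raise ValueError(
                f"overlapping ruffle events exceed the 50% cell-area bound at frame {t}"
            )


@dataclass
class Fiber:
    endpoint_a: tuple[float, float]
    endpoint_b: tuple[float, float]
    width: float = 2.0
    intensity: float = 100.0


@dataclass
class StaticStructureSpec:
    """Static linear 'stress fiber' structures, identical in every frame."""

    fibers: list[Fiber] = field(default_factory=list)

    def validate(self, scene: SceneSpec) -> None:
        cr, cc = scene.cell_center
        ar, ac = scene.cell_axes
        for f in self.fibers:
            for p in (f.endpoint_a, f.endpoint_b):
                if ((p[0] - cr) / ar) ** 2 + ((p[1] - cc) / ac) ** 2 > 1.0:
                    raise ValueError("fiber endpoints must lie inside the cell ellipse")
            if f.width < 1:
                raise ValueError("fiber width must be >= 1 px")


@dataclass
class ProtrusionSceneSpec:
    """Two-channel optogenetic-style scene with a growing protrusion.

    The cell occupies ``base_mask`` at the first frame and grows into
    ``full_mask`` (a superset) following ``growth_schedule``: an integer
    array, aligned to the image, giving for each added pixel the frame at
    which it appears. The membrane channel carries ``membrane_intensity``
    on the current cell mask; the reporter channel is the membrane channel
    multiplied per-region by ``reporter_ratio_protrusive`` (pixels of
    ``full_mask`` minus ``base_mask``) or ``reporter_ratio_body``.
    """

    base_mask: np.ndarray
    full_mask: np.ndarray
    growth_schedule: Optional[np.ndarray] = None
    n_frames: int = 20
    membrane_intensity: float = 100.0
    reporter_ratio_protrusive: float = 2.0
    reporter_ratio_body: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        base = np.asarray(self.base_mask, dtype=bool)
        full = np.asarray(self.full_mask, dtype=bool)
        if base.shape != full.shape:
            raise ValueError("base_mask and full_mask must have equal shapes")
        if np.any(base & ~full):
            raise ValueError("base_mask must be a subset of full_mask")
        if not (self.reporter_ratio_protrusive > 0 and self.reporter_ratio_body > 0):
            raise ValueError("reporter ratios must be > 0")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames (T0 and T1)")


@dataclass
class SpotSceneSpec:
    """A 3D two-channel scene: ellipsoidal cell plus Gaussian point sources.

    ``spots_inside``/``spots_outside`` are lists of
    ``(center_zyx, sigma, amplitude)`` with centers in voxel coordinates.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cell_center: tuple[float, float, float] = (32.0, 32.0, 32.0)
    cell_axes: tuple[float, float, float] = (22.0, 24.0, 24.0)
    cell_intensity: float = 200.0
    background_intensity: float = 10.0
    spots_inside: list[tuple[tuple[float, float, float], float, float]] = field(default_factory=list)
    spots_outside: list[tuple[tuple[float, float, float], float, float]] = field(default_factory=list)
    min_separation: float = 12.0
    noise_sd: float = 0.0
    seed: int = 0

    def _inside(self, c: Sequence[float]) -> bool:
        return (
            sum(((c[i] - self.cell_center[i]) / self.cell_axes[i]) ** 2 for i in range(3)) <= 1.0
        )

    def validate(self) -> None:
        for c, s, a in self.spots_inside:
            if not self._inside(c):
                raise ValueError(f"spot at {c} declared inside but lies outside the ellipsoid")
        for c, s, a in self.spots_outside:
            if self._inside(c):
                raise ValueError(f"spot at {c} declared outside but lies inside the ellipsoid")
        centers = [c for c, _, _ in self.spots_inside + self.spots_outside]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                d = math.dist(centers[i], centers[j])
                if d < self.min_separation:
                    raise ValueError(
                        f"spots {i} and {j} are {d:.1f} voxels apart, closer than "
                        f"min_separation={self.min_separation}"
                    )


@dataclass
class NucleiSceneSpec:
    """A 2D field of non-overlapping round nuclei for the EdU/DAPI readout.

    A fraction ``positive_fraction`` of the nuclei are EdU-positive; the
    positive subset is the first ``floor(n * fraction + 0.5)`` nuclei in
    seeded shuffle order, so the positive count is deterministic and exact.
    """

    height: int = 256
    width: int = 256
    n_nuclei: int = 20
    positive_fraction: float = 0.4
    radius_mean: float = 9.0
    radius_sd: float = 0.0
    dapi_intensity: float = 150.0
    edu_intensity: float = 150.0
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.n_nuclei < 1:
            raise ValueError("need at least one nucleus")
        if self.radius_mean <= 0 or self.radius_sd < 0:
            raise ValueError("invalid radius parameters")


@dataclass
class GroundTruth:
    """Planted truth for a generated scene; populated fields depend on the
    generator. All masks match the emitted image dimensions and are computed
    on the noiseless scene."""

    ruffle_masks: Optional[np.ndarray] = None
    cell_masks: Optional[np.ndarray] = None
    mask_t0: Optional[np.ndarray] = None
    mask_t1: Optional[np.ndarray] = None
    protrusive_mask: Optional[np.ndarray] = None
    non_protrusive_mask: Optional[np.ndarray] = None
    reporter_ratio_protrusive: Optional[float] = None
    reporter_ratio_body: Optional[float] = None
    spots_inside: Optional[np.ndarray] = None
    spots_outside: Optional[np.ndarray] = None
    cell_mask_3d: Optional[np.ndarray] = None
    nucleus_centers: Optional[np.ndarray] = None
    nucleus_radii: Optional[np.ndarray] = None
    nucleus_positive: Optional[np.ndarray] = None
    positive_pixel_fraction: Optional[float] = None


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _ellipse_mask(height: int, width: int, center, axes) -> np.ndarray:
    rr, cc = np.ogrid[:height, :width]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _half_disk_cap(
    scene: SceneSpec, cell: np.ndarray, angle: float, area_fraction: float
) -> np.ndarray:
    """Render a half-disk ruffle cap attached to the inside of the cell edge.

    The cap is the inner half (relative to the local edge tangent) of a disk
    centered on the ellipse boundary point at ``angle``, intersected with the
    cell. The disk radius is adjusted iteratively so the rasterized cap area
    matches ``area_fraction`` of the cell area despite edge curvature.
    """
    cr, cc = scene.cell_center
    ar, ac = scene.cell_axes
    target = area_fraction * cell.sum()
    # boundary point and inward normal of the ellipse at parametric angle
    pr = cr + ar * math.sin(angle)
    pc = cc + ac * math.cos(angle)
    # gradient of the implicit ellipse eq gives the outward normal
    nr = 2 * (pr - cr) / ar**2
    nc = 2 * (pc - cc) / ac**2
    norm = math.hypot(nr, nc)
    nr, nc = nr / norm, nc / norm  # outward unit normal

    rr, cc_grid = np.ogrid[: scene.height, : scene.width]
    r0 = math.sqrt(2.0 * target / math.pi)  # exact for a flat edge
    r = r0
    mask = np.zeros_like(cell)
    for _ in range(8):
        disk = (rr - pr) ** 2 + (cc_grid - pc) ** 2 <= r**2
        inner_half = (rr - pr) * nr + (cc_grid - pc) * nc <= 0.0
        mask = disk & inner_half & cell
        area = mask.sum()
        if area == 0:
            r *= 1.5
            continue
        if abs(area - target) / target < 0.02:
            break
        r *= math.sqrt(target / area)
    return mask


def _add_fibers(frame: np.ndarray, statics: StaticStructureSpec) -> None:
    h, w = frame.shape
    rr, cc = np.mgrid[:h, :w]
    for f in statics.fibers:
        a = np.array(f.endpoint_a, dtype=float)
        b = np.array(f.endpoint_b, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            d2 = (rr - a[0]) ** 2 + (cc - a[1]) ** 2
        else:
            t = np.clip(((rr - a[0]) * ab[0] + (cc - a[1]) * ab[1]) / denom, 0.0, 1.0)
            d2 = (rr - (a[0] + t * ab[0])) ** 2 + (cc - (a[1] + t * ab[1])) ** 2
        frame[d2 <= (f.width / 2.0) ** 2] += f.intensity


def _apply_noise(scene_stack: np.ndarray, noise_sd: float, shot: bool, rng) -> np.ndarray:
    out = scene_stack
    if shot:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, None) if (shot or noise_sd > 0) else out.copy()


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def generate_ruffle_movie(
    scene: SceneSpec,
    ruffles: RuffleSpec | None = None,
    statics: StaticStructureSpec | None = None,
) -> tuple[Movie, GroundTruth]:
    """Generate an actin-like movie: static cell + fibers + transient ruffles.

    Returns the noisy movie and a :class:`GroundTruth` with per-frame ruffle
    and cell masks. Ruffle caps slide along the cell edge by their drift
    (converted to arc length) each frame, so any single pixel is occupied
    only transiently — the temporal signature the ruffling-rate method
    exploits.
    """
    ruffles = ruffles or RuffleSpec()
    statics = statics or StaticStructureSpec()
    scene.validate()
    ruffles.validate(scene)
    statics.validate(scene)

    cell = _ellipse_mask(scene.height, scene.width, scene.cell_center, scene.cell_axes)
    base = np.full((scene.height, scene.width), scene.background_intensity)
    base[cell] = scene.cell_intensity
    _add_fibers(base, statics)

    ar, ac = scene.cell_axes
    mean_edge_radius = (ar + ac) / 2.0

    T = scene.n_frames
    clean = np.repeat(base[None], T, axis=0)
    ruffle_masks = np.zeros((T, scene.height, scene.width), dtype=bool)
    for ev in ruffles.events:
        for k in range(ev.duration_frames):
            t = ev.onset_frame + k
            angle = ev.edge_angle + k * ev.drift_px_per_frame / mean_edge_radius
            cap = _half_disk_cap(scene, cell, angle, ev.area_fraction_of_cell)
            ruffle_masks[t] |= cap
            clean[t][cap] += ev.amplitude

    rng = np.random.default_rng(scene.seed)
    data = _apply_noise(clean, scene.noise_sd, scene.shot_noise, rng)

    gt = GroundTruth(ruffle_masks=ruffle_masks, cell_masks=np.repeat(cell[None], T, axis=0))
    return Movie(data, frame_interval=scene.frame_interval), gt


def plan_ruffle_events(
    target_fraction: float,
    n_frames: int,
    rng: np.random.Generator,
    duration_frames: int = 8,
    amplitude: float = 200.0,
    drift_px_per_frame: float = 2.0,
) -> RuffleSpec:
    """Tile ruffle events back-to-back so every frame carries one cap of
    ``target_fraction`` of the cell area, i.e. the time-averaged planted
    ruffle area fraction equals ``target_fraction``.

    Successive events attach at golden-angle increments around the edge
    (random starting phase), so the caps sweep the whole perimeter and no
    pixel stays bright for more than a small part of any median window —
    the transient, fast-moving behavior that distinguishes ruffles from
    static structures. Angles drawn independently at random can, by
    chance, revisit the same edge region for most of a window, which would
    plant a quasi-static structure instead of a ruffle.
    """
    golden = 2.399963  # ~137.5 degrees
    phase = float(rng.uniform(0, 2 * math.pi))
    events = []
    t = 0
    k = 0
    while t < n_frames:
        d = min(duration_frames, n_frames - t)
        events.append(
            RuffleEvent(
                edge_angle=phase + k * golden,
                area_fraction_of_cell=target_fraction,
                onset_frame=t,
                duration_frames=d,
                amplitude=amplitude,
                drift_px_per_frame=drift_px_per_frame,
            )
        )
        t += d
        k += 1
    return RuffleSpec(events=events)


def linear_growth_schedule(
    base_mask: np.ndarray, full_mask: np.ndarray, n_frames: int
) -> np.ndarray:
    """Frame of appearance for each added pixel: pixels closer to the base
    cell appear earlier, emulating a steadily advancing protrusion front."""
    from scipy import ndimage

    base = np.asarray(base_mask, dtype=bool)
    full = np.asarray(full_mask, dtype=bool)
    added = full & ~base
    sched = np.zeros(base.shape, dtype=int)
    if not added.any():
        return sched
    dist = ndimage.distance_transform_edt(~base)
    d = dist[added]
    lo, hi = d.min(), d.max()
    if hi == lo:
        sched[added] = 1
    else:
        # appear between frame 1 and n_frames - 1
        sched[added] = 1 + np.round((d - lo) / (hi - lo) * (n_frames - 2)).astype(int)
    return sched


def generate_protrusion_movie(
    spec: ProtrusionSceneSpec,
) -> tuple[Movie, Movie, GroundTruth]:
    """Generate reporter + membrane channels of a growing-protrusion scene."""
    spec.validate()
    base = np.asarray(spec.base_mask, dtype=bool)
    full = np.asarray(spec.full_mask, dtype=bool)
    T = spec.n_frames
    sched = spec.growth_schedule
    if sched is None:
        sched = linear_growth_schedule(base, full, T)
    sched = np.asarray(sched, dtype=int)

    added = full & ~base
    protrusive = added
    non_protrusive = base  # present at both T0 and T1

    ratio_map = np.zeros(base.shape)
    ratio_map[non_protrusive] = spec.reporter_ratio_body
    ratio_map[protrusive] = spec.reporter_ratio_protrusive

    membrane = np.zeros((T,) + base.shape)
    reporter = np.zeros_like(membrane)
    for t in range(T):
        current = base | (added & (sched <= t))
        membrane[t][current] = spec.membrane_intensity
        reporter[t] = membrane[t] * ratio_map

    rng = np.random.default_rng(spec.seed)
    reporter_noisy = _apply_noise(reporter, spec.noise_sd, False, rng)
    membrane_noisy = _apply_noise(membrane, spec.noise_sd, False, rng)

    gt = GroundTruth(
        mask_t0=base.copy(),
        mask_t1=full.copy(),
        protrusive_mask=protrusive,
        non_protrusive_mask=non_protrusive.copy(),
        reporter_ratio_protrusive=spec.reporter_ratio_protrusive,
        reporter_ratio_body=spec.reporter_ratio_body,
    )
    return Movie(reporter_noisy), Movie(membrane_noisy), gt


def _render_gaussian(vol: np.ndarray, center, sigma: float, amplitude: float) -> None:
    """Add an isotropic 3D Gaussian, evaluated on a local +/-5 sigma window."""
    zc, yc, xc = center
    half = int(math.ceil(5 * sigma))
    sl = []
    for c, n in zip(center, vol.shape):
        lo = max(int(math.floor(c)) - half, 0)
        hi = min(int(math.ceil(c)) + half + 1, n)
        sl.append((lo, hi))
    (z0, z1), (y0, y1), (x0, x1) = sl
    zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
    d2 = (zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2
    vol[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-d2 / (2 * sigma**2))


def generate_spot_volume(spec: SpotSceneSpec) -> tuple[Volume, Volume, GroundTruth]:
    """Generate an actin (ellipsoid cell) channel and a spot channel.

    The spot channel is ``background + sum of isotropic Gaussians`` at the
    planted centers; the ground truth partitions centers into those inside
    and outside the cell ellipsoid.
    """
    spec.validate()
    nz, ny, nx = spec.shape
    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = spec.cell_center
    az, ay, ax = spec.cell_axes
    ellipsoid = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    actin = np.full(spec.shape, spec.background_intensity)
    actin[ellipsoid] = spec.cell_intensity

    spots = np.full(spec.shape, spec.background_intensity)
    for c, s, a in spec.spots_inside + spec.spots_outside:
        _render_gaussian(spots, c, s, a)

    rng = np.random.default_rng(spec.seed)
    actin_noisy = _apply_noise(actin, spec.noise_sd, False, rng)
    spots_noisy = _apply_noise(spots, spec.noise_sd, False, rng)

    gt = GroundTruth(
        spots_inside=np.array([c for c, _, _ in spec.spots_inside], dtype=float).reshape(-1, 3),
        spots_outside=np.array([c for c, _, _ in spec.spots_outside], dtype=float).reshape(-1, 3),
        cell_mask_3d=ellipsoid,
    )
    return (
        Volume(actin_noisy, spec.voxel_spacing),
        Volume(spots_noisy, spec.voxel_spacing),
        gt,
    )


def random_spot_scene(
    seed: int,
    n_inside: int = 5,
    n_outside: int = 2,
    sigma_range: tuple[float, float] = (3.0, 5.0),
    amplitude: float = 50.0,
    noise_sd: float = 5.0,
    shape: tuple[int, int, int] = (64, 64, 64),
) -> SpotSceneSpec:
    """A seeded random PLA-like scene: well-separated spots of sigma in
    ``sigma_range`` and amplitude ``amplitude`` (10x the default noise sd),
    ``n_inside`` inside the cell ellipsoid and ``n_outside`` outside it."""
    rng = np.random.default_rng(seed)
    spec = SpotSceneSpec(shape=shape, noise_sd=noise_sd, seed=seed, min_separation=13.0)
    cz, cy, cx = spec.cell_center
    az, ay, ax = spec.cell_axes
    margin = 8.0
    centers: list[tuple[float, float, float]] = []

    def far_enough(c) -> bool:
        return all(math.dist(c, o) >= spec.min_separation for o in centers)

    inside: list[tuple[tuple[float, float, float], float, float]] = []
    attempts = 0
    while len(inside) < n_inside:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place inside spots; relax separation")
        c = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
            rng.uniform(margin, shape[2] - margin),
        )
        # keep inside the ellipsoid with some slack from its surface
        if ((c[0] - cz) / az) ** 2 + ((c[1] - cy) / ay) ** 2 + ((c[2] - cx) / ax) ** 2 > 0.7:
            continue
        if far_enough(c):
            centers.append(c)
            inside.append((c, float(rng.uniform(*sigma_range)), amplitude))
    outside: list[tuple[tuple[float, float, float], float, float]] = []
    attempts = 0
    while len(outside) < n_outside:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place outside spots; relax separation")
        c = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
            rng.uniform(margin, shape[2] - margin),
        )
        # clearly outside the ellipsoid
        if ((c[0] - cz) / az) ** 2 + ((c[1] - cy) / ay) ** 2 + ((c[2] - cx) / ax) ** 2 < 1.4:
            continue
        if far_enough(c):
            centers.append(c)
            outside.append((c, float(rng.uniform(*sigma_range)), amplitude))
    spec.spots_inside = inside
    spec.spots_outside = outside
    return spec


def generate_nuclei_images(spec: NucleiSceneSpec) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate paired EdU and DAPI images of non-overlapping round nuclei.

    DAPI shows every nucleus; EdU shows only the positive subset. Returns
    ``(edu, dapi, ground_truth)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    max_attempts = 20_000
    while len(centers) < spec.n_nuclei:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei in a "
                f"{spec.height}x{spec.width} field after {max_attempts} attempts; "
                "enlarge the field or reduce n_nuclei/radius"
            )
        attempts += 1
        r = max(2.0, rng.normal(spec.radius_mean, spec.radius_sd)) if spec.radius_sd > 0 else spec.radius_mean
        cy = rng.uniform(r + 1, spec.height - r - 1)
        cx = rng.uniform(r + 1, spec.width - r - 1)
        if all(math.hypot(cy - oy, cx - ox) >= r + orad + 2 for (oy, ox), orad in zip(centers, radii)):
            centers.append((cy, cx))
            radii.append(r)

    n_pos = int(math.floor(spec.n_nuclei * spec.positive_fraction + 0.5))
    order = rng.permutation(spec.n_nuclei)
    positive = np.zeros(spec.n_nuclei, dtype=bool)
    positive[order[:n_pos]] = True

    rr, cc = np.ogrid[: spec.height, : spec.width]
    dapi = np.full((spec.height, spec.width), spec.background)
    edu = np.full((spec.height, spec.width), spec.background)
    dapi_px = 0
    edu_px = 0
    for (cy, cx), r, pos in zip(centers, radii, positive):
        disk = (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
        dapi[disk] = spec.dapi_intensity
        dapi_px += int(disk.sum())
        if pos:
            edu[disk] = spec.edu_intensity
            edu_px += int(disk.sum())

    edu_noisy = _apply_noise(edu[None], spec.noise_sd, False, rng)[0]
    dapi_noisy = _apply_noise(dapi[None], spec.noise_sd, False, rng)[0]

    gt = GroundTruth(
        nucleus_centers=np.array(centers),
        nucleus_radii=np.array(radii),
        nucleus_positive=positive,
        positive_pixel_fraction=(edu_px / dapi_px if dapi_px else 0.0),
    )
    return edu_noisy, dapi_noisy, gt
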