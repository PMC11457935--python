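"""Synthetic pseudo-embryo generator: paired DIC-like and fluorescence-like
volumes, imperfect training masks, and a ground-truth lineage.

The simulator emulates the study system end-to-end so the whole pipeline is
trainable and testable without external data:

* a binary lineage tree with Sulston-style names (daughters append ``a``/``p``
  to the parent), per-generation mean cycle lengths, and lognormal
  cycle-duration noise;
* nucleus positions inside an ellipsoidal embryo, continuous across frames
  (frame-to-frame movement well below a nuclear radius, except at division)
  and kept apart by iterative pairwise repulsion;
* a DIC-like relief rendering: the directional derivative of a smoothed
  refractive-index phantom along a shear direction, so each nucleus appears
  as a paired bright/dark shadow rather than a bright blob; during mitosis
  nuclei render as an elongating dumbbell (the hard case for detection);
* a fluorescence-like rendering of nuclei as anisotropic Gaussian blobs with
  Poisson counting noise;
* imperfect binary masks emulating the output of a pretrained 2D
  fluorescence segmentation model: per-slice nucleus cross-sections subject
  to random omission, boundary jitter, and occasional merging of adjacent
  nuclei.

All operations are pure functions of (inputs, config.rng_seed).
"""

from __future__ import annotations

import hashlib
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .lineage_metrics import LineageTree
from .trackgraph import Detection, TrackGraph
from .volumes import ImageVolume, MaskVolume

__all__ = [
    "InvalidConfigError",
    "MaskCorruption",
    "SimulationConfig",
    "NucleusState",
    "simulate_lineage",
    "simulate_positions",
    "place_nuclei",
    "render_dic",
    "render_fluorescence",
    "make_masks",
    "true_masks",
    "ground_truth_track_graph",
]


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MaskCorruption:
    """Error modes of the emulated 2D segmentation model."""

    miss_rate: float = 0.05
    boundary_jitter_voxels: float = 1.0
    split_merge_rate: float = 0.02


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry, timing, and rendering parameters of the pseudo-embryo.

    Spatial units are voxels (z, y, x); ``z_spacing_um``/``xy_spacing_um``
    give the physical anisotropy (0.75 um axial steps by default, matching
    one-minute frame intervals of typical lineaging acquisitions).
    Per-generation vectors (cycle means, nucleus radii) are clamped to their
    last entry for later generations.
    """

    rng_seed: int = 0
    embryo_half_axes: tuple[float, float, float] = (8.0, 18.0, 26.0)  # (z,y,x)
    n_generations: int = 3
    mean_cycle_minutes: tuple[float, ...] = (16.0, 18.0, 22.0, 26.0, 32.0)
    cycle_cv: float = 0.05
    frame_interval_minutes: float = 1.0
    z_spacing_um: float = 0.75
    xy_spacing_um: float = 0.5
    nucleus_radius_voxels: tuple[float, ...] = (8.0, 6.5, 5.2, 4.2, 3.5)
    dic_shear_direction: tuple[float, float] = (1.0, 1.0)  # (y, x)
    noise_sd: float = 0.02
    illumination_gradient: float = 0.03
    cytoplasm_texture: float = 0.02
    embryo_boundary_contrast: float = 0.08
    dic_relief_gain: float = 2.0
    mitosis_minutes: float = 2.0
    fluor_photons: float = 200.0
    mask_corruption: MaskCorruption = field(default_factory=MaskCorruption)
    volume_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.n_generations < 1:
            raise InvalidConfigError("n_generations must be >= 1")
        if any(a <= 0 for a in self.embryo_half_axes):
            raise InvalidConfigError("embryo half-axes must be positive")
        if any(r <= 0 for r in self.nucleus_radius_voxels):
            raise InvalidConfigError("nucleus radii must be strictly positive")
        if any(m <= 0 for m in self.mean_cycle_minutes):
            raise InvalidConfigError("mean cycle durations must be positive")
        if self.cycle_cv < 0:
            raise InvalidConfigError("cycle_cv must be >= 0")
        if self.frame_interval_minutes <= 0:
            raise InvalidConfigError("frame_interval_minutes must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        mc = self.mask_corruption
        for name in ("miss_rate", "split_merge_rate"):
            v = getattr(mc, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if mc.boundary_jitter_voxels < 0:
            raise InvalidConfigError("boundary_jitter_voxels must be >= 0")

    # -- derived quantities ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume shape (z, y, x); derived from the half-axes if not set.

        In-plane dimensions are rounded up to a multiple of 8 so rendered
        slices divide cleanly through small encoder-decoder networks.
        """
        if self.volume_shape is not None:
            return tuple(int(s) for s in self.volume_shape)
        hz, hy, hx = self.embryo_half_axes
        z = int(np.ceil(2 * hz)) + 4
        y = int(np.ceil(2 * hy)) + 6
        x = int(np.ceil(2 * hx)) + 6
        return (z, -(-y // 8) * 8, -(-x // 8) * 8)

    @property
    def anisotropy(self) -> float:
        return self.z_spacing_um / self.xy_spacing_um

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return (self.z_spacing_um, self.xy_spacing_um, self.xy_spacing_um)

    def cycle_mean(self, generation: int) -> float:
        v = self.mean_cycle_minutes
        return v[min(generation, len(v) - 1)]

    def radius(self, generation: int) -> float:
        v = self.nucleus_radius_voxels
        return v[min(generation, len(v) - 1)]


@dataclass
class NucleusState:
    """One nucleus at one timepoint: where it is and what it looks like."""

    cell_name: str
    timepoint: int
    center: np.ndarray  # (z, y, x) voxels, 0-based
    radius: float
    phase: str = "interphase"  # or "mitosis"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=np.float64)
        if self.center.shape != (3,):
            raise ValueError("center must be 3 floats (z, y, x)")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.phase not in ("interphase", "mitosis"):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def generation(self) -> int:
        return max(len(self.cell_name) - 2, 0)


def _generation(name: str) -> int:
    return max(len(name) - 2, 0)


# ---------------------------------------------------------------------------
# lineage simulation
# ---------------------------------------------------------------------------

def simulate_lineage(config: SimulationConfig) -> LineageTree:
    """Simulate a binary lineage with per-generation lognormal cycle times.

    The founder ("AB") is born at t=0; each cell of generation g <
    ``n_generations`` divides after a lognormal duration with mean
    ``cycle_mean(g)`` and CV ``cycle_cv`` into daughters named with ``a``/``p``
    suffixes. Final-generation cells never divide; they persist to a common
    movie end one final-generation mean cycle after the last division, so
    nuclei do not vanish mid-movie.
    """
    rng = np.random.default_rng([config.rng_seed, 11])
    tree = LineageTree()

    def draw_duration(gen: int) -> float:
        m = config.cycle_mean(gen)
        cv = config.cycle_cv
        if cv == 0:
            return m
        sigma2 = np.log1p(cv * cv)
        mu = np.log(m) - sigma2 / 2.0
        return float(rng.lognormal(mu, np.sqrt(sigma2)))

    queue: deque[tuple[str, float, str | None]] = deque([("AB", 0.0, None)])
    leaves: list[str] = []
    while queue:
        name, birth, parent = queue.popleft()
        gen = _generation(name)
        end = birth + draw_duration(gen)
        tree.add_cell(name, birth, end, parent)
        if gen < config.n_generations:
            queue.append((name + "a", end, name))
            queue.append((name + "p", end, name))
        else:
            leaves.append(name)
    movie_end = max(
        (c.end for c in tree.cells.values() if c.daughters), default=0.0
    ) + config.cycle_mean(config.n_generations)
    for name in leaves:
        tree.cells[name].end = max(movie_end, tree.cells[name].birth)
    return tree


# ---------------------------------------------------------------------------
# nucleus placement
# ---------------------------------------------------------------------------

def _unit_from_name(name: str, ndim: int = 3) -> np.ndarray:
    """Deterministic pseudo-random unit vector derived from a cell name."""
    digest = hashlib.md5(name.encode()).digest()
    seed = int.from_bytes(digest[:8], "little") % (2 ** 31)
    v = np.random.default_rng(seed).normal(size=ndim)
    return v / np.linalg.norm(v)


def _alive(tree: LineageTree, time: float) -> list[str]:
    return sorted(
        n for n, c in tree.cells.items() if c.birth <= time and time < c.end
    )


def simulate_positions(
    config: SimulationConfig,
    tree: LineageTree | None = None,
    t_max: int | None = None,
) -> dict[int, list[NucleusState]]:
    """Deterministic per-frame nucleus positions for the whole movie.

    Cells drift with small random steps (bounded well below a radius per
    frame), daughters start on opposite sides of the parent's last position,
    and capped iterative pairwise repulsion keeps center separations at or
    above 0.8x the sum of radii while a soft ellipsoid clamp keeps nuclei
    inside the embryo.
    """
    if tree is None:
        tree = simulate_lineage(config)
    rng = np.random.default_rng([config.rng_seed, 12])
    shape = np.array(config.shape, dtype=np.float64)
    center = (shape - 1) / 2.0
    az = config.anisotropy
    phys = np.array([az, 1.0, 1.0])
    half = np.array(config.embryo_half_axes, dtype=np.float64)

    last_frame = int(np.floor(tree.end_time() / config.frame_interval_minutes))
    if t_max is not None:
        last_frame = min(last_frame, t_max)

    pos: dict[str, np.ndarray] = {}
    frames: dict[int, list[NucleusState]] = {}
    for t in range(last_frame + 1):
        time = t * config.frame_interval_minutes
        alive = _alive(tree, time)
        radii = {n: config.radius(_generation(n)) for n in alive}
        # drift existing, place newborns
        for name in alive:
            r = radii[name]
            if name in pos:
                step = rng.normal(0.0, 0.12 * r, size=3) / phys
                norm = np.linalg.norm(step * phys)
                cap = 0.25 * r
                if norm > cap:
                    step *= cap / norm
                pos[name] = pos[name] + step
            else:
                cell = tree.cells[name]
                if cell.parent is not None and cell.parent in pos:
                    axis = _unit_from_name(cell.parent) / phys
                    sign = 1.0 if name.endswith("a") else -1.0
                    parent_r = config.radius(_generation(cell.parent))
                    pos[name] = pos[cell.parent] + sign * 0.7 * parent_r * axis
                else:
                    pos[name] = center.copy()
        for gone in set(pos) - set(alive):
            del pos[gone]
        # pairwise repulsion + ellipsoid clamp, capped iterations
        names = list(alive)
        for _ in range(60):
            moved = False
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    a, b = names[i], names[j]
                    delta = (pos[b] - pos[a]) * phys
                    dist = np.linalg.norm(delta)
                    target = 0.8 * (radii[a] + radii[b]) * 1.02
                    if dist < 1e-9:
                        delta = _unit_from_name(a + b)
                        dist = 1e-9
                    if dist < target:
                        push = (target - dist) / 2.0 * delta / max(dist, 1e-9)
                        pos[a] = pos[a] - push / phys
                        pos[b] = pos[b] + push / phys
                        moved = True
            for name in names:
                rel = (pos[name] - center) / np.maximum(half - 0.3 * radii[name], 1.0)
                q = float(np.sum(rel * rel))
                if q > 1.0:
                    pos[name] = center + (pos[name] - center) / np.sqrt(q)
                    moved = True
            if not moved:
                break
        states = []
        for name in names:
            cell = tree.cells[name]
            phase = (
                "mitosis"
                if cell.divided and time >= cell.end - config.mitosis_minutes
                else "interphase"
            )
            states.append(
                NucleusState(name, t, pos[name].copy(), radii[name], phase)
            )
        frames[t] = states
    return frames


def place_nuclei(
    tree: LineageTree, config: SimulationConfig, timepoint: int
) -> list[NucleusState]:
    """Nucleus states at one timepoint (replays the deterministic trajectory)."""
    frames = simulate_positions(config, tree, t_max=timepoint)
    if timepoint not in frames:
        raise ValueError(
            f"timepoint {timepoint} outside the simulated range 0..{max(frames)}"
        )
    return frames[timepoint]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _timepoint_of(nuclei: list[NucleusState], timepoint: int | None) -> int:
    if timepoint is not None:
        return timepoint
    return nuclei[0].timepoint if nuclei else 0


def _add_blob(
    field_: np.ndarray,
    center: np.ndarray,
    sigma_vox: np.ndarray,
    amplitude: float,
):
    """Accumulate an anisotropic Gaussian within a 3.5-sigma bounding box."""
    shape = field_.shape
    lo = np.maximum(np.floor(center - 3.5 * sigma_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center + 3.5 * sigma_vox).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    d2 = (
        ((zz - center[0]) / sigma_vox[0]) ** 2
        + ((yy - center[1]) / sigma_vox[1]) ** 2
        + ((xx - center[2]) / sigma_vox[2]) ** 2
    )
    field_[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(
        -0.5 * d2
    )


def _nuclear_phantom(nuclei: list[NucleusState], config: SimulationConfig) -> np.ndarray:
    """Smooth refractive-index bumps; mitotic nuclei become dumbbells."""
    field_ = np.zeros(config.shape, dtype=np.float64)
    az = config.anisotropy
    for nuc in nuclei:
        if nuc.phase == "mitosis":
            axis = _unit_from_name(nuc.cell_name + "/div") / np.array([az, 1.0, 1.0])
            axis /= max(np.linalg.norm(axis), 1e-9)
            s = nuc.radius / 2.2
            sigma = np.array([s / az, s, s])
            for sign in (-1.0, 1.0):
                _add_blob(
                    field_, nuc.center + sign * 0.55 * nuc.radius * axis, sigma, 1.0
                )
        else:
            s = nuc.radius / 1.8
            _add_blob(field_, nuc.center, np.array([s / az, s, s]), 1.0)
    return field_


def _embryo_interior(config: SimulationConfig) -> np.ndarray:
    shape = config.shape
    center = (np.array(shape) - 1) / 2.0
    half = np.array(config.embryo_half_axes, dtype=np.float64)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    q = (
        ((zz - center[0]) / half[0]) ** 2
        + ((yy - center[1]) / half[1]) ** 2
        + ((xx - center[2]) / half[2]) ** 2
    )
    return (q <= 1.0).astype(np.float64)


def render_dic(
    nuclei: list[NucleusState],
    config: SimulationConfig,
    timepoint: int | None = None,
) -> ImageVolume:
    """Render a DIC-like relief volume from nucleus states.

    Per slice, the image is the directional derivative of a smoothed density
    phantom (nuclear bumps + eggshell step + cytoplasmic texture) along
    ``dic_shear_direction``, on a mid-gray offset with an optional linear
    illumination gradient and Gaussian noise. Each nucleus therefore appears
    as a paired bright/dark shadow, not a bright blob.
    """
    t = _timepoint_of(nuclei, timepoint)
    phantom = _nuclear_phantom(nuclei, config)
    if config.embryo_boundary_contrast > 0:
        interior = _embryo_interior(config)
        phantom += config.embryo_boundary_contrast * gaussian_filter(
            interior, sigma=(1.0, 2.0, 2.0)
        )
    if config.cytoplasm_texture > 0:
        rng_tex = np.random.default_rng([config.rng_seed, 13, t])
        texture = gaussian_filter(
            rng_tex.standard_normal(config.shape), sigma=(0.8, 1.6, 1.6)
        )
        sd = texture.std()
        if sd > 0:
            phantom += config.cytoplasm_texture * _embryo_interior(config) * (
                texture / sd
            )
    dy, dx = config.dic_shear_direction
    norm = float(np.hypot(dy, dx))
    if norm == 0:
        raise InvalidConfigError("dic_shear_direction must be nonzero")
    dy, dx = dy / norm, dx / norm
    gy = np.gradient(phantom, axis=1)
    gx = np.gradient(phantom, axis=2)
    relief = dy * gy + dx * gx
    image = 0.5 + config.dic_relief_gain * relief
    if config.illumination_gradient:
        nx = config.shape[2]
        ramp = (np.arange(nx) / max(nx - 1, 1)) - 0.5
        image = image + config.illumination_gradient * ramp[None, None, :]
    if config.noise_sd > 0:
        rng_noise = np.random.default_rng([config.rng_seed, 14, t])
        image = image + rng_noise.normal(0.0, config.noise_sd, size=image.shape)
    return ImageVolume(image, spacing_um=config.spacing_um, timepoint=t)


def render_fluorescence(
    nuclei: list[NucleusState],
    config: SimulationConfig,
    timepoint: int | None = None,
) -> ImageVolume:
    """Render a fluorescence-like volume: Gaussian blobs + Poisson noise."""
    t = _timepoint_of(nuclei, timepoint)
    az = config.anisotropy
    vol = np.zeros(config.shape, dtype=np.float64)
    for nuc in nuclei:
        s = nuc.radius / 1.8
        _add_blob(vol, nuc.center, np.array([s / az, s, s]), 1.0)
    if config.fluor_photons > 0:
        rng = np.random.default_rng([config.rng_seed, 15, t])
        vol = rng.poisson(vol * config.fluor_photons).astype(np.float64)
        vol /= config.fluor_photons
    return ImageVolume(vol, spacing_um=config.spacing_um, timepoint=t)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def _paint_disk(mask: np.ndarray, z: int, cy: float, cx: float, radius: float):
    if radius <= 0:
        return
    ny, nx = mask.shape[1:]
    y0 = max(int(np.floor(cy - radius)), 0)
    y1 = min(int(np.ceil(cy + radius)) + 1, ny)
    x0 = max(int(np.floor(cx - radius)), 0)
    x1 = min(int(np.ceil(cx + radius)) + 1, nx)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.meshgrid(np.arange(y0, y1), np.arange(x0, x1), indexing="ij")
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius * radius
    mask[z, y0:y1, x0:x1] |= disk


def true_masks(
    nuclei: list[NucleusState],
    config: SimulationConfig,
    timepoint: int | None = None,
) -> MaskVolume:
    """Exact analytic per-slice sphere cross-sections (uncorrupted labels)."""
    t = _timepoint_of(nuclei, timepoint)
    mask = np.zeros(config.shape, dtype=bool)
    az = config.anisotropy
    for nuc in nuclei:
        cz, cy, cx = nuc.center
        for z in range(config.shape[0]):
            rad2 = nuc.radius ** 2 - ((z - cz) * az) ** 2
            if rad2 > 0:
                _paint_disk(mask, z, cy, cx, float(np.sqrt(rad2)))
    return MaskVolume(
        mask.astype(np.uint8), spacing_um=config.spacing_um, timepoint=t
    )


def make_masks(
    nuclei: list[NucleusState],
    config: SimulationConfig,
    timepoint: int | None = None,
) -> MaskVolume:
    """Imperfect per-slice binary labels emulating a pretrained 2D segmenter.

    Starting from analytic sphere cross-sections, whole nuclei are omitted
    with probability ``miss_rate``, slice disks are jittered in center and
    radius by ``boundary_jitter_voxels``, and with probability
    ``split_merge_rate`` a nucleus is inflated so it can fuse with an
    adjacent one. Deterministic given the config seed and timepoint.
    """
    t = _timepoint_of(nuclei, timepoint)
    mc = config.mask_corruption
    rng = np.random.default_rng([config.rng_seed, 16, t])
    mask = np.zeros(config.shape, dtype=bool)
    az = config.anisotropy
    for nuc in nuclei:
        missed = rng.random() < mc.miss_rate
        inflated = rng.random() < mc.split_merge_rate
        cz, cy, cx = nuc.center
        grow = 2.0 if inflated else 0.0
        for z in range(config.shape[0]):
            rad2 = nuc.radius ** 2 - ((z - cz) * az) ** 2
            if rad2 <= 0:
                continue
            jy, jx, jr = rng.normal(0.0, 1.0, size=3)
            jitter = mc.boundary_jitter_voxels
            if missed:
                continue
            radius = float(np.sqrt(rad2)) + grow + 0.5 * jitter * jr
            _paint_disk(mask, z, cy + jitter * jy, cx + jitter * jx, radius)
    return MaskVolume(
        mask.astype(np.uint8), spacing_um=config.spacing_um, timepoint=t
    )


# ---------------------------------------------------------------------------
# ground truth track graph
# ---------------------------------------------------------------------------

def ground_truth_track_graph(
    config: SimulationConfig,
    tree: LineageTree | None = None,
    t_max: int | None = None,
) -> TrackGraph:
    """Export the simulated trajectory as a track graph.

    Detections are ordered by cell name within each frame; edges follow each
    cell across consecutive frames and fan out to both daughters at division.
    """
    if tree is None:
        tree = simulate_lineage(config)
    frames = simulate_positions(config, tree, t_max=t_max)
    graph = TrackGraph()
    index: dict[int, dict[str, int]] = {}
    for t in sorted(frames):
        index[t] = {}
        for i, state in enumerate(frames[t]):
            graph.add_detection(
                Detection(
                    id=i,
                    timepoint=t,
                    center=state.center,
                    diameter=2.0 * state.radius,
                    score=1.0,
                    name=state.cell_name,
                )
            )
            index[t][state.cell_name] = i
    for t in sorted(frames)[:-1]:
        nxt = index.get(t + 1, {})
        for name, i in index[t].items():
            if name in nxt:
                graph.add_edge((t, i), (t + 1, nxt[name]))
            else:
                for suffix in ("a", "p"):
                    d = name + suffix
                    if d in nxt:
                        graph.add_edge((t, i), (t + 1, nxt[d]))
    return graph
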