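"""Synthetic movies, cell fields, and spheroid sections with ground truth.

The generator emulates the statistical structure the analysis assumes:
diffusing vesicles imaged as PSF-blurred point sources, abrupt galectin
recruitment at a known onset frame, step-wise cargo loss with a variable
residual fraction (and optional slow residual decay), compartment-marker
channels with photobleaching, and Poisson shot noise plus Gaussian read
noise on top of a uniform background. Every stochastic choice is driven by
a single seed, so identical parameters reproduce bit-identical output.

Point sources are rendered by stamping a normalized sampled-Gaussian PSF
kernel (in-plane sigma ``psf_sigma_px``, axial sigma ``psf_sigma_z_planes``)
at integer voxel positions. Because the kernel sums to one, the total
image intensity of a noise-free frame equals the uniform background plus
the sum of the planted source integrals, which the tests verify exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ParameterError
from .io import Movie

DEFAULT_CHANNELS = ("galectin", "cargo", "marker")

# placement margins keep PSF stamps and the local-background ring fully
# inside the field of view
XY_MARGIN = 16


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic-movie generator.

    Intensity knobs are in camera counts; the source "amplitude" of a
    vesicle is the integral of its blurred image (the PSF kernel sums to
    one), so the expected peak pixel value is amplitude times the kernel
    maximum, and the expected 6 px mask-mean increase is amplitude times
    :func:`mask_gain_factor`.
    """

    n_frames: int = 100
    frame_interval_s: float = 3.0
    n_z: int = 30
    z_step_um: float = 0.3
    image_size_px: tuple[int, int] = (64, 64)
    pixel_size_um: float = 0.1
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    n_events: int = 3
    event_amplitude: float = 10000.0
    cargo_level: float = 10000.0
    marker_level: float = 60000.0
    release_fraction_true: float | tuple = 0.8
    residual_decay_s: float | None = None
    marker_positive_prob: float = 0.45
    bleach_rate: float = 0.002
    bleach_mode: str = "exponential"
    motion_sigma_px: float = 0.5
    psf_sigma_px: float = 1.3
    psf_sigma_z_planes: float = 1.2
    noise_gaussian_sd: float = 2.0
    noise_poisson: bool = True
    background_level: float = 100.0
    #: uniform cytosolic galectin level added inside the cell region
    cell_galectin_level: float = 0.0
    #: static marker-only vesicles (undamaged endosomes) per movie
    n_decoy_markers: int = 8
    #: earliest / latest-from-end allowed onset frame
    t0_min_frame: int = 12
    t0_margin_end: int = 15
    rng_seed: int = 0

    # --- cell-field / spheroid knobs (used by the respective generators) ---
    n_cells: int = 4
    foci_per_cell: tuple[int, ...] | None = None
    cytosolic_level: float | tuple = 20.0
    vesicles_per_cell: int = 5
    vesicle_level: float = 2000.0
    vesicle_radius_px: int = 2
    spheroid_radius_px: int = 150
    spheroid_profile: tuple = ("uniform", 500.0)

    def validate(self) -> None:
        p = self
        for name in ("n_frames", "n_z", "n_events", "n_decoy_markers", "n_cells",
                     "vesicles_per_cell"):
            v = getattr(p, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ParameterError(f"SimParams.{name} must be a count >= 0, got {v!r}")
        if p.frame_interval_s <= 0:
            raise ParameterError("SimParams.frame_interval_s must be > 0")
        fracs = np.atleast_1d(np.asarray(p.release_fraction_true, dtype=float))
        if ((fracs < 0) | (fracs > 1)).any():
            raise ParameterError("SimParams.release_fraction_true must lie in [0, 1]")
        if not 0 <= p.marker_positive_prob <= 1:
            raise ParameterError("SimParams.marker_positive_prob must lie in [0, 1]")
        if p.bleach_mode not in ("exponential", "linear"):
            raise ParameterError("SimParams.bleach_mode must be 'exponential' or 'linear'")
        if p.background_level < 0 or p.noise_gaussian_sd < 0:
            raise ParameterError("background_level and noise_gaussian_sd must be >= 0")
        h, w = p.image_size_px
        if p.n_events > 0 and (h < 2 * XY_MARGIN + 4 or w < 2 * XY_MARGIN + 4):
            raise ParameterError(
                f"image_size_px {p.image_size_px} too small for planted events "
                f"(needs margin {XY_MARGIN} px on each side)")
        if p.n_events > 0 and p.n_frames < p.t0_min_frame + p.t0_margin_end:
            raise ParameterError("n_frames too small for the requested onset window")

    def channel_index(self, role: str) -> int:
        try:
            return self.channels.index(role)
        except ValueError:
            raise ParameterError(f"channel role {role!r} not in {self.channels}")


@dataclass
class SimEvent:
    """One planted membrane-damage event."""

    true_t0_frame: int
    x: int
    y: int
    z: int
    amplitude: float
    release_fraction_true: float
    cargo_level: float
    marker_label: str            # "positive" | "negative"
    marker_level: float
    #: planted (z, y, x) per frame, shape (n_frames, 3)
    path: np.ndarray

    def to_json(self) -> dict:
        d = dataclasses.asdict(self)
        d["path"] = self.path.tolist()
        return d


@dataclass
class GroundTruth:
    """Machine-readable ground truth emitted next to every simulation."""

    events: list
    bleach_rate: float
    rng_seed: int
    cell_labels: np.ndarray | None = None
    decoy_positions: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def save(self, path) -> None:
        d = {"events": [e.to_json() for e in self.events],
             "bleach_rate": self.bleach_rate, "rng_seed": self.rng_seed,
             "decoy_positions": None if self.decoy_positions is None
             else np.asarray(self.decoy_positions).tolist(),
             "extras": _jsonable(self.extras)}
        Path(path).write_text(json.dumps(d, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# PSF helpers

def _gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Sampled, sum-normalized Gaussian kernel (matches the standard
    sampled-kernel construction used by scipy's Gaussian filters)."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def psf_kernel(params: SimParams) -> np.ndarray:
    """3D separable PSF kernel (z, y, x), normalized to sum one."""
    kz = _gaussian_kernel_1d(params.psf_sigma_z_planes)
    kxy = _gaussian_kernel_1d(params.psf_sigma_px)
    return kz[:, None, None] * kxy[None, :, None] * kxy[None, None, :]


def _stamp(volume: np.ndarray, kernel: np.ndarray, z: int, y: int, x: int,
           amount: float) -> None:
    """Add ``amount * kernel`` centered at (z, y, x), clipping at borders."""
    rz, ry, rx = (s // 2 for s in kernel.shape)
    z0, z1 = z - rz, z + rz + 1
    y0, y1 = y - ry, y + ry + 1
    x0, x1 = x - rx, x + rx + 1
    nz, ny, nx = volume.shape
    kz0, ky0, kx0 = max(0, -z0), max(0, -y0), max(0, -x0)
    kz1 = kernel.shape[0] - max(0, z1 - nz)
    ky1 = kernel.shape[1] - max(0, y1 - ny)
    kx1 = kernel.shape[2] - max(0, x1 - nx)
    volume[max(0, z0):min(nz, z1), max(0, y0):min(ny, y1), max(0, x0):min(nx, x1)] \
        += amount * kernel[kz0:kz1, ky0:ky1, kx0:kx1]


def mask_gain_factor(params: SimParams, mask_diameter_px: int = 6) -> float:
    """Expected single-plane mask-mean increase per unit source amplitude.

    Computed directly from the PSF kernel: the kernel's central z-plane
    averaged over the circular measurement mask.
    """
    kernel = psf_kernel(params)
    plane = kernel[kernel.shape[0] // 2]
    cy, cx = plane.shape[0] // 2, plane.shape[1] // 2
    r = mask_diameter_px / 2.0
    yy, xx = np.mgrid[0:plane.shape[0], 0:plane.shape[1]]
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    n_disk = int(np.ceil(r))
    # pixel count of the full disk on an unbounded grid
    offs = np.mgrid[-n_disk:n_disk + 1, -n_disk:n_disk + 1]
    n_pix = int(((offs[0] ** 2 + offs[1] ** 2) <= r * r).sum())
    return float(plane[disk].sum() / n_pix)


def pixel_noise_sd(params: SimParams) -> float:
    """Per-pixel noise s.d. at the background level (shot + read noise)."""
    var = params.noise_gaussian_sd ** 2
    if params.noise_poisson:
        var += params.background_level
    return float(np.sqrt(var))


def _bleach_factor(params: SimParams, frame: int) -> float:
    if params.bleach_rate <= 0:
        return 1.0
    if params.bleach_mode == "linear":
        return max(0.0, 1.0 - params.bleach_rate * frame)
    return float(np.exp(-params.bleach_rate * frame))


def cell_region_mask(params: SimParams) -> np.ndarray:
    """Central rectangular 'cell' region; its complement is image background."""
    h, w = params.image_size_px
    mask = np.zeros((h, w), dtype=bool)
    m = XY_MARGIN // 2
    mask[m:h - m, m:w - m] = True
    return mask


def _apply_noise(expected: np.ndarray, params: SimParams,
                 rng: np.random.Generator) -> np.ndarray:
    if not params.noise_poisson and params.noise_gaussian_sd == 0:
        return expected
    if params.noise_poisson:
        data = rng.poisson(expected).astype(np.float64)
    else:
        data = expected.copy()
    if params.noise_gaussian_sd > 0:
        noise = rng.standard_normal(data.shape)
        noise *= params.noise_gaussian_sd
        data += noise
    # camera counts are digitized and non-negative
    np.rint(data, out=data)
    np.clip(data, 0.0, None, out=data)
    return data


def _sample_positions(rng: np.random.Generator, n: int, params: SimParams,
                      min_dist: float = 18.0, max_tries: int = 5000,
                      avoid=()):
    """Rejection-sample positions separated by ``min_dist`` pixels from each
    other and from the ``avoid`` set (so a planted-negative vesicle never
    sits inside another object's signal)."""
    h, w = params.image_size_px
    zmargin = min(params.n_z // 2, int(3 * params.psf_sigma_z_planes + 0.5))
    zlo, zhi = zmargin, max(zmargin, params.n_z - 1 - zmargin)
    taken: list = []
    # progressively relax the mutual separation if rejection sampling
    # dead-ends; the distance to the avoid set is never relaxed
    for dist in (min_dist, 0.75 * min_dist, 0.5 * min_dist):
        for _ in range(max_tries):
            if len(taken) == n:
                return taken
            y = int(rng.integers(XY_MARGIN, h - XY_MARGIN))
            x = int(rng.integers(XY_MARGIN, w - XY_MARGIN))
            z = int(rng.integers(zlo, zhi + 1))
            if all((y - ty) ** 2 + (x - tx) ** 2 >= dist ** 2
                   for _, ty, tx in taken) and \
               all((y - ty) ** 2 + (x - tx) ** 2 >= min_dist ** 2
                   for _, ty, tx in avoid):
                taken.append((z, y, x))
        if len(taken) == n:
            return taken
    raise ParameterError(
        f"cannot place {n} events at minimum separation {min_dist} px in a "
        f"{params.image_size_px} field")


def _random_walk(rng: np.random.Generator, start, n_frames: int,
                 params: SimParams) -> np.ndarray:
    """Integer-rounded 2D random walk in (y, x); z is kept constant."""
    z, y, x = start
    h, w = params.image_size_px
    path = np.empty((n_frames, 3), dtype=int)
    fy, fx = float(y), float(x)
    for t in range(n_frames):
        path[t] = (z, int(round(fy)), int(round(fx)))
        if params.motion_sigma_px > 0:
            fy += rng.normal(0.0, params.motion_sigma_px)
            fx += rng.normal(0.0, params.motion_sigma_px)
            fy = min(max(fy, XY_MARGIN), h - 1 - XY_MARGIN)
            fx = min(max(fx, XY_MARGIN), w - 1 - XY_MARGIN)
    return path


def _event_cargo_level(event: SimEvent, frame: int, params: SimParams) -> float:
    if frame < event.true_t0_frame:
        return event.cargo_level
    residual = event.cargo_level * (1.0 - event.release_fraction_true)
    if params.residual_decay_s:
        dt = (frame - event.true_t0_frame) * params.frame_interval_s
        residual *= np.exp(-dt / params.residual_decay_s)
    return residual


def simulate_movie(params: SimParams) -> tuple[Movie, GroundTruth]:
    """Generate a multi-channel time-lapse z-stack with planted damage events.

    The cargo channel of each event drops by its release fraction within one
    frame of the true onset (plus optional slow residual decay), the galectin
    channel steps from baseline to the event amplitude at the onset, and the
    marker channel carries bleached signal on marker-positive vesicles and on
    static decoy endosomes. Returns the movie and the planted ground truth.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_size_px
    nc = len(params.channels)
    kernel = psf_kernel(params)

    events: list[SimEvent] = []
    fracs = np.atleast_1d(np.asarray(params.release_fraction_true, dtype=float))
    if params.n_events:
        positions = _sample_positions(rng, params.n_events, params)
        for i, pos in enumerate(positions):
            t0 = int(rng.integers(params.t0_min_frame,
                                  params.n_frames - params.t0_margin_end + 1))
            frac = float(fracs[i % len(fracs)])
            marker_pos = bool(rng.random() < params.marker_positive_prob)
            events.append(SimEvent(
                true_t0_frame=t0, x=pos[2], y=pos[1], z=pos[0],
                amplitude=float(params.event_amplitude),
                release_fraction_true=frac,
                cargo_level=float(params.cargo_level),
                marker_label="positive" if marker_pos else "negative",
                marker_level=float(params.marker_level) if marker_pos else 0.0,
                path=_random_walk(rng, pos, params.n_frames, params)))

    decoys = None
    if params.n_decoy_markers and "marker" in params.channels:
        # keep undamaged decoy endosomes clear of every event's path so a
        # planted-negative vesicle never measures a neighbor's marker signal
        footprint = {tuple(pos) for ev in events
                     for pos in ev.path[::5].tolist()}
        decoys = np.array(_sample_positions(rng, params.n_decoy_markers,
                                            params, min_dist=14.0,
                                            avoid=sorted(footprint)))

    has_marker = "marker" in params.channels
    has_cargo = "cargo" in params.channels
    c_gal = params.channel_index("galectin")
    cell_mask = cell_region_mask(params)

    expected = np.full((params.n_frames, nc, params.n_z, h, w),
                       params.background_level, dtype=float)
    if params.cell_galectin_level > 0:
        expected[:, c_gal] += params.cell_galectin_level * cell_mask
    for t in range(params.n_frames):
        bleach = _bleach_factor(params, t)
        for ev in events:
            z, y, x = ev.path[t]
            if t >= ev.true_t0_frame:
                _stamp(expected[t, c_gal], kernel, z, y, x, ev.amplitude)
            if has_cargo:
                level = _event_cargo_level(ev, t, params)
                if level > 0:
                    _stamp(expected[t, params.channel_index("cargo")],
                           kernel, z, y, x, level)
            if has_marker and ev.marker_level > 0:
                _stamp(expected[t, params.channel_index("marker")],
                       kernel, z, y, x, ev.marker_level * bleach)
        if has_marker and decoys is not None:
            for z, y, x in decoys:
                _stamp(expected[t, params.channel_index("marker")],
                       kernel, z, y, x, params.marker_level * bleach)

    data = _apply_noise(expected, params, rng)
    movie = Movie(data=data, frame_interval_s=params.frame_interval_s,
                  pixel_size_um=params.pixel_size_um, z_step_um=params.z_step_um,
                  channel_names=params.channels)
    truth = GroundTruth(events=events, bleach_rate=params.bleach_rate,
                        rng_seed=params.rng_seed, decoy_positions=decoys,
                        extras={"cell_mask_margin": XY_MARGIN // 2})
    return movie, truth


def expected_frame_total(params: SimParams, truth: GroundTruth,
                         frame: int) -> float:
    """Closed-form total intensity of a noise-free frame (all channels)."""
    h, w = params.image_size_px
    total = params.background_level * len(params.channels) * params.n_z * h * w
    total += params.cell_galectin_level * cell_region_mask(params).sum() * params.n_z
    bleach = _bleach_factor(params, frame)
    for ev in truth.events:
        if frame >= ev.true_t0_frame:
            total += ev.amplitude
        if "cargo" in params.channels:
            total += _event_cargo_level(ev, frame, params)
        if "marker" in params.channels:
            total += ev.marker_level * bleach
    if truth.decoy_positions is not None:
        total += len(truth.decoy_positions) * params.marker_level * bleach
    return total


# ---------------------------------------------------------------------------
# cell fields

@dataclass
class CellFieldTruth:
    """Planted per-cell quantities for a synthetic cell-field image."""

    cell_labels: np.ndarray
    foci_labels: np.ndarray
    foci_counts: dict
    cytosolic_levels: dict
    vesicle_positions: dict        # cell id -> list of (y, x)
    vesicle_level: float
    vesicle_radius_px: int
    best_z: int
    rng_seed: int


def _cell_grid(params: SimParams) -> np.ndarray:
    """Tile the field into ``n_cells`` rectangular cells with 2 px gaps."""
    h, w = params.image_size_px
    n = params.n_cells
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    labels = np.zeros((h, w), dtype=np.uint16)
    ch, cw = h // nrows, w // ncols
    lab = 0
    for r in range(nrows):
        for c in range(ncols):
            if lab >= n:
                break
            lab += 1
            labels[r * ch + 2:(r + 1) * ch - 2, c * cw + 2:(c + 1) * cw - 2] = lab
    return labels


def simulate_cell_field(params: SimParams) -> tuple[np.ndarray, CellFieldTruth]:
    """Generate a labeled cell field with planted foci counts, vesicular
    cargo, and cytosolic cargo levels.

    Returns a (z, y, x) intensity stack and the ground truth. The stack's
    intensity per cell peaks at ``best_z`` (a triangular z-profile), which
    exercises best-plane selection in the uptake measurement.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    h, w = params.image_size_px
    labels = _cell_grid(params)
    cells = [int(v) for v in np.unique(labels) if v != 0]

    if params.foci_per_cell is not None:
        if len(params.foci_per_cell) != len(cells):
            raise ParameterError("foci_per_cell length must equal n_cells")
        foci_counts = {c: int(k) for c, k in zip(cells, params.foci_per_cell)}
    else:
        foci_counts = {c: int(rng.poisson(5)) for c in cells}

    cyto = np.atleast_1d(np.asarray(params.cytosolic_level, dtype=float))
    cyto_levels = {c: float(cyto[(c - 1) % len(cyto)]) for c in cells}

    foci_labels = np.zeros((h, w), dtype=np.uint16)
    vesicle_positions = {c: [] for c in cells}
    n_z = max(2, min(params.n_z, 5))
    best_z = n_z // 2
    zprofile = 1.0 - np.abs(np.arange(n_z) - best_z) / n_z  # peak at best_z

    base = np.zeros((h, w), dtype=float)
    lab = 0
    rad = params.vesicle_radius_px
    yy, xx = np.mgrid[0:h, 0:w]
    for c in cells:
        inside = np.argwhere(labels == c)
        interior = inside[(inside[:, 0] > rad + 1) & (inside[:, 0] < h - rad - 2)
                          & (inside[:, 1] > rad + 1) & (inside[:, 1] < w - rad - 2)]
        base[labels == c] += cyto_levels[c]
        for _ in range(foci_counts[c]):
            lab += 1
            y, x = interior[rng.integers(len(interior))]
            foci_labels[y, x] = lab
        for _ in range(params.vesicles_per_cell):
            y, x = interior[rng.integers(len(interior))]
            disk = (yy - y) ** 2 + (xx - x) ** 2 <= rad ** 2
            base[disk & (labels == c)] += params.vesicle_level
            vesicle_positions[c].append((int(y), int(x)))

    expected = params.background_level + base[None] * zprofile[:, None, None]
    data = _apply_noise(expected, params, rng)
    truth = CellFieldTruth(cell_labels=labels, foci_labels=foci_labels,
                           foci_counts=foci_counts, cytosolic_levels=cyto_levels,
                           vesicle_positions=vesicle_positions,
                           vesicle_level=params.vesicle_level,
                           vesicle_radius_px=rad, best_z=best_z,
                           rng_seed=params.rng_seed)
    return data, truth


# ---------------------------------------------------------------------------
# spheroid sections

def simulate_spheroid_section(params: SimParams):
    """Generate a circular spheroid section with a known radial profile.

    ``spheroid_profile`` is either ``("uniform", level)`` or
    ``("linear", margin_level, center_level)``; the pixel value at relative
    depth d in [0, 1] (0 = margin, 1 = center) follows that function.
    Returns ``(image, mask, background_mask, truth_profile)`` where
    ``truth_profile`` samples the radial function at the centers of 200
    one-pixel shells of the radius-200 scaled geometry (margin first).
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    R = params.spheroid_radius_px
    pad = 20
    size = 2 * (R + pad) + 1
    if R < 10:
        raise ParameterError("spheroid_radius_px must be >= 10")
    cy = cx = R + pad
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - cy, xx - cx)
    mask = r <= R

    kind = params.spheroid_profile[0]
    if kind == "uniform":
        level = float(params.spheroid_profile[1])
        def f(depth):  # noqa: E306
            return np.full_like(np.asarray(depth, dtype=float), level)
    elif kind == "linear":
        m, c = map(float, params.spheroid_profile[1:3])
        def f(depth):  # noqa: E306
            return m + (c - m) * np.asarray(depth, dtype=float)
    else:
        raise ParameterError(f"unknown spheroid_profile kind {kind!r}")

    depth = np.clip((R - r) / R, 0.0, 1.0)
    expected = np.where(mask, f(depth), params.background_level)
    data = _apply_noise(expected[None], params, rng)[0]

    background_mask = np.zeros_like(mask)
    background_mask[:pad // 2, :pad // 2] = True

    shell_centers = (np.arange(1, 201) - 0.5) / 200.0
    truth_profile = f(shell_centers)
    return data, mask, background_mask, truth_profile
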