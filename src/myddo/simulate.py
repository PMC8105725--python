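"""Synthetic TIRF data with exhaustive ground truth.

This module emulates the statistical structure the rest of the pipeline
assumes, so every downstream stage can be verified against known truth:

* **Live-cell puncta movies** — diffraction-limited spots nucleate at a
  Poisson rate, perform a birth-death walk in copy number (transient small
  oligomers vs. stable growing oligomers once a critical size is reached),
  and are rendered as pixel-integrated 2-D Gaussians on a camera model of
  offset + Poisson shot noise + Gaussian read noise.
* **Calibration stacks** — sparse immobile single emitters with single-step
  photobleaching, for measuring the single-GFP unit intensity.
* **FRAP traces** — prebleach plateau, instantaneous bleach, single
  exponential recovery toward a configurable mobile fraction.
* **Fixed-cell fields** — 20x-style multi-channel images with disk nuclei
  inside larger cytoplasm disks, plus optional crowded clusters, border
  cells and elongated debris for exercising the quality filters.

Brightness model
----------------
A punctum of ``n`` monomers carries the summed brightness of ``n``
independent fluorophores, each drawn once (at recruitment) from
``Normal(gfp_unit_mean, (gfp_unit_cv * gfp_unit_mean)^2)``.  The total is
therefore ``Normal(n*mu, n*sigma^2)`` — i.e. ``n*mu*(1 + eps)`` with
``eps ~ Normal(0, cv/sqrt(n))`` — and is constant in time while ``n`` is
constant; frame-to-frame fluctuation comes only from the camera model.
This matches the Gaussian N-mer model used for size classification.

Randomness: each ``simulate_*`` call consumes a single
``numpy.random.Generator``; the draw order is (per frame) punctum dynamics
in id order, then nucleation, then rendering noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .core import DEFAULT_PIXEL_SIZE_UM, Movie, Track
from .frap import FRAPTrace


@dataclass
class SimulationConfig:
    """Parameters of the live-cell puncta simulation.

    The defaults emulate the acquisition geometry and two-population
    kinetics of the assay being modelled: 150 nm pixels, 1 s frame
    interval, a net-shrinking birth-death walk for nascent oligomers
    (most dissolve within seconds) and slow monotonic growth once a
    punctum reaches ``stable_size_threshold`` monomers.
    """

    image_shape: tuple[int, int] = (128, 128)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = 1.0
    n_frames: int = 300
    psf_sigma_px: float = 1.1
    gfp_unit_mean: float = 500.0      # ADU per GFP, integrated over the PSF
    gfp_unit_cv: float = 0.25
    camera_offset: float = 100.0      # ADU
    read_noise_sd: float = 1.6        # ADU rms per pixel
    shot_noise: bool = True
    nucleation_rate: float = 0.3      # puncta per frame over the field
    initial_size_range: tuple[int, int] = (1, 3)
    p_grow: float = 0.22              # per-frame monomer gain, unstable phase
    p_shrink: float = 0.38            # per-frame monomer loss, unstable phase
    stable_size_threshold: int = 6    # monomers at which a punctum stabilizes
    stable_p_grow: float = 0.05       # per-frame growth once stable
    stable_p_death: float = 0.01      # per-frame whole-punctum loss once stable
    max_size: int | None = None       # monomer cap; None emulates unchecked growth
    diffusion_step_um: float = 0.0    # per-frame Gaussian step SD (stationary default)
    min_separation_px: float = 0.0    # reject nucleation closer than this to a live punctum
    nucleation_margin_px: float = 0.0 # keep nucleation at least this far from the border
    partner_size_threshold: int | None = None  # enable the partner channel when set
    partner_delay_mean_s: float = 15.0
    partner_delay_sd_s: float = 5.0
    partner_n: int = 4                # partner punctum brightness, in unit intensities
    seed: int = 0

    def validate(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.psf_sigma_px >= min(h, w) / 4:
            raise ValueError("psf_sigma_px too large for the image")
        for name in ("p_grow", "p_shrink", "stable_p_grow", "stable_p_death"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_grow + self.p_shrink > 1.0:
            raise ValueError("p_grow + p_shrink must not exceed 1")
        if self.gfp_unit_cv < 0:
            raise ValueError("gfp_unit_cv must be non-negative")
        if self.nucleation_rate < 0:
            raise ValueError("nucleation_rate must be non-negative")


@dataclass
class GroundTruthPunctum:
    """Exhaustive truth for one simulated punctum.

    Arrays are indexed per observed frame ``birth_frame .. death_frame``.
    ``brightness`` is the noiseless integrated intensity (ADU) the punctum
    emits in each frame; ``n`` the monomer copy number.
    """

    id: int
    birth_frame: int
    x_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    y_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    n: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    brightness: np.ndarray = field(default_factory=lambda: np.empty(0))
    is_stable: bool = False
    partner_recruit_frame: int | None = None
    censored: bool = False

    @property
    def death_frame(self) -> int:
        return self.birth_frame + len(self.n) - 1

    @property
    def lifetime_frames(self) -> int:
        return len(self.n)

    @property
    def max_n(self) -> int:
        return int(self.n.max())


class _LivePunctum:
    __slots__ = ("gt", "x", "y", "units", "stable", "recruit_frame_pending")

    def __init__(self, gt: GroundTruthPunctum, x: float, y: float, units: list):
        self.gt = gt
        self.x = x
        self.y = y
        self.units = units
        self.stable = False
        self.recruit_frame_pending = False


def _draw_unit(rng: np.random.Generator, cfg: SimulationConfig) -> float:
    if cfg.gfp_unit_cv == 0:
        return cfg.gfp_unit_mean
    return rng.normal(cfg.gfp_unit_mean, cfg.gfp_unit_cv * cfg.gfp_unit_mean)


def simulate_kinetics(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[GroundTruthPunctum]:
    """Run the nucleation / birth-death / stabilization process without rendering.

    Used directly for large-n kinetic checks and internally by
    :func:`simulate_puncta_movie`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    h, w = config.image_shape
    margin = config.nucleation_margin_px
    lo_x, hi_x = margin * config.pixel_size_um, (w - margin) * config.pixel_size_um
    lo_y, hi_y = margin * config.pixel_size_um, (h - margin) * config.pixel_size_um
    done: list[GroundTruthPunctum] = []
    alive: list[_LivePunctum] = []
    next_id = 0
    records: dict[int, list] = {}

    for t in range(config.n_frames):
        survivors = []
        for p in alive:
            n = len(p.units)
            if not p.stable:
                u = rng.random()
                if u < config.p_grow:
                    p.units.append(_draw_unit(rng, config))
                elif u < config.p_grow + config.p_shrink:
                    p.units.pop()
            else:
                if rng.random() < config.stable_p_death:
                    p.units.clear()
                elif rng.random() < config.stable_p_grow:
                    if config.max_size is None or len(p.units) < config.max_size:
                        p.units.append(_draw_unit(rng, config))
            if config.diffusion_step_um > 0:
                p.x += rng.normal(0.0, config.diffusion_step_um)
                p.y += rng.normal(0.0, config.diffusion_step_um)
            if p.units:
                survivors.append(p)
            else:
                done.append(p.gt)
        alive = survivors

        k = rng.poisson(config.nucleation_rate)
        for _ in range(k):
            pos = None
            for _try in range(100):
                x = rng.uniform(lo_x, hi_x)
                y = rng.uniform(lo_y, hi_y)
                if config.min_separation_px > 0:
                    min_d = config.min_separation_px * config.pixel_size_um
                    if any((q.x - x) ** 2 + (q.y - y) ** 2 < min_d**2 for q in alive):
                        continue
                pos = (x, y)
                break
            if pos is None:
                continue
            lo, hi = config.initial_size_range
            n0 = int(rng.integers(lo, hi + 1))
            units = [_draw_unit(rng, config) for _ in range(n0)]
            gt = GroundTruthPunctum(id=next_id, birth_frame=t)
            records[next_id] = []
            alive.append(_LivePunctum(gt, pos[0], pos[1], units))
            next_id += 1

        for p in alive:
            n = len(p.units)
            if not p.stable and n >= config.stable_size_threshold:
                p.stable = True
                p.gt.is_stable = True
            if (
                config.partner_size_threshold is not None
                and p.gt.partner_recruit_frame is None
                and not p.recruit_frame_pending
                and n >= config.partner_size_threshold
            ):
                delay = max(0.0, rng.normal(config.partner_delay_mean_s, config.partner_delay_sd_s))
                frame = p.gt.birth_frame + int(round(delay / config.frame_interval_s))
                p.gt.partner_recruit_frame = max(frame, t)
                p.recruit_frame_pending = True
            records[p.gt.id].append((p.x, p.y, n, float(sum(p.units))))

    for p in alive:
        p.gt.censored = True
        done.append(p.gt)

    for gt in done:
        rec = records[gt.id]
        gt.x_um = np.array([r[0] for r in rec])
        gt.y_um = np.array([r[1] for r in rec])
        gt.n = np.array([r[2] for r in rec], dtype=int)
        gt.brightness = np.array([r[3] for r in rec])
        if gt.partner_recruit_frame is not None and gt.partner_recruit_frame > gt.death_frame:
            gt.partner_recruit_frame = None
    done.sort(key=lambda g: g.id)
    return done


def add_gaussian_spot(frame: np.ndarray, x_um: float, y_um: float, intensity: float,
                      sigma_px: float, pixel_size_um: float, support_sigmas: float = 5.0) -> None:
    """Add a pixel-integrated isotropic 2-D Gaussian in place.

    The amplitude is normalised so the infinite-plane integral equals
    ``intensity``; each pixel receives the exact integral of the Gaussian
    over its footprint (difference of error functions), truncated at
    ``support_sigmas`` standard deviations.
    """
    h, w = frame.shape
    px = x_um / pixel_size_um  # continuous pixel coordinate; pixel i spans [i, i+1)
    py = y_um / pixel_size_um
    r = support_sigmas * sigma_px
    x0, x1 = max(0, int(math.floor(px - r))), min(w, int(math.ceil(px + r)) + 1)
    y0, y1 = max(0, int(math.floor(py - r))), min(h, int(math.ceil(py + r)) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    s = sigma_px * math.sqrt(2.0)
    ex = 0.5 * np.diff(special.erf((np.arange(x0, x1 + 1) - px) / s))
    ey = 0.5 * np.diff(special.erf((np.arange(y0, y1 + 1) - py) / s))
    frame[y0:y1, x0:x1] += intensity * np.outer(ey, ex)


def _apply_camera(signal: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    out = np.clip(signal, 0.0, None)
    if config.shot_noise:
        out = rng.poisson(out).astype(float)
    out = out + config.camera_offset
    if config.read_noise_sd > 0:
        out = out + rng.normal(0.0, config.read_noise_sd, size=out.shape)
    return out


def _render(ground_truth, config, rng, brightness_of, frame_of_punctum):
    """Shared renderer: accumulate noiseless signal per frame, then camera noise."""
    h, w = config.image_shape
    frames = np.zeros((config.n_frames, h, w), dtype=float)
    for gt in ground_truth:
        for i in range(gt.lifetime_frames):
            t = gt.birth_frame + i
            b = brightness_of(gt, i)
            if b > 0:
                add_gaussian_spot(frames[t], gt.x_um[i], gt.y_um[i], b,
                                  config.psf_sigma_px, config.pixel_size_um)
    for t in range(config.n_frames):
        frames[t] = _apply_camera(frames[t], config, rng)
    return frames


def simulate_puncta_movie(config: SimulationConfig) -> tuple[Movie, list[GroundTruthPunctum]]:
    """Simulate kinetics and render the reference-channel movie.

    Returns the movie and the exhaustive ground truth (one record per
    punctum that ever existed, including censored ones still alive at the
    final frame).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ground_truth = simulate_kinetics(config, rng)
    frames = _render(ground_truth, config, rng, lambda gt, i: gt.brightness[i], None)
    movie = Movie(frames, config.pixel_size_um, config.frame_interval_s, channel="C0")
    return movie, ground_truth


def simulate_two_channel_movie(config: SimulationConfig) -> tuple[Movie, Movie, list[GroundTruthPunctum]]:
    """Simulate the reference channel plus the recruited partner channel.

    Partner puncta appear at ``partner_recruit_frame`` at the (moving)
    position of their reference punctum, with brightness ``partner_n``
    unit intensities, and persist until the reference punctum dies.
    ``config.partner_size_threshold`` must be set.
    """
    if config.partner_size_threshold is None:
        raise ValueError("partner_size_threshold must be set for a two-channel simulation")
    config.validate()
    rng = np.random.default_rng(config.seed)
    ground_truth = simulate_kinetics(config, rng)
    frames_a = _render(ground_truth, config, rng, lambda gt, i: gt.brightness[i], None)

    def partner_brightness(gt: GroundTruthPunctum, i: int) -> float:
        if gt.partner_recruit_frame is None:
            return 0.0
        if gt.birth_frame + i < gt.partner_recruit_frame:
            return 0.0
        return config.partner_n * config.gfp_unit_mean

    frames_b = _render(ground_truth, config, rng, partner_brightness, None)
    movie_a = Movie(frames_a, config.pixel_size_um, config.frame_interval_s, channel="C0")
    movie_b = Movie(frames_b, config.pixel_size_um, config.frame_interval_s, channel="C1")
    return movie_a, movie_b, ground_truth


def simulate_calibration_stack(
    config: SimulationConfig,
    n_emitters: int = 100,
    bleach_rate: float = 0.0,
    return_truth: bool = False,
):
    """Render sparse immobile single emitters (n = 1) for unit-intensity calibration.

    Each emitter's brightness is one draw from the unit-intensity
    distribution; single-step photobleaching occurs with per-frame
    probability ``bleach_rate``.  Refuses densities at which the expected
    nearest-neighbour spacing falls below ``4 * psf_sigma_px``.
    """
    config.validate()
    if not 0.0 <= bleach_rate <= 1.0:
        raise ValueError("bleach_rate must be in [0, 1]")
    h, w = config.image_shape
    density = n_emitters / (h * w)
    mean_nn_px = 0.5 / math.sqrt(density)  # Poisson spatial process expectation
    if mean_nn_px < 4 * config.psf_sigma_px:
        raise ValueError(
            f"emitter density too high: mean NN spacing {mean_nn_px:.1f} px "
            f"< 4*psf_sigma ({4 * config.psf_sigma_px:.1f} px)"
        )
    rng = np.random.default_rng(config.seed)
    margin = max(4.0, 4 * config.psf_sigma_px)
    xs = rng.uniform(margin, w - margin, n_emitters) * config.pixel_size_um
    ys = rng.uniform(margin, h - margin, n_emitters) * config.pixel_size_um
    brightness = np.array([_draw_unit(rng, config) for _ in range(n_emitters)])
    if bleach_rate > 0:
        # geometric survival: emitter visible in frames [0, bleach_frame)
        bleach_frame = rng.geometric(bleach_rate, n_emitters)
    else:
        bleach_frame = np.full(n_emitters, config.n_frames + 1)

    frames = np.zeros((config.n_frames, h, w), dtype=float)
    for t in range(config.n_frames):
        for i in range(n_emitters):
            if t < bleach_frame[i]:
                add_gaussian_spot(frames[t], xs[i], ys[i], brightness[i],
                                  config.psf_sigma_px, config.pixel_size_um)
        frames[t] = _apply_camera(frames[t], config, rng)
    movie = Movie(frames, config.pixel_size_um, config.frame_interval_s, channel="C0")
    if return_truth:
        truth = pd.DataFrame({"x_um": xs, "y_um": ys, "brightness": brightness,
                              "bleach_frame": np.minimum(bleach_frame, config.n_frames)})
        return movie, truth
    return movie


def simulate_frap_trace(
    prebleach_level: float = 1000.0,
    bleach_depth: float = 0.8,
    recovery_fraction: float = 0.57,
    tau_s: float = 30.0,
    n_frames: int = 120,
    frame_interval_s: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_prebleach: int = 10,
) -> FRAPTrace:
    """Simulate a photobleaching recovery trace.

    The trace holds ``n_prebleach`` samples at ``prebleach_level``, drops
    instantaneously to ``prebleach_level * (1 - bleach_depth)`` at the
    bleach frame, then recovers single-exponentially with time constant
    ``tau_s`` toward ``recovery_fraction`` of the bleached amplitude.
    """
    if not 0.0 <= bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in [0, 1]")
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ValueError("recovery_fraction must be in [0, 1]")
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    rng = np.random.default_rng(seed)
    floor = prebleach_level * (1.0 - bleach_depth)
    t_post = np.arange(n_frames) * frame_interval_s
    post = floor + recovery_fraction * (prebleach_level - floor) * (1.0 - np.exp(-t_post / tau_s))
    intensity = np.concatenate([np.full(n_prebleach, prebleach_level), post])
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, intensity.size)
    time_s = np.arange(intensity.size) * frame_interval_s
    return FRAPTrace(time_s=time_s, intensity=intensity, bleach_index=n_prebleach)


# ---------------------------------------------------------------------------
# Fixed-cell fields


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _ellipse_mask(shape, cy, cx, ry, rx):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def simulate_fixedcell_field(
    n_cells: int = 8,
    nuclear_ratio: float = 3.0,
    image_shape: tuple[int, int] = (512, 512),
    pixel_size_um: float = 0.2833,
    nucleus_radius_um: tuple[float, float] = (6.5, 8.5),
    cyto_margin_um: tuple[float, float] = (2.5, 4.0),
    stain_base: float = 100.0,
    noise_sd: float = 0.0,
    n_crowded: int = 0,
    n_edge: int = 0,
    n_elongated: int = 0,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Render a fixed-cell field with known compartment geometry.

    Channels returned: ``dapi`` (nuclei), ``marker`` (whole cell bodies;
    stands in for the GFP or phalloidin channel) and ``stain`` (antibody
    channel with nuclear:cytoplasmic mean ratio ``nuclear_ratio``).  A
    small central intensity bump is added to each nucleus so seeded
    watershed has one distinct maximum per nucleus.

    Optional constructions for filter testing: ``n_crowded`` adds a
    cluster of six nuclei whose centroids all lie within 16 um of each
    other; ``n_edge`` adds cells overlapping the image border;
    ``n_elongated`` adds high-aspect-ratio debris.  Raises if the
    requested cells cannot be placed without violating the packing limit.
    """
    if nuclear_ratio <= 0:
        raise ValueError("nuclear_ratio must be positive")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    dapi = np.zeros(image_shape)
    marker = np.zeros(image_shape)
    stain = np.zeros(image_shape)
    rows = []
    placed = []  # (cy, cx, clearance_px)

    def try_place(clearance_px, lo_y, hi_y, lo_x, hi_x, max_tries=500):
        for _ in range(max_tries):
            cy = rng.uniform(lo_y, hi_y)
            cx = rng.uniform(lo_x, hi_x)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= (clearance_px + pc) ** 2 for py, px, pc in placed):
                return cy, cx
        raise RuntimeError("could not place cell: packing limit exceeded")

    def paint_cell(cy, cx, r_nuc_px, r_cyto_px, nuc_mask=None):
        nuc = _disk_mask(image_shape, cy, cx, r_nuc_px) if nuc_mask is None else nuc_mask
        cell = _disk_mask(image_shape, cy, cx, r_cyto_px)
        cell |= nuc
        dapi[nuc] = 1.0
        # central bump so the watershed seed detector finds one maximum per nucleus
        yy, xx = np.ogrid[:h, :w]
        bump = 0.3 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.5**2)))
        dapi[nuc] += bump[nuc]
        marker[cell] = 1.0
        stain[cell & ~nuc] = stain_base
        stain[nuc] = stain_base * nuclear_ratio

    cell_id = 0
    for _ in range(n_cells):
        r_nuc = rng.uniform(*nucleus_radius_um) / pixel_size_um
        r_cyto = r_nuc + rng.uniform(*cyto_margin_um) / pixel_size_um
        clearance = r_cyto + 18.0 / pixel_size_um / 2  # keep passing cells uncrowded
        cy, cx = try_place(clearance, r_cyto + 2, h - r_cyto - 2, r_cyto + 2, w - r_cyto - 2)
        paint_cell(cy, cx, r_nuc, r_cyto)
        placed.append((cy, cx, clearance))
        rows.append((cell_id, cx * pixel_size_um, cy * pixel_size_um,
                     r_nuc * pixel_size_um, r_cyto * pixel_size_um, "pass", True))
        cell_id += 1

    if n_crowded:
        # six nuclei whose centroids all sit within a 7 um-radius disk, so every
        # pairwise centroid distance is < 16 um: all six fail the crowding rule
        r_nuc = 6.0 / pixel_size_um
        ring = 7.0 / pixel_size_um
        clearance = ring + r_nuc + 4.0 / pixel_size_um + 18.0 / pixel_size_um / 2
        ccy, ccx = try_place(clearance, clearance + 2, h - clearance - 2, clearance + 2, w - clearance - 2)
        for k in range(6):
            ang = 2 * math.pi * k / 6
            cy, cx = ccy + ring * math.sin(ang), ccx + ring * math.cos(ang)
            paint_cell(cy, cx, r_nuc, r_nuc + 3.0 / pixel_size_um)
            rows.append((cell_id, cx * pixel_size_um, cy * pixel_size_um,
                         r_nuc * pixel_size_um, (r_nuc + 3.0 / pixel_size_um) * pixel_size_um,
                         "crowded", False))
            cell_id += 1
        placed.append((ccy, ccx, clearance))

    for _ in range(n_edge):
        r_nuc = rng.uniform(*nucleus_radius_um) / pixel_size_um
        r_cyto = r_nuc + 3.0 / pixel_size_um
        for _try in range(500):
            side = rng.integers(0, 4)
            along = rng.uniform(r_cyto + 20, (w if side < 2 else h) - r_cyto - 20)
            if side == 0:
                cy, cx = r_cyto * 0.3, along
            elif side == 1:
                cy, cx = h - 1 - r_cyto * 0.3, along
            elif side == 2:
                cy, cx = along, r_cyto * 0.3
            else:
                cy, cx = along, w - 1 - r_cyto * 0.3
            if all((cy - py) ** 2 + (cx - px) ** 2 >= (r_cyto + pc) ** 2 for py, px, pc in placed):
                break
        else:
            raise RuntimeError("could not place edge cell: packing limit exceeded")
        paint_cell(cy, cx, r_nuc, r_cyto)
        placed.append((cy, cx, r_cyto + 18.0 / pixel_size_um / 2))
        rows.append((cell_id, cx * pixel_size_um, cy * pixel_size_um,
                     r_nuc * pixel_size_um, r_cyto * pixel_size_um, "edge", False))
        cell_id += 1

    for _ in range(n_elongated):
        ry = 9.0 / pixel_size_um
        rx = 3.0 / pixel_size_um   # aspect ratio 3 > 1.66: fails eccentricity
        clearance = ry + 4.0 / pixel_size_um + 18.0 / pixel_size_um / 2
        cy, cx = try_place(clearance, clearance + 2, h - clearance - 2, clearance + 2, w - clearance - 2)
        nuc = _ellipse_mask(image_shape, cy, cx, ry, rx)
        cell = _ellipse_mask(image_shape, cy, cx, ry + 2.0 / pixel_size_um, rx + 2.0 / pixel_size_um)
        dapi[nuc] = 1.0
        yy, xx = np.ogrid[:h, :w]
        dapi[nuc] += (0.3 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.5**2))))[nuc]
        marker[cell] = 1.0
        stain[cell & ~nuc] = stain_base
        stain[nuc] = stain_base * nuclear_ratio
        placed.append((cy, cx, clearance))
        rows.append((cell_id, cx * pixel_size_um, cy * pixel_size_um,
                     math.sqrt(ry * rx) * pixel_size_um, (ry + 2.0 / pixel_size_um) * pixel_size_um,
                     "elongated", False))
        cell_id += 1

    if noise_sd > 0:
        dapi = dapi + rng.normal(0, noise_sd, image_shape)
        marker = marker + rng.normal(0, noise_sd, image_shape)
        stain = stain + rng.normal(0, noise_sd * stain_base, image_shape)

    truth = pd.DataFrame(rows, columns=["cell_id", "x_um", "y_um", "nucleus_radius_um",
                                        "cyto_radius_um", "kind", "expect_pass"])
    return {"dapi": dapi, "marker": marker, "stain": stain}, truth


# ---------------------------------------------------------------------------
# Benchmark fields with fixed stoichiometry


def render_nmer_field(
    config: SimulationConfig,
    n_monomers: int,
    n_spots: int = 64,
    n_frames: int = 5,
    spacing_px: int = 14,
    margin_px: int = 8,
    rng: np.random.Generator | None = None,
) -> tuple[Movie, pd.DataFrame]:
    """Render a jittered grid of stationary constant-copy-number puncta.

    Every punctum is an N-mer whose brightness is one draw of the summed
    unit-intensity model; positions have sub-pixel jitter.  Used to
    benchmark size recovery at known stoichiometry.  Returns the movie
    and a truth table (x_um, y_um, brightness).
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    per_side = int(math.ceil(math.sqrt(n_spots)))
    size = margin_px * 2 + per_side * spacing_px
    frames = np.zeros((n_frames, size, size))
    rows = []
    k = 0
    for i in range(per_side):
        for j in range(per_side):
            if k >= n_spots:
                break
            x = (margin_px + j * spacing_px + spacing_px / 2 + rng.uniform(-1, 1)) * config.pixel_size_um
            y = (margin_px + i * spacing_px + spacing_px / 2 + rng.uniform(-1, 1)) * config.pixel_size_um
            b = float(sum(_draw_unit(rng, config) for _ in range(n_monomers)))
            rows.append((x, y, b))
            k += 1
    for t in range(n_frames):
        for x, y, b in rows:
            add_gaussian_spot(frames[t], x, y, b, config.psf_sigma_px, config.pixel_size_um)
        frames[t] = _apply_camera(frames[t], config, rng)
    truth = pd.DataFrame(rows, columns=["x_um", "y_um", "brightness"])
    return Movie(frames, config.pixel_size_um, config.frame_interval_s), truth


def render_partner_field(
    config: SimulationConfig,
    n_spots: int = 64,
    n_frames: int = 45,
    n_monomers: int = 6,
    birth_frame_max: int = 5,
    spacing_px: int = 14,
    margin_px: int = 8,
    rng: np.random.Generator | None = None,
) -> tuple[Movie, Movie, pd.DataFrame]:
    """Render a two-channel grid of stable puncta with delayed partners.

    Reference puncta (N-mers) appear at a random frame in
    ``[0, birth_frame_max)`` and persist; the partner punctum appears at
    the same position after a delay drawn from
    ``Normal(partner_delay_mean_s, partner_delay_sd_s)`` truncated at 0.
    Returns both movies and the truth table (birth and recruit frames).
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    per_side = int(math.ceil(math.sqrt(n_spots)))
    size = margin_px * 2 + per_side * spacing_px
    fa = np.zeros((n_frames, size, size))
    fb = np.zeros((n_frames, size, size))
    rows = []
    k = 0
    for i in range(per_side):
        for j in range(per_side):
            if k >= n_spots:
                break
            x = (margin_px + j * spacing_px + spacing_px / 2 + rng.uniform(-1, 1)) * config.pixel_size_um
            y = (margin_px + i * spacing_px + spacing_px / 2 + rng.uniform(-1, 1)) * config.pixel_size_um
            birth = int(rng.integers(0, birth_frame_max))
            delay_s = max(0.0, rng.normal(config.partner_delay_mean_s, config.partner_delay_sd_s))
            recruit = birth + int(round(delay_s / config.frame_interval_s))
            ba = float(sum(_draw_unit(rng, config) for _ in range(n_monomers)))
            bb = config.partner_n * config.gfp_unit_mean
            for t in range(birth, n_frames):
                add_gaussian_spot(fa[t], x, y, ba, config.psf_sigma_px, config.pixel_size_um)
            for t in range(recruit, n_frames):
                add_gaussian_spot(fb[t], x, y, bb, config.psf_sigma_px, config.pixel_size_um)
            rows.append((x, y, birth, recruit))
            k += 1
    for t in range(n_frames):
        fa[t] = _apply_camera(fa[t], config, rng)
        fb[t] = _apply_camera(fb[t], config, rng)
    truth = pd.DataFrame(rows, columns=["x_um", "y_um", "birth_frame", "recruit_frame"])
    movie_a = Movie(fa, config.pixel_size_um, config.frame_interval_s, "C0")
    movie_b = Movie(fb, config.pixel_size_um, config.frame_interval_s, "C1")
    return movie_a, movie_b, truth


# ---------------------------------------------------------------------------
# Ground-truth helpers


def tracks_from_ground_truth(
    ground_truth: list[GroundTruthPunctum],
    config: SimulationConfig,
    measurement_noise_sd: float = 0.0,
    seed: int = 0,
    channel: str = "C0",
) -> list[Track]:
    """Build idealized :class:`~myddo.core.Track` objects from ground truth.

    Intensities are the noiseless punctum brightnesses plus optional
    additive Gaussian measurement noise — i.e. what a perfect detector
    would measure.  Used for large-n analytics checks where rendering and
    re-detecting every punctum would add nothing but runtime.
    """
    rng = np.random.default_rng(seed)
    tracks = []
    for gt in ground_truth:
        intensity = gt.brightness.astype(float)
        if measurement_noise_sd > 0:
            intensity = intensity + rng.normal(0.0, measurement_noise_sd, intensity.size)
        tracks.append(
            Track(
                track_id=gt.id,
                frames=np.arange(gt.birth_frame, gt.death_frame + 1),
                x_um=gt.x_um.copy(),
                y_um=gt.y_um.copy(),
                intensity=intensity,
                channel=channel,
                censored=gt.censored,
            )
        )
    return tracks


def ground_truth_to_dataframe(ground_truth: list[GroundTruthPunctum]) -> pd.DataFrame:
    """Long-format ground-truth table (one row per punctum per frame)."""
    rows = []
    for gt in ground_truth:
        for i in range(gt.lifetime_frames):
            rows.append((gt.id, gt.birth_frame + i, gt.x_um[i], gt.y_um[i],
                         int(gt.n[i]), gt.is_stable, gt.partner_recruit_frame))
    return pd.DataFrame(rows, columns=["punctum_id", "frame", "x_um", "y_um", "n", "stable", "partner_frame"])
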