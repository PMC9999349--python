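"""Ground-truthed synthetic micrographs of membrane-bound actin networks.

The generator emulates quasi-2D filament networks as imaged on a
supported lipid bilayer: straight-to-semiflexible bright filaments at a
controllable surface density, integer bundling multiplicity, spatially
structured pi-periodic orientation statistics (isotropic through nematic
domains), Gaussian line-spread rendering and a Poisson + Gaussian camera
noise model.  Time series add kinematic contraction toward aster centers
with a co-accumulating myosin channel, and scalar fixtures provide FRAP
recovery and stepwise optical-thickness (RIfS) traces.

Every sampling routine returns the generating truth (filament polylines,
multiplicities, crossing coordinates, domain directors, imposed flow) so
that downstream estimators can be validated against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .core import Micrograph, TimeSeries, VelocityField
from .layerphys import FRAPTrace, RIfSTrace

__all__ = [
    "SynthParams",
    "SynthTruth",
    "ContractionParams",
    "sample_filament_field",
    "render_micrograph",
    "generate_contraction_series",
    "generate_frap_trace",
    "generate_rifs_trace",
]


@dataclass
class SynthParams:
    """Free parameters of the synthetic filament-field generator.

    Attributes
    ----------
    image_size_px
        (rows, cols) of the rendered image.
    pixel_size_um
        Physical pixel edge in micrometers.
    n_filaments
        Number of filament polylines placed in the field of view.
    length_um_mean, length_um_sd
        Mean and SD of the (normal, positive-clipped) filament length.
    orientation_kappa
        Concentration of the pi-periodic orientation noise about the
        local domain director (von Mises on the doubled angle); 0 gives
        orientations uniform on [0, pi).
    n_director_domains
        Number of Voronoi director domains tiling the field.
    bundle_multiplicity_probs
        Probability vector over integer bundle multiplicities 1, 2, 3...
    psf_sigma_um
        Gaussian line-spread SD of the rendered ridge profile.
    line_amplitude
        Peak ridge counts contributed per unit multiplicity.
    background
        Additive constant background (counts).
    poisson_noise
        Apply shot noise to signal + background.
    read_noise_sd
        SD of additive Gaussian read noise (counts), applied last.
    wlc_persistence_um
        Optional worm-like-chain persistence length; ``None`` (default)
        renders filaments as straight segments, appropriate because the
        persistence length of actin far exceeds typical filament length
        at this field of view.
    seed
        RNG seed; identical seeds reproduce bit-identical output.
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.2
    n_filaments: int = 100
    length_um_mean: float = 8.0
    length_um_sd: float = 2.0
    orientation_kappa: float = 0.0
    n_director_domains: int = 1
    bundle_multiplicity_probs: tuple[float, ...] = (1.0,)
    psf_sigma_um: float = 0.25
    line_amplitude: float = 100.0
    background: float = 20.0
    poisson_noise: bool = True
    read_noise_sd: float = 2.0
    wlc_persistence_um: float | None = None
    domain_directors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_size_px
        if rows <= 0 or cols <= 0:
            raise ValueError("image_size_px must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_filaments < 0:
            raise ValueError("n_filaments must be non-negative")
        if self.length_um_mean <= 0 or self.length_um_sd <= 0:
            raise ValueError("length parameters must be positive")
        if self.orientation_kappa < 0:
            raise ValueError("orientation_kappa must be non-negative")
        if self.n_director_domains < 1:
            raise ValueError("n_director_domains must be positive")
        probs = np.asarray(self.bundle_multiplicity_probs, dtype=float)
        if probs.ndim != 1 or probs.size == 0 or np.any(probs < 0):
            raise ValueError("bundle_multiplicity_probs must be a probability vector")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("bundle_multiplicity_probs must sum to 1")
        if self.psf_sigma_um <= 0 or self.line_amplitude <= 0:
            raise ValueError("psf_sigma_um and line_amplitude must be positive")
        if self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read_noise_sd must be non-negative")
        if (
            self.domain_directors is not None
            and len(self.domain_directors) != self.n_director_domains
        ):
            raise ValueError("domain_directors must match n_director_domains")

    @property
    def field_um(self) -> tuple[float, float]:
        """(width, height) spanned by pixel centers, micrometers."""
        rows, cols = self.image_size_px
        return ((cols - 1) * self.pixel_size_um, (rows - 1) * self.pixel_size_um)


@dataclass
class SynthTruth:
    """Generating ground truth of one synthetic field.

    ``filaments`` are polylines in micrometer coordinates; each carries
    the sampled orientation angle (radians, in [0, pi)) and its integer
    bundle multiplicity.  ``node_coords`` are the exact pairwise
    crossing points between distinct filaments.  ``director_field`` is a
    coarse map of the domain director angle sampled on a regular grid.
    """

    filaments: list[np.ndarray]
    orientations: np.ndarray
    multiplicities: np.ndarray
    node_coords: np.ndarray
    director_field: np.ndarray
    domain_directors: np.ndarray

    def analytic_order_parameter(self) -> float:
        """Nematic order of the sampled orientations about their directors.

        Returns mean of cos 2(theta - director) over filaments; 1 for
        perfect alignment, ~0 for isotropic sampling.
        """
        if self.orientations.size == 0:
            return float("nan")
        rel = self.orientations - self.domain_directors
        return float(np.mean(np.cos(2.0 * rel)))


def _clip_segment(p0: np.ndarray, p1: np.ndarray, w: float, h: float) -> np.ndarray | None:
    """Liang-Barsky clip of segment p0->p1 to the box [0,w] x [0,h]."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-d[0], p0[0]),
        (d[0], w - p0[0]),
        (-d[1], p0[1]),
        (d[1], h - p0[1]),
    ):
        if p == 0.0:
            if q < 0:
                return None
            continue
        r = q / p
        if p < 0:
            if r > t1:
                return None
            t0 = max(t0, r)
        else:
            if r < t0:
                return None
            t1 = min(t1, r)
    return np.array([p0 + t0 * d, p0 + t1 * d])


def _segment_intersections(a: np.ndarray, b: np.ndarray) -> list[np.ndarray]:
    """All proper crossing points between polylines a and b (um coords)."""
    pts: list[np.ndarray] = []
    for i in range(len(a) - 1):
        p, r = a[i], a[i + 1] - a[i]
        for j in range(len(b) - 1):
            q, s = b[j], b[j + 1] - b[j]
            denom = r[0] * s[1] - r[1] * s[0]
            if abs(denom) < 1e-12:
                continue
            qp = q - p
            t = (qp[0] * s[1] - qp[1] * s[0]) / denom
            u = (qp[0] * r[1] - qp[1] * r[0]) / denom
            if -1e-12 <= t <= 1 + 1e-12 and -1e-12 <= u <= 1 + 1e-12:
                pts.append(p + t * r)
    return pts


def _sample_orientation(rng: np.random.Generator, director: float, kappa: float) -> float:
    """Pi-periodic orientation about ``director``: von Mises on 2*theta."""
    if kappa == 0.0:
        return float(rng.uniform(0.0, np.pi))
    phi = rng.vonmises(2.0 * director, kappa)
    return float((phi / 2.0) % np.pi)


def sample_filament_field(params: SynthParams) -> tuple[SynthTruth, list[tuple[np.ndarray, int]]]:
    """Sample a ground-truthed filament field.

    Filament centers are uniform over the field of view; each filament
    takes its orientation from the director of the Voronoi domain its
    center falls in, perturbed by pi-periodic von Mises noise of
    concentration ``orientation_kappa``.  Segments are clipped at the
    field borders.  Returns the truth record and a geometry set of
    ``(polyline_um, multiplicity)`` pairs ready for rendering.
    """
    rng = np.random.default_rng(params.seed)
    w, h = params.field_um

    # director domains: Voronoi cells of random seed points
    n_dom = params.n_director_domains
    dom_xy = rng.uniform([0, 0], [w, h], size=(n_dom, 2))
    if params.domain_directors is not None:
        dom_theta = np.asarray(params.domain_directors, dtype=float) % np.pi
    else:
        dom_theta = rng.uniform(0.0, np.pi, size=n_dom)

    probs = np.asarray(params.bundle_multiplicity_probs, dtype=float)
    mult_support = np.arange(1, probs.size + 1)

    filaments: list[np.ndarray] = []
    orientations: list[float] = []
    mults: list[int] = []
    directors: list[float] = []
    while len(filaments) < params.n_filaments:
        c = rng.uniform([0, 0], [w, h])
        dom = int(np.argmin(np.sum((dom_xy - c) ** 2, axis=1)))
        theta = _sample_orientation(rng, dom_theta[dom], params.orientation_kappa)
        length = abs(rng.normal(params.length_um_mean, params.length_um_sd))
        length = max(length, 2.0 * params.pixel_size_um)
        if params.wlc_persistence_um is None:
            u = np.array([np.cos(theta), np.sin(theta)])
            seg = _clip_segment(c - 0.5 * length * u, c + 0.5 * length * u, w, h)
            if seg is None:  # pragma: no cover - center is inside the box
                continue
            poly = seg
        else:
            poly = _wlc_polyline(rng, c, theta, length, params.wlc_persistence_um, w, h)
            if poly is None:
                continue
        filaments.append(poly)
        orientations.append(theta)
        directors.append(float(dom_theta[dom]))
        mults.append(int(rng.choice(mult_support, p=probs)))

    # exact pairwise crossings
    nodes: list[np.ndarray] = []
    for i in range(len(filaments)):
        for j in range(i + 1, len(filaments)):
            nodes.extend(_segment_intersections(filaments[i], filaments[j]))
    node_coords = np.array(nodes) if nodes else np.empty((0, 2))

    # coarse director map (16x16 grid of nearest-domain directors)
    gx = np.linspace(0, w, 16)
    gy = np.linspace(0, h, 16)
    gxx, gyy = np.meshgrid(gx, gy)
    pts = np.stack([gxx.ravel(), gyy.ravel()], axis=1)
    nearest = np.argmin(
        np.sum((pts[:, None, :] - dom_xy[None, :, :]) ** 2, axis=2), axis=1
    )
    director_field = dom_theta[nearest].reshape(16, 16)

    truth = SynthTruth(
        filaments=filaments,
        orientations=np.asarray(orientations),
        multiplicities=np.asarray(mults, dtype=int),
        node_coords=node_coords,
        director_field=director_field,
        domain_directors=np.asarray(directors),
    )
    geometry = [(f, m) for f, m in zip(filaments, truth.multiplicities)]
    return truth, geometry


def _wlc_polyline(
    rng: np.random.Generator,
    center: np.ndarray,
    theta: float,
    length: float,
    lp_um: float,
    w: float,
    h: float,
) -> np.ndarray | None:
    """Discrete worm-like chain: tangent angle diffuses with variance ds/lp."""
    ds = min(0.5, length / 8.0)
    n_steps = max(2, int(round(length / ds)))
    angles = theta + np.cumsum(rng.normal(0.0, math.sqrt(ds / lp_um), size=n_steps))
    steps = ds * np.stack([np.cos(angles), np.sin(angles)], axis=1)
    pts = np.concatenate([[np.zeros(2)], np.cumsum(steps, axis=0)])
    pts = pts - pts.mean(axis=0) + center
    pts[:, 0] = np.clip(pts[:, 0], 0.0, w)
    pts[:, 1] = np.clip(pts[:, 1], 0.0, h)
    return pts


def _render_geometry(
    geometry: Sequence[tuple[np.ndarray, float]],
    params: SynthParams,
) -> np.ndarray:
    """Noise-free ridge rendering: sum of Gaussian-profile lines.

    Each polyline contributes amplitude ``line_amplitude * weight`` times
    a Gaussian of the perpendicular distance to the nearest point of the
    polyline (SD ``psf_sigma_um``).  Additive over filaments.
    """
    rows, cols = params.image_size_px
    px = params.pixel_size_um
    sigma = params.psf_sigma_um
    img = np.zeros((rows, cols), dtype=float)
    reach = 6.0 * sigma  # keep truncation error below 1e-6 of the peak
    for poly, weight in geometry:
        for i in range(len(poly) - 1):
            p0, p1 = poly[i], poly[i + 1]
            lo = np.minimum(p0, p1) - reach
            hi = np.maximum(p0, p1) + reach
            c0 = max(0, int(math.floor(lo[0] / px)))
            c1 = min(cols - 1, int(math.ceil(hi[0] / px)))
            r0 = max(0, int(math.floor(lo[1] / px)))
            r1 = min(rows - 1, int(math.ceil(hi[1] / px)))
            if c1 < c0 or r1 < r0:
                continue
            xs = np.arange(c0, c1 + 1) * px
            ys = np.arange(r0, r1 + 1) * px
            xx, yy = np.meshgrid(xs, ys)
            d = p1 - p0
            len2 = float(d @ d)
            if len2 == 0.0:
                dist2 = (xx - p0[0]) ** 2 + (yy - p0[1]) ** 2
            else:
                t = ((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / len2
                t = np.clip(t, 0.0, 1.0)
                dist2 = (xx - (p0[0] + t * d[0])) ** 2 + (yy - (p0[1] + t * d[1])) ** 2
            img[r0 : r1 + 1, c0 : c1 + 1] += (
                params.line_amplitude * weight * np.exp(-dist2 / (2.0 * sigma**2))
            )
    return img


def _apply_noise(signal: np.ndarray, params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Camera model: Poisson on signal+background, then Gaussian read noise."""
    img = signal + params.background
    if params.poisson_noise:
        img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
    if params.read_noise_sd > 0:
        img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def render_micrograph(
    geometry: Sequence[tuple[np.ndarray, int]],
    params: SynthParams,
    channel: str = "actin",
    rng: np.random.Generator | None = None,
) -> Micrograph:
    """Render a geometry set into a noisy micrograph.

    Each filament becomes a Gaussian-profile ridge of SD ``psf_sigma_um``
    and peak amplitude ``line_amplitude * multiplicity``; ridges add,
    then background is added and noise applied last.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    signal = _render_geometry([(p, float(m)) for p, m in geometry], params)
    pixels = _apply_noise(signal, params, rng)
    return Micrograph(pixels=pixels, pixel_size_um=params.pixel_size_um, channel=channel)


# ---------------------------------------------------------------------------
# contraction time series
# ---------------------------------------------------------------------------


@dataclass
class ContractionParams:
    """Kinematic aster-contraction scenario for a time series.

    ``mode``: ``"global"`` applies the inward flow everywhere within
    ``capture_radius_um`` of the nearest aster; ``"partial"`` applies it
    only in the left image half; ``"none"`` imposes no flow (``v0`` is
    forced to 0 on construction).
    """

    n_frames: int = 12
    frame_interval_s: float = 10.0
    aster_centers: tuple[tuple[float, float], ...] = ()
    v0_um_per_s: float = 0.1
    capture_radius_um: float = 40.0
    myosin_punctum_rate: float = 2.0
    bleach_rate_per_frame: float = 0.01
    mode: str = "global"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("global", "partial", "none"):
            raise ValueError("mode must be global, partial or none")
        if self.mode == "none":
            self.v0_um_per_s = 0.0
        elif not self.aster_centers:
            raise ValueError("aster_centers required unless mode='none'")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not 0.0 <= self.bleach_rate_per_frame < 1.0:
            raise ValueError("bleach_rate_per_frame must be in [0, 1)")
        if self.v0_um_per_s < 0 or self.capture_radius_um <= 0:
            raise ValueError("speeds and radii must be non-negative")


def _imposed_velocity(
    xy: np.ndarray, cparams: ContractionParams, half_width_um: float
) -> np.ndarray:
    """Ground-truth flow (um/s) at positions xy under the aster kinematics."""
    v = np.zeros_like(xy)
    if cparams.v0_um_per_s == 0.0 or not cparams.aster_centers:
        return v
    centers = np.asarray(cparams.aster_centers, dtype=float)
    d2 = np.sum((xy[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    nearest = np.argmin(d2, axis=1)
    delta = centers[nearest] - xy
    dist = np.hypot(delta[:, 0], delta[:, 1])
    move = (dist < cparams.capture_radius_um) & (dist > 1e-9)
    if cparams.mode == "partial":
        move &= xy[:, 0] < half_width_um
    v[move] = cparams.v0_um_per_s * delta[move] / dist[move, None]
    return v


def generate_contraction_series(
    geometry: Sequence[tuple[np.ndarray, int]],
    cparams: ContractionParams,
    optics: SynthParams,
    velocity_grid_px: int = 16,
) -> tuple[TimeSeries, TimeSeries, list[VelocityField]]:
    """Advect a filament field toward aster centers and image both channels.

    Per frame, filament vertices within ``capture_radius_um`` of the
    nearest aster move toward it at ``v0_um_per_s`` (left half only for
    ``mode='partial'``); a myosin channel accumulates Gaussian puncta at
    the aster centers at ``myosin_punctum_rate`` per aster per frame;
    global intensity decays by ``bleach_rate_per_frame``.  Filament
    fluorescence is conserved under compaction: as a filament shortens
    its ridge amplitude scales with original/current length, the way
    labeled actin densifies at an aster without vanishing.

    Returns the actin series, the myosin series, and the imposed
    per-frame ground-truth flow sampled on a regular grid.
    """
    rng = np.random.default_rng(cparams.seed)
    w, h = optics.field_um
    polys = [np.array(p, dtype=float, copy=True) for p, _ in geometry]
    mults = [float(m) for _, m in geometry]
    lengths0 = [_poly_length(p) for p in polys]

    gstep = velocity_grid_px * optics.pixel_size_um
    gx = np.arange(gstep / 2, w, gstep)
    gy = np.arange(gstep / 2, h, gstep)
    gxx, gyy = np.meshgrid(gx, gy)
    grid_xy = np.stack([gxx.ravel(), gyy.ravel()], axis=1)

    actin_frames: list[Micrograph] = []
    myosin_frames: list[Micrograph] = []
    flows: list[VelocityField] = []
    puncta: list[np.ndarray] = []
    dt = cparams.frame_interval_s
    punctum_sigma = 2.0 * optics.psf_sigma_um

    for t in range(cparams.n_frames):
        bleach = (1.0 - cparams.bleach_rate_per_frame) ** t

        # conserve each filament's integrated fluorescence as it compacts:
        # a Gaussian ridge of length L and peak W integrates to
        # W (sqrt(2 pi) sigma L + 2 pi sigma^2) including end caps
        sig = optics.psf_sigma_um
        cap = 2.0 * np.pi * sig**2
        per_len = math.sqrt(2.0 * np.pi) * sig
        weights = []
        for p, m, L0 in zip(polys, mults, lengths0):
            L = _poly_length(p)
            weights.append(m * bleach * (per_len * L0 + cap) / (per_len * L + cap))
        actin_signal = _render_geometry(list(zip(polys, weights)), optics)
        actin_frames.append(
            Micrograph(
                _apply_noise(actin_signal, optics, rng),
                optics.pixel_size_um,
                "actin",
            )
        )

        # myosin: cumulative puncta near the aster centers
        if cparams.aster_centers and cparams.myosin_punctum_rate > 0:
            for cx, cy in cparams.aster_centers:
                n_new = rng.poisson(cparams.myosin_punctum_rate)
                if n_new:
                    puncta.append(
                        np.array([cx, cy])
                        + rng.normal(0.0, 1.0, size=(n_new, 2))
                    )
        myo_signal = np.zeros_like(actin_signal)
        if puncta:
            pts = np.concatenate(puncta)
            myo_geom = [(np.array([pt, pt]), 1.0) for pt in pts]
            myo_optics = replace(optics, psf_sigma_um=punctum_sigma)
            myo_signal = _render_geometry(myo_geom, myo_optics) * bleach
        myosin_frames.append(
            Micrograph(
                _apply_noise(myo_signal, optics, rng),
                optics.pixel_size_um,
                "myosin",
            )
        )

        vgrid = _imposed_velocity(grid_xy, cparams, w / 2.0)
        flows.append(
            VelocityField(
                x_um=gxx,
                y_um=gyy,
                u_um_s=vgrid[:, 0].reshape(gxx.shape),
                v_um_s=vgrid[:, 1].reshape(gxx.shape),
                valid=np.ones(gxx.shape, dtype=bool),
                time_s=t * dt,
            )
        )

        # advance geometry to the next frame
        for p in polys:
            vel = _imposed_velocity(p, cparams, w / 2.0)
            step = vel * dt
            if cparams.aster_centers:
                centers = np.asarray(cparams.aster_centers, dtype=float)
                d2 = np.sum((p[:, None, :] - centers[None, :, :]) ** 2, axis=2)
                dist = np.sqrt(np.min(d2, axis=1))
                stepmag = np.hypot(step[:, 0], step[:, 1])
                over = stepmag > dist
                if np.any(over):  # do not overshoot the aster center
                    step[over] *= (dist[over] / stepmag[over])[:, None]
            p += step

    actin = TimeSeries(actin_frames, cparams.frame_interval_s, t0_index=0)
    myosin = TimeSeries(myosin_frames, cparams.frame_interval_s, t0_index=0)
    return actin, myosin, flows


def _poly_length(p: np.ndarray) -> float:
    return float(np.sum(np.hypot(*(np.diff(p, axis=0).T))))


def contraction_scenario(
    mode: str,
    seed: int,
    optics: SynthParams | None = None,
    n_frames: int = 15,
) -> tuple[SynthParams, ContractionParams]:
    """Canonical generator conditions for the three contraction phenotypes.

    ``global``: four asters, one per image quadrant, capturing the whole
    field — every filament converges and the network quiets once the
    asters are formed.  ``partial``: a single aster of limited capture
    radius in the left image half — local aster formation while the rest
    of the network only drifts.  ``none``: no asters, no flow; the
    series evolves by bleaching and noise only.
    """
    if optics is None:
        optics = SynthParams(n_filaments=80, seed=seed)
    else:
        optics = replace(optics, seed=seed)
    w, h = optics.field_um
    if mode == "global":
        asters = ((w / 4, h / 4), (3 * w / 4, h / 4), (w / 4, 3 * h / 4), (3 * w / 4, 3 * h / 4))
        capture = 40.0
    elif mode == "partial":
        asters = ((w / 4, h / 2),)
        capture = 18.0
    elif mode == "none":
        asters = ()
        capture = 20.0
    else:
        raise ValueError("mode must be global, partial or none")
    cparams = ContractionParams(
        n_frames=n_frames,
        frame_interval_s=10.0,
        aster_centers=asters,
        v0_um_per_s=0.2,
        capture_radius_um=capture,
        mode=mode,
        seed=seed,
    )
    return optics, cparams


# ---------------------------------------------------------------------------
# scalar-trace fixtures: FRAP and RIfS
# ---------------------------------------------------------------------------


def disc_frap_recovery(t_s: np.ndarray, D_um2_per_s: float, radius_um: float) -> np.ndarray:
    """Fractional FRAP recovery for a uniform-disc bleach in 2D.

    Closed-form series solution for free diffusion into a uniformly
    bleached disc of radius r, observed as the mean intensity inside the
    disc: f(t) = e^(-x) [I0(x) + I1(x)] with x = r^2 / (2 D t); rises
    from 0 at t=0+ to 1 as t -> inf.
    """
    from scipy.special import ive

    t = np.asarray(t_s, dtype=float)
    f = np.zeros_like(t)
    pos = t > 0
    x = radius_um**2 / (2.0 * D_um2_per_s * t[pos])
    f[pos] = ive(0, x) + ive(1, x)  # ive = e^-x I_n(x), stable for large x
    return f


def generate_frap_trace(
    D_um2_per_s: float,
    bleach_radius_um: float,
    immobile_fraction: float,
    frame_time_s: float,
    n_frames: int,
    noise_sd: float,
    bleach_depth: float = 0.9,
    n_prebleach: int = 5,
    seed: int | None = 0,
) -> FRAPTrace:
    """Simulate a spot-averaged FRAP recovery trace.

    Pre-bleach intensity is normalized to 1; the bleach pulse drops the
    spot to ``1 - bleach_depth``; the mobile fraction recovers following
    2D free diffusion into a uniform-disc bleach, so the plateau is
    ``1 - immobile_fraction * bleach_depth``.
    """
    if D_um2_per_s <= 0 or bleach_radius_um <= 0:
        raise ValueError("D and bleach radius must be positive")
    if not 0.0 <= immobile_fraction <= 1.0:
        raise ValueError("immobile_fraction must be in [0, 1]")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_total = n_prebleach + n_frames
    times = np.arange(n_total) * frame_time_s
    trace = np.ones(n_total)
    t_post = times[n_prebleach:] - times[n_prebleach]
    rec = disc_frap_recovery(t_post, D_um2_per_s, bleach_radius_um)
    trace[n_prebleach:] = 1.0 - bleach_depth + bleach_depth * (1.0 - immobile_fraction) * rec
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n_total)
    return FRAPTrace(
        times_s=times,
        spot_intensity=trace,
        bleach_radius_um=bleach_radius_um,
        bleach_index=n_prebleach,
    )


def generate_rifs_trace(
    step_levels: Sequence[tuple[float, float]],
    noise_sd: float,
    sample_rate_hz: float = 1.0,
    seed: int | None = 0,
) -> RIfSTrace:
    """Piecewise-constant optical-thickness trace with Gaussian noise.

    ``step_levels`` is a list of (duration_s, dOT_nm) plateaus, e.g. a
    baseline followed by a protein-binding step.
    """
    if not step_levels:
        raise ValueError("step_levels must be non-empty")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz
    values: list[float] = []
    for duration, level in step_levels:
        if duration <= 0:
            raise ValueError("durations must be positive")
        n = max(1, int(round(duration * sample_rate_hz)))
        values.extend([level] * n)
    arr = np.asarray(values, dtype=float)
    if noise_sd > 0:
        arr = arr + rng.normal(0.0, noise_sd, size=arr.size)
    times = np.arange(arr.size) * dt
    return RIfSTrace(times_s=times, dOT_nm=arr)
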