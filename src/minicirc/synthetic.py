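"""Synthetic inputs with known ground truth for every analysis stage.

Three generators, all bit-reproducible given (config, seed):

* minicircle trajectories whose poloidal angle follows a prescribed von Mises
  law (each frame rebuilds the ideal circle with its helix phases advanced by
  a drawn angle, plus isotropic coordinate noise);
* AFM-like scenes of Gaussian-tube rings, free globular spots, and
  ring+marker complexes with the marker placed inside or outside the ring,
  smoothed by a Gaussian PSF and overlaid with pixel noise;
* noisy sinusoidal offset-vs-insert-position series with a 10.5-bp period.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .afm import AFMImage
from .errors import PlacementError
from .geometry import (
    HelixParameters,
    bend_coordinates,
    default_helix_parameters,
    helix_positions,
    quantize_twist,
)
from .phase_fit import DEFAULT_PERIOD_BP, SeriesPoint
from .poloidal import Conformation, Trajectory, poloidal_angle


# ---------------------------------------------------------------------------
# poloidally biased trajectories
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTrajectoryConfig:
    n_bp: int = 105
    frames: int = 100
    mu_deg: float = 0.0            # von Mises mean direction of the poloidal angle
    kappa: float = 10.0            # concentration; math.inf pins the angle at mu
    noise_sd_nm: float = 0.0       # isotropic Gaussian coordinate noise
    seed: int = 0
    ref_bp: int = 0                # reference phosphate the target law refers to
    strand: int = 1
    params: HelixParameters | None = None
    angle_mode: str = "centerline"

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if self.noise_sd_nm < 0:
            raise ValueError("noise sd must be >= 0")


class _PhaseCalibration:
    """Monotone map between the applied helix-phase advance and the poloidal
    angle measured on the noise-free ideal circle.

    The measured angle tracks the phase up to a smooth wobble (the 10-bp
    segment centroid sits slightly inward of the tube center), so target
    angles are converted to phases via a gridded inverse plus fixed-point
    refinement against the exact forward map.
    """

    GRID = 720

    def __init__(self, n_bp: int, params: HelixParameters, twist: float,
                 radius: float, ref_bp: int, strand: int, angle_mode: str):
        self.n_bp = n_bp
        self.params = params
        self.twist = twist
        self.radius = radius
        self.ref_bp = ref_bp
        self.strand = strand
        self.angle_mode = angle_mode
        phases = np.linspace(0.0, 360.0, self.GRID, endpoint=False)
        angles = np.array([self.forward(p) for p in phases])
        # unwrap so angle(phase) is a continuous monotone degree-valued curve
        self._phases = phases
        self._angles = np.degrees(np.unwrap(np.radians(angles)))
        if np.any(np.diff(self._angles) <= 0):
            raise ValueError("phase response is not monotone; cannot calibrate")

    def forward(self, phase_deg: float) -> float:
        shifted = self.params.with_phase_shift(phase_deg)
        pos = helix_positions(self.n_bp, shifted, self.twist)
        bent = bend_coordinates(pos, self.radius, self.angle_mode)
        return poloidal_angle(Conformation(positions=bent), self.ref_bp, self.strand)

    def phase_for_angle(self, target_deg: float, iterations: int = 4) -> float:
        t = target_deg % 360.0
        # gridded inverse: lift target onto the unwrapped branch
        a0 = self._angles[0]
        lifted = a0 + (t - a0) % 360.0
        phase = float(np.interp(lifted, self._angles, self._phases))
        # fixed-point refinement: phase <- phase + (target - forward(phase))
        for _ in range(iterations):
            err = (t - self.forward(phase) + 180.0) % 360.0 - 180.0
            phase += err
        return phase % 360.0


_calibration_cache: dict[tuple, _PhaseCalibration] = {}


def _get_calibration(n_bp: int, params: HelixParameters, twist: float,
                     radius: float, ref_bp: int, strand: int,
                     angle_mode: str) -> _PhaseCalibration:
    key = (n_bp, json.dumps(params.to_dict(), sort_keys=True), round(twist, 9),
           round(radius, 9), ref_bp, strand, angle_mode)
    cal = _calibration_cache.get(key)
    if cal is None:
        cal = _PhaseCalibration(n_bp, params, twist, radius, ref_bp, strand,
                                angle_mode)
        _calibration_cache[key] = cal
    return cal


def simulate_poloidal_trajectory(cfg: SyntheticTrajectoryConfig) -> Trajectory:
    """Frames of an ideal minicircle whose measured poloidal angle follows
    vonMises(mu, kappa).

    Per frame, a target angle is drawn (kappa = 0 gives the uniform circular
    law; kappa = inf pins the angle at mu), converted to a helix-phase advance
    through the calibrated phase response, the circle is rebuilt with all
    angular offsets advanced by that phase, and coordinate noise is added.
    """
    params = cfg.params if cfg.params is not None else default_helix_parameters()
    twist = quantize_twist(params.twist_deg, cfg.n_bp)
    radius = cfg.n_bp * params.rise_nm / (2.0 * math.pi)
    rng = np.random.default_rng(cfg.seed)
    cal = _get_calibration(cfg.n_bp, params, twist, radius, cfg.ref_bp,
                           cfg.strand, cfg.angle_mode)

    if math.isinf(cfg.kappa):
        targets = np.full(cfg.frames, cfg.mu_deg)
    elif cfg.kappa == 0.0:
        targets = rng.uniform(0.0, 360.0, size=cfg.frames)
    else:
        targets = np.degrees(
            rng.vonmises(math.radians(cfg.mu_deg), cfg.kappa, size=cfg.frames))

    frames = []
    for t, target in enumerate(targets):
        phi = cal.phase_for_angle(float(target))
        shifted = params.with_phase_shift(phi)
        pos = helix_positions(cfg.n_bp, shifted, twist)
        bent = bend_coordinates(pos, radius, cfg.angle_mode)
        if cfg.noise_sd_nm > 0:
            bent = bent + rng.normal(0.0, cfg.noise_sd_nm, size=bent.shape)
        frames.append(Conformation(positions=bent, time=float(t)))

    return Trajectory(frames=frames, metadata={
        "n_bp": cfg.n_bp, "source": "synthetic-vonmises",
        "mu_deg": cfg.mu_deg, "kappa": cfg.kappa,
        "noise_sd_nm": cfg.noise_sd_nm, "seed": cfg.seed,
        "ref_bp": cfg.ref_bp, "strand": cfg.strand,
        "twist_deg": twist, "radius_nm": radius,
        "equilibration_fraction": 0.0,
    })


# ---------------------------------------------------------------------------
# AFM scenes
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSceneConfig:
    size_px: int = 256
    pixel_size_nm: float = 1.0
    ring_radius_nm: float = 5.7        # 105 bp x 0.34 nm / (2 pi)
    ring_height_nm: float = 2.0
    tube_sigma_nm: float = 1.5         # Gaussian half-width of the ring tube
    spot_sigma_nm: float = 2.0         # free protein footprint
    spot_height_nm: float = 4.0
    marker_mass_fraction: float = 0.3  # marker share of a complex's total mass
    marker_placement: str | float = "outside"  # "inside" | "outside" | angle deg
    marker_offset_nm: float = 2.0      # radial offset of marker from ring line
    marker_sigma_nm: float = 1.5
    n_rings: int = 0
    n_spots: int = 0
    n_complexes: int = 1
    psf_sigma_nm: float = 1.0
    noise_sd_nm: float = 0.0
    seed: int = 0
    max_retries: int = 2000
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("pixel_size_nm", "ring_radius_nm", "ring_height_nm",
                     "tube_sigma_nm", "spot_sigma_nm", "spot_height_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.marker_mass_fraction < 1.0):
            raise ValueError("marker mass fraction must be in (0, 1)")


def _render_ring(grid_r: np.ndarray, grid_c: np.ndarray, center: np.ndarray,
                 radius_px: float, height: float, sigma_px: float) -> np.ndarray:
    d = np.hypot(grid_r - center[0], grid_c - center[1])
    return height * np.exp(-0.5 * ((d - radius_px) / sigma_px) ** 2)


def _render_spot(grid_r: np.ndarray, grid_c: np.ndarray, center: np.ndarray,
                 height: float, sigma_px: float) -> np.ndarray:
    d2 = (grid_r - center[0]) ** 2 + (grid_c - center[1]) ** 2
    return height * np.exp(-0.5 * d2 / sigma_px ** 2)


def simulate_afm_scene(cfg: SyntheticSceneConfig) -> tuple[AFMImage, pd.DataFrame]:
    """Render a scene and return (image, ground-truth table).

    Particle centers are placed by rejection sampling with a minimum pairwise
    separation; the truth table records type, center, and (for complexes) the
    marker position and its offset from the ring center.  Marker amplitude is
    set so the marker carries ``marker_mass_fraction`` of the complex's total
    integrated height.
    """
    px = cfg.pixel_size_nm
    n = cfg.size_px
    rng = np.random.default_rng(cfg.seed)
    grid_r, grid_c = np.meshgrid(np.arange(n, dtype=float),
                                 np.arange(n, dtype=float), indexing="ij")

    r_px = cfg.ring_radius_nm / px
    margin = r_px + (cfg.marker_offset_nm + 3 * cfg.marker_sigma_nm) / px + 3 * cfg.psf_sigma_nm / px
    min_sep = 2.0 * margin

    centers: list[np.ndarray] = []

    def place() -> np.ndarray:
        for _ in range(cfg.max_retries):
            c = rng.uniform(margin, n - margin, size=2)
            if all(np.linalg.norm(c - o) >= min_sep for o in centers):
                centers.append(c)
                return c
        raise PlacementError(
            f"could not place particle after {cfg.max_retries} retries "
            "(scene too dense)")

    image = np.zeros((n, n), dtype=float)
    truth_rows = []

    for _ in range(cfg.n_rings):
        c = place()
        image += _render_ring(grid_r, grid_c, c, r_px, cfg.ring_height_nm,
                              cfg.tube_sigma_nm / px)
        truth_rows.append({"type": "ring", "center_row": c[0], "center_col": c[1],
                           "marker_row": np.nan, "marker_col": np.nan,
                           "marker_offset_nm": np.nan, "mass_fraction": np.nan})

    for _ in range(cfg.n_spots):
        c = place()
        image += _render_spot(grid_r, grid_c, c, cfg.spot_height_nm,
                              cfg.spot_sigma_nm / px)
        truth_rows.append({"type": "spot", "center_row": c[0], "center_col": c[1],
                           "marker_row": np.nan, "marker_col": np.nan,
                           "marker_offset_nm": np.nan, "mass_fraction": np.nan})

    for _ in range(cfg.n_complexes):
        c = place()
        ring = _render_ring(grid_r, grid_c, c, r_px, cfg.ring_height_nm,
                            cfg.tube_sigma_nm / px)
        if isinstance(cfg.marker_placement, str):
            sign = {"inside": -1.0, "outside": +1.0}[cfg.marker_placement]
            d_px = r_px + sign * cfg.marker_offset_nm / px
            ang = rng.uniform(0.0, 2.0 * math.pi)
        else:
            d_px = r_px + cfg.marker_offset_nm / px
            ang = math.radians(float(cfg.marker_placement))
        mpos = c + d_px * np.array([math.sin(ang), math.cos(ang)])
        unit_marker = _render_spot(grid_r, grid_c, mpos, 1.0, cfg.marker_sigma_nm / px)
        f = cfg.marker_mass_fraction
        amp = f / (1.0 - f) * float(ring.sum()) / float(unit_marker.sum())
        image += ring + amp * unit_marker
        truth_rows.append({"type": "complex", "center_row": c[0], "center_col": c[1],
                           "marker_row": mpos[0], "marker_col": mpos[1],
                           "marker_offset_nm": d_px * px, "mass_fraction": f})

    if cfg.psf_sigma_nm > 0:
        image = ndimage.gaussian_filter(image, sigma=cfg.psf_sigma_nm / px)
    if cfg.noise_sd_nm > 0:
        image = image + rng.normal(0.0, cfg.noise_sd_nm, size=image.shape)

    meta = {"source": "synthetic-scene", "seed": cfg.seed, **cfg.metadata}
    return AFMImage(image, px, meta), pd.DataFrame(truth_rows, columns=[
        "type", "center_row", "center_col", "marker_row", "marker_col",
        "marker_offset_nm", "mass_fraction"])


# ---------------------------------------------------------------------------
# delta-vs-insert-position series
# ---------------------------------------------------------------------------

def simulate_delta_series(
    peak_bp: float,
    amplitude_nm: float,
    offset_nm: float,
    noise_sd_nm: float,
    positions_bp=(0, 2, 4, 6, 8, 10, 12),
    n_per_pos: int = 30,
    seed: int = 0,
    period_bp: float = DEFAULT_PERIOD_BP,
    center: str = "median",
) -> list[SeriesPoint]:
    """Per insert position, draw noisy samples of the fixed-period sinusoid
    C + A*cos(2*pi*(p - p*)/T) and report (median-or-mean, sd, n)."""
    if amplitude_nm < 0:
        raise ValueError("amplitude must be >= 0")
    if not len(positions_bp):
        raise ValueError("positions must be non-empty")
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    rng = np.random.default_rng(seed)
    series = []
    for p in positions_bp:
        model = offset_nm + amplitude_nm * math.cos(
            2.0 * math.pi * (p - peak_bp) / period_bp)
        draws = model + rng.normal(0.0, noise_sd_nm, size=n_per_pos)
        value = float(np.median(draws) if center == "median" else np.mean(draws))
        sd = float(np.std(draws, ddof=1)) if n_per_pos > 1 else 0.0
        series.append(SeriesPoint(position_bp=float(p), value_nm=value,
                                  sd_nm=sd, n=n_per_pos))
    return series
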