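"""Synthetic list-mode event generation for a carbon pencil beam on graphite.

The generator emulates the statistical structure the analysis assumes,
not full radiation transport: a 290 MeV/u carbon pencil beam (lateral
Gaussian sigma = 11 mm) stops in a graphite phantom; excited 10B*
fragments along the track relax by emitting 718 keV prompt gammas whose
depth distribution is modelled as a plateau + end-of-range Gaussian
mixture (the true distribution is not known quantitatively); photons
Compton-scatter once in an 8-layer Si stack and are photo-absorbed in a
4-layer CdTe stack, with Klein-Nishina angular sampling, Gaussian energy
smearing, and a flat-spectrum random-coincidence background that buries
the 718 keV line in the raw summed spectrum.

Coordinate convention (lab frame, mm): x is the beam direction with
x = 0 at the entrance face of the phantom in its origin position; y is
transverse in-plane; z points toward the camera; the image plane z = 0
contains the beam axis; the first Si layer plane sits at z = +140.
Detector hits are continuous points on layer planes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .events import Detector, GroundTruthTag, Hit, TriggerGroup
from .kinematics import ELECTRON_MASS_KEV, FWHM_TO_SIGMA


@dataclass
class BeamConfig:
    """Irradiation parameters of one phantom run."""

    energy_label: str = "290 MeV/u"
    bp_depth: float = 98.4          # nominal Bragg-peak depth from entrance, mm
    lateral_sigma: float = 11.0     # pencil-beam lateral Gaussian sigma, mm
    particles_per_pulse: float = 3e9
    pulse_period: float = 3.0       # s
    pulse_on: float = 1.0           # s beam-on per pulse
    duration: float = 600.0         # s
    phantom_shift: float = 0.0      # mm along beam (0 / 30 / 60 in the study)

    def __post_init__(self) -> None:
        if self.pulse_on > self.pulse_period:
            raise ValueError("pulse_on must not exceed pulse_period")
        for name in ("bp_depth", "lateral_sigma", "particles_per_pulse",
                     "pulse_period", "pulse_on", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CameraGeometry:
    """Si/CdTe stack geometry; layer planes parallel to the image plane."""

    n_si_layers: int = 8
    n_cdte_layers: int = 4
    layer_side: float = 50.0        # mm, square layers
    si_pitch: float = 4.0           # mm between Si layer planes
    si_to_cdte_gap: float = 8.0     # mm, last Si to first CdTe
    cdte_pitch: float = 4.0
    axis_to_first_si: float = 140.0  # mm, beam axis to first Si plane
    camera_center_x: float = 98.4   # mm, beam-axis coordinate the stack is centred on

    def __post_init__(self) -> None:
        for name in ("layer_side", "si_pitch", "si_to_cdte_gap", "cdte_pitch",
                     "axis_to_first_si"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def si_layer_z(self, layer: int) -> float:
        return self.axis_to_first_si + layer * self.si_pitch

    def cdte_layer_z(self, layer: int) -> float:
        return (self.axis_to_first_si + (self.n_si_layers - 1) * self.si_pitch
                + self.si_to_cdte_gap + layer * self.cdte_pitch)

    @property
    def half_side(self) -> float:
        return self.layer_side / 2.0


@dataclass
class EmissionModel:
    """Depth distribution of 718 keV prompt-gamma emissions along the track.

    A phenomenological mixture: a uniform "plateau" component over
    (0, bp_depth) for emissions along the entrance channel, and a
    Gaussian end-of-range component at bp_depth + peak_depth_offset.
    """

    peak_depth_offset: float = 0.0  # mm relative to bp_depth
    peak_sigma: float = 5.0         # mm
    plateau_fraction: float = 0.5   # share drawn uniformly over (0, bp_depth)
    line_energy: float = 718.0      # keV
    extra_lines: list = field(default_factory=list)  # (energy keV, rel. intensity)

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must lie in [0, 1]")
        if self.peak_sigma < 0 or self.line_energy <= 0:
            raise ValueError("peak_sigma must be >= 0 and line_energy > 0")


@dataclass
class DetectorResponse:
    """Energy resolution, absorption and background model."""

    fwhm_frac_at_662: float = 0.022       # fractional FWHM at 662 keV
    resolution_scaling: str = "SQRT_E"    # or "CONSTANT_FRACTION"
    absorb_prob: float = 0.5              # P(full absorption | CdTe layer crossed)
    background_fraction: float = 0.5      # share of output coincidences that are background
    si_last_layer_prob: float = 0.5       # scatter-layer occupancy skew
    cdte_first_layer_prob: float = 0.7    # absorber-layer occupancy skew
    background_span: tuple = (40.0, 1600.0)  # keV, flat summed-energy range

    def __post_init__(self) -> None:
        for name in ("absorb_prob", "background_fraction", "si_last_layer_prob",
                     "cdte_first_layer_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.resolution_scaling not in ("SQRT_E", "CONSTANT_FRACTION"):
            raise ValueError("resolution_scaling must be SQRT_E or CONSTANT_FRACTION")
        if self.fwhm_frac_at_662 < 0:
            raise ValueError("fwhm_frac_at_662 must be >= 0")


# ---------------------------------------------------------------------------
# Samplers

def sample_emission_depth(model: EmissionModel, beam: BeamConfig, rng, n=None):
    """Draw emission positions along the beam axis, in lab x (mm).

    Mixture draw: with probability ``plateau_fraction`` uniform on
    (0, bp_depth); otherwise Gaussian(bp_depth + peak_depth_offset,
    peak_sigma) truncated at 0.  Phantom-local depths are shifted by
    ``phantom_shift`` into lab coordinates.
    """
    scalar = n is None
    m = 1 if scalar else int(n)
    from_plateau = rng.random(m) < model.plateau_fraction
    depth = np.empty(m)
    depth[from_plateau] = rng.uniform(0.0, beam.bp_depth, from_plateau.sum())
    n_peak = m - from_plateau.sum()
    mu = beam.bp_depth + model.peak_depth_offset
    peak = rng.normal(mu, model.peak_sigma, n_peak)
    # truncate at the entrance face by redrawing (resampling keeps the shape)
    while np.any(peak < 0):
        bad = peak < 0
        peak[bad] = rng.normal(mu, model.peak_sigma, bad.sum())
    depth[~from_plateau] = peak
    depth += beam.phantom_shift
    return float(depth[0]) if scalar else depth


def klein_nishina_pdf(cos_theta, e0: float):
    """Unnormalised Klein-Nishina angular density in cos(theta) at ``e0`` keV.

    Proportional to d(sigma)/d(cos theta): the differential cross-section
    per solid angle times 2*pi (constant, dropped).
    """
    cos_theta = np.asarray(cos_theta, dtype=float)
    alpha = e0 / ELECTRON_MASS_KEV
    r = 1.0 / (1.0 + alpha * (1.0 - cos_theta))  # E'/E
    return r * r * (r + 1.0 / r - (1.0 - cos_theta**2))


def sample_klein_nishina(e0: float, rng, n=None):
    """Sample Compton scattering angles (degrees) from the KN cross-section.

    Rejection sampling of cos(theta) against a uniform proposal: the
    unnormalised density is bounded by its forward value 2.0 for all
    energies.  At 718 keV the distribution is forward-peaked.
    """
    if e0 <= 0:
        raise ValueError("incident energy must be positive")
    scalar = n is None
    m = 1 if scalar else int(n)
    out = np.empty(m)
    filled = 0
    while filled < m:
        k = max(2 * (m - filled), 128)
        c = rng.uniform(-1.0, 1.0, k)
        u = rng.uniform(0.0, 2.0, k)
        acc = c[u < klein_nishina_pdf(c, e0)]
        take = min(acc.size, m - filled)
        out[filled:filled + take] = acc[:take]
        filled += take
    theta = np.rad2deg(np.arccos(out))
    return float(theta[0]) if scalar else theta


def energy_fwhm(e, resp: DetectorResponse):
    """FWHM (keV) of the energy response at deposit energy ``e`` keV."""
    e = np.asarray(e, dtype=float)
    fwhm_662 = resp.fwhm_frac_at_662 * 662.0
    if resp.resolution_scaling == "CONSTANT_FRACTION":
        return fwhm_662 * (e / 662.0)
    return fwhm_662 * np.sqrt(e / 662.0)


def smear_energy(e, resp: DetectorResponse, rng):
    """Add Gaussian detector noise to a deposit; negatives clamp to zero."""
    e = np.asarray(e, dtype=float)
    sigma = energy_fwhm(e, resp) * FWHM_TO_SIGMA
    smeared = np.clip(e + rng.normal(0.0, 1.0, e.shape) * sigma, 0.0, None)
    return float(smeared) if smeared.ndim == 0 else smeared


def total_projectiles(beam: BeamConfig) -> float:
    """Carbon ions delivered: whole pulses in the run times ions per pulse."""
    return math.floor(beam.duration / beam.pulse_period) * beam.particles_per_pulse


# ---------------------------------------------------------------------------
# Event generation

def _isotropic_directions(rng, n):
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _rotate_about(d, theta_rad, phi):
    """Directions at polar angle ``theta`` / azimuth ``phi`` about axis ``d``."""
    # orthonormal basis transverse to each d
    ref = np.zeros_like(d)
    smallest = np.argmin(np.abs(d), axis=1)
    ref[np.arange(len(d)), smallest] = 1.0
    u = np.cross(d, ref)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    st, ct = np.sin(theta_rad), np.cos(theta_rad)
    return (d * ct[:, None]
            + u * (st * np.cos(phi))[:, None]
            + v * (st * np.sin(phi))[:, None])


def _cross_plane(origin, direction, z_plane):
    """Ray-plane intersection points; NaN where the ray runs away from the plane."""
    dz = direction[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (z_plane - origin[:, 2]) / dz
    ok = (dz != 0) & (t > 0)
    pts = origin + direction * t[:, None]
    pts[~ok] = np.nan
    return pts


def _in_aperture(pts, geom: CameraGeometry):
    return (np.abs(pts[:, 0] - geom.camera_center_x) <= geom.half_side) & (
        np.abs(pts[:, 1]) <= geom.half_side
    )


def _layer_choice(rng, n, n_layers, first_prob, favoured):
    """Layer indices with one favoured layer; the rest share the remainder."""
    if n_layers == 1:
        return np.zeros(n, dtype=int)
    p = np.full(n_layers, (1.0 - first_prob) / (n_layers - 1))
    p[favoured] = first_prob
    return rng.choice(n_layers, size=n, p=p)


def _sample_timestamps(beam: BeamConfig, rng, n):
    n_pulses = max(int(beam.duration // beam.pulse_period), 1)
    pulse = rng.integers(0, n_pulses, n)
    return pulse * beam.pulse_period + rng.uniform(0.0, beam.pulse_on, n)


def generate_events(
    beam: BeamConfig,
    geom: CameraGeometry,
    emission: EmissionModel,
    resp: DetectorResponse,
    n_signal: int,
    rng,
    max_attempts: int = 50_000_000,
) -> list[TriggerGroup]:
    """Monte-Carlo generate list-mode trigger groups with ground truth.

    Signal events (exactly ``n_signal`` accepted coincidences): sample an
    emission point from the beam/emission model, emit the 718 keV photon
    isotropically, keep rays crossing the Si-stack aperture, pick the
    scatter layer, draw the scattering angle from Klein-Nishina and the
    azimuth uniformly, split the energy, propagate the scattered ray to a
    CdTe layer (Bernoulli full-absorption), smear both deposits, and tag
    the truth.  Background coincidences (``background_fraction`` of the
    output) pair independent uniform positions in random Si and CdTe
    layers with energies drawn so the summed spectrum is flat over
    ``background_span``.  Timestamps fall uniformly within beam-on
    intervals; output is time-ordered.
    """
    if geom.layer_side <= 0:
        raise ValueError("camera aperture has zero solid angle")
    if resp.background_fraction >= 1.0:
        raise ValueError("background_fraction must be < 1 when generating signal")
    sig_rng, bg_rng, t_rng = rng.spawn(3)

    groups: list[TriggerGroup] = []
    attempts = 0
    batch = max(4 * n_signal, 4096)
    while len(groups) < n_signal and attempts < max_attempts:
        attempts += batch
        n_found = _signal_batch(beam, geom, emission, resp, sig_rng, batch,
                                groups, n_signal)
        if n_found == 0 and attempts > 100 * batch:
            break
    if len(groups) < n_signal:
        raise RuntimeError(
            f"generated only {len(groups)}/{n_signal} signal events in "
            f"{attempts} attempts; check geometry/acceptance"
        )

    bf = resp.background_fraction
    n_bg = int(round(n_signal * bf / (1.0 - bf))) if bf > 0 else 0
    groups.extend(_background_batch(geom, resp, bg_rng, n_bg))

    times = _sample_timestamps(beam, t_rng, len(groups))
    stamped = [TriggerGroup(t_s=float(t), hits=g.hits, truth=g.truth)
               for g, t in zip(groups, times)]
    stamped.sort(key=lambda g: g.t_s)
    return stamped


def _signal_batch(beam, geom, emission, resp, rng, m, out, n_target) -> int:
    """One vectorised batch of signal attempts; appends accepted groups."""
    e0 = emission.line_energy
    # emission points: depth along x, lateral Gaussian in y and z
    x = sample_emission_depth(emission, beam, rng, m)
    y = rng.normal(0.0, beam.lateral_sigma, m)
    z = rng.normal(0.0, beam.lateral_sigma, m)
    src = np.column_stack([x, y, z])
    d = _isotropic_directions(rng, m)

    # must cross the front-face aperture of the Si stack
    front = _cross_plane(src, d, geom.si_layer_z(0))
    keep = ~np.isnan(front[:, 0]) & _in_aperture(front, geom)
    src, d = src[keep], d[keep]
    if src.shape[0] == 0:
        return 0

    # interaction layer: last Si layer favoured (occupancy skew), point on plane
    si_layer = _layer_choice(rng, src.shape[0], geom.n_si_layers,
                             resp.si_last_layer_prob, geom.n_si_layers - 1)
    z_si = geom.axis_to_first_si + si_layer * geom.si_pitch
    scat = src + d * ((z_si - src[:, 2]) / d[:, 2])[:, None]
    keep = _in_aperture(scat, geom)
    src, d, si_layer, scat = src[keep], d[keep], si_layer[keep], scat[keep]
    if src.shape[0] == 0:
        return 0

    # Klein-Nishina scatter
    n = src.shape[0]
    theta_deg = sample_klein_nishina(e0, rng, n)
    theta = np.deg2rad(theta_deg)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    d_sc = _rotate_about(d, theta, phi)
    cos_t = np.cos(theta)
    e2 = e0 / (1.0 + (e0 / ELECTRON_MASS_KEV) * (1.0 - cos_t))
    e1 = e0 - e2

    # absorber: favoured first CdTe layer, aperture and absorption checks
    cdte_layer = _layer_choice(rng, n, geom.n_cdte_layers,
                               resp.cdte_first_layer_prob, 0)
    z_cdte = np.array([geom.cdte_layer_z(j) for j in range(geom.n_cdte_layers)])[cdte_layer]
    dz = d_sc[:, 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (z_cdte - scat[:, 2]) / dz
    absb = scat + d_sc * t[:, None]
    keep = (dz > 0) & (t > 0) & _in_aperture(absb, geom)
    keep &= rng.random(n) < resp.absorb_prob
    idx = np.flatnonzero(keep)

    e1_s = smear_energy(e1[idx], resp, rng)
    e2_s = smear_energy(e2[idx], resp, rng)

    found = 0
    for k, i in enumerate(idx):
        if len(out) >= n_target:
            break
        truth = GroundTruthTag(
            emission_point=(float(src[i, 0]), float(src[i, 1]), float(src[i, 2])),
            true_e0=e0,
            is_background=False,
        )
        hits = (
            Hit(Detector.SI, int(si_layer[i]),
                (float(scat[i, 0]), float(scat[i, 1]), float(scat[i, 2])),
                float(e1_s[k])),
            Hit(Detector.CDTE, int(cdte_layer[i]),
                (float(absb[i, 0]), float(absb[i, 1]), float(absb[i, 2])),
                float(e2_s[k])),
        )
        out.append(TriggerGroup(t_s=0.0, hits=hits, truth=truth))
        found += 1
    return found


def _background_batch(geom, resp, rng, n_bg) -> list[TriggerGroup]:
    """Random uncorrelated two-hit coincidences with a flat summed spectrum."""
    if n_bg == 0:
        return []
    lo, hi = resp.background_span
    e_sum = rng.uniform(lo, hi, n_bg)
    frac = rng.uniform(0.0, 1.0, n_bg)
    e1, e2 = e_sum * frac, e_sum * (1.0 - frac)
    si_layer = rng.integers(0, geom.n_si_layers, n_bg)
    cdte_layer = rng.integers(0, geom.n_cdte_layers, n_bg)
    hs = geom.half_side
    cx = geom.camera_center_x
    xs = rng.uniform(cx - hs, cx + hs, (n_bg, 2))
    ys = rng.uniform(-hs, hs, (n_bg, 2))
    groups = []
    for i in range(n_bg):
        truth = GroundTruthTag(emission_point=(math.nan,) * 3,
                               true_e0=math.nan, is_background=True)
        hits = (
            Hit(Detector.SI, int(si_layer[i]),
                (float(xs[i, 0]), float(ys[i, 0]), geom.si_layer_z(int(si_layer[i]))),
                float(e1[i])),
            Hit(Detector.CDTE, int(cdte_layer[i]),
                (float(xs[i, 1]), float(ys[i, 1]), geom.cdte_layer_z(int(cdte_layer[i]))),
                float(e2[i])),
        )
        groups.append(TriggerGroup(t_s=0.0, hits=hits, truth=truth))
    return groups
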