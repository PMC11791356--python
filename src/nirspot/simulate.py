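"""Seeded synthetic NIR fluorescence movies with ground truth.

Forward model: each release site contributes an isotropic 2-D Gaussian
dopamine concentration field that switches on at its release onset (full
amplitude within one frame -- sensor binding is effectively instantaneous at
5 frames/s) and decays exponentially with the clearance time constant tau.
Concentration fields of overlapping sites add.  Pixel fluorescence is

    F(t, x, y) = baseline * (1 + response(sensor, c(t, x, y)))

with optional Poisson shot noise and Gaussian read noise, emulating an
InGaAs camera.  The sensor does not photobleach, so the pre-stimulation
baseline is flat in expectation.

Group presets reproduce the per-FOV statistics reported for control vs
GBA1-PD dopaminergic cultures at early (day 25) and late (day 40)
differentiation: hotspot count, hotspot-level peak dF/F0, hotspot area, and
the control-vs-PD clearance time-constant ratio of 3.5 (absolute taus of
2 s / 7 s are conventions; only the ratio is constrained).  Peak-amplitude
and area presets are sampled from lognormals with the reported mean and SD,
so the generating means equal the reported values exactly.

Ground truth per site records two peak levels: the center-pixel response and
the hotspot-level mean response over the half-maximum region -- the latter is
what an ROI-averaged trace (and hence the reported group statistics)
measures; for a Gaussian profile it is 0.5/ln2 ~ 0.72 of the center value.
Site amplitudes are calibrated against the hotspot-level target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .movie import MovieGeometry, MovieStack, StimulusProtocol
from .sensor import SensorParams, inverse_response, response

__all__ = [
    "ReleaseSite", "GroupPreset", "PRESETS", "SimConfig", "SiteTruth",
    "GroundTruth", "simulate_movie", "sample_sites", "simulate_dose_response",
    "simulate_clearance_trace",
]

#: Clearance time constant of healthy control cultures (s).  Convention: the
#: absolute value is not constrained by the reported data, only the 3.5-fold
#: control-vs-PD ratio.
CONTROL_CLEARANCE_TAU_S = 2.0
#: Clearance time constant of GBA1-PD cultures (s): 3.5 x control.
PD_CLEARANCE_TAU_S = 7.0


@dataclass(frozen=True)
class ReleaseSite:
    """One dopamine release site (generative counterpart of a hotspot)."""

    row: int
    col: int
    amplitude_um: float      # peak local DA concentration (uM)
    sigma_um: float          # spatial Gaussian sigma of the concentration field
    onset_s: float           # release onset (s from movie start)
    clearance_tau_s: float   # exponential decay constant of the field

    def __post_init__(self) -> None:
        if self.amplitude_um <= 0 or self.sigma_um <= 0 or self.clearance_tau_s <= 0:
            raise ValueError("amplitude, sigma and tau must all be positive")


@dataclass(frozen=True)
class GroupPreset:
    """Per-FOV generative statistics for one experimental group."""

    name: str
    mean_peak_dff: float
    sd_peak_dff: float
    mean_count: float
    sd_count: float
    mean_area_um2: float
    sd_area_um2: float
    clearance_tau_s: float


# Reported per-FOV statistics for the four groups.  The control-late hotspot
# size is reported inconsistently (170 +/- 19 um^2 yet "not statistically
# different" from 26 +/- 21 um^2); the early-stage value is reused there.
PRESETS: dict[str, GroupPreset] = {
    "control_early": GroupPreset("control_early", 0.158, 0.084, 45.0, 12.6,
                                 26.0, 21.0, CONTROL_CLEARANCE_TAU_S),
    "control_late": GroupPreset("control_late", 0.513, 0.431, 55.8, 23.1,
                                26.0, 21.0, CONTROL_CLEARANCE_TAU_S),
    "pd_early": GroupPreset("pd_early", 0.845, 0.364, 17.0, 8.8,
                            32.0, 21.0, PD_CLEARANCE_TAU_S),
    "pd_late": GroupPreset("pd_late", 0.328, 0.312, 16.3, 8.1,
                           11.0, 13.0, PD_CLEARANCE_TAU_S),
}


@dataclass
class SimConfig:
    """Everything needed to generate one movie bit-exactly from ``seed``."""

    geometry: MovieGeometry
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    sensor: SensorParams = field(default_factory=SensorParams)
    preset: Optional[str] = None
    sites: Optional[list[ReleaseSite]] = None
    baseline_level: float = 1000.0
    shot_noise: bool = True
    read_noise_sd: float = 10.0
    seed: int = 0
    #: fraction of the per-repeat amplitude jitter (lognormal CV) when a
    #: protocol has several stimulation epochs in one movie
    repeat_amplitude_cv: float = 0.2
    #: minimum center-to-center distance between sampled sites (px)
    min_separation_px: float = 12.0
    #: half-maximum fraction used for ground-truth areas / hotspot peaks;
    #: matches the detection default
    truth_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"choose from {sorted(PRESETS)}")
        if self.baseline_level <= 0:
            raise ValueError("baseline_level must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass(frozen=True)
class SiteTruth:
    """Ground truth for one planted site."""

    site: ReleaseSite
    center_peak_dff: float     # response of the center pixel at full amplitude
    hotspot_peak_dff: float    # mean response over the half-max pixel region
    area_um2: float            # area of the half-max pixel region
    n_pixels: int

    def to_dict(self) -> dict:
        d = asdict(self.site)
        d.update(center_peak_dff=self.center_peak_dff,
                 hotspot_peak_dff=self.hotspot_peak_dff,
                 area_um2=self.area_um2, n_pixels=self.n_pixels)
        return d


@dataclass
class GroundTruth:
    sites: list[SiteTruth]
    preset: Optional[str]
    seed: int

    def to_dict(self) -> dict:
        return {"preset": self.preset, "seed": self.seed,
                "sites": [s.to_dict() for s in self.sites]}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    s2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - s2 / 2.0), float(np.sqrt(s2))


def gaussian_halfmax_area_um2(sigma_um: float, fraction: float = 0.5) -> float:
    """Analytic area (um^2) of the region where a Gaussian field exceeds
    ``fraction`` of its peak: pi * r^2 with r^2 = 2 sigma^2 ln(1/fraction)."""
    return float(2.0 * np.pi * sigma_um ** 2 * np.log(1.0 / fraction))


def sigma_for_area(area_um2: float, fraction: float = 0.5) -> float:
    """Inverse of :func:`gaussian_halfmax_area_um2` (linear-response regime)."""
    return float(np.sqrt(area_um2 / (2.0 * np.pi * np.log(1.0 / fraction))))


def _response_patch(sensor: SensorParams, amplitude_um: float, sigma_px: float,
                    fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Response field on a local pixel patch and its above-fraction mask.

    The patch is centred on the site pixel and extends 4 sigma (at least
    3 px); the mask marks pixels whose response is >= fraction * the center
    response.  Used both for amplitude calibration and for truth records.
    """
    r = max(3, int(np.ceil(4.0 * sigma_px)))
    ax = np.arange(-r, r + 1, dtype=np.float64)
    d2 = ax[:, None] ** 2 + ax[None, :] ** 2
    conc = amplitude_um * np.exp(-d2 / (2.0 * sigma_px ** 2))
    resp = response(sensor, conc)
    mask = resp >= fraction * resp[r, r]
    return resp, mask


def _hotspot_mean_response(sensor: SensorParams, amplitude_um: float,
                           sigma_px: float, fraction: float) -> float:
    resp, mask = _response_patch(sensor, amplitude_um, sigma_px, fraction)
    return float(resp[mask].mean())


def amplitude_for_hotspot_peak(target_dff: float, sigma_px: float,
                               sensor: SensorParams,
                               fraction: float = 0.5) -> float:
    """Concentration amplitude (uM) whose half-max-region mean response equals
    ``target_dff``.

    Because every pixel in the region responds at >= fraction * center, the
    region mean is bracketed between fraction * center and center, which gives
    a guaranteed root bracket in amplitude.
    """
    if not 0 < target_dff < 0.9 * sensor.dfmax:
        raise ValueError("target_dff must lie well inside (0, dfmax)")
    lo = inverse_response(sensor, target_dff)          # mean <= center == target
    hi_dff = min(target_dff / fraction, 0.999 * sensor.dfmax)
    hi = inverse_response(sensor, hi_dff)              # mean >= fraction*center >= target

    def g(a: float) -> float:
        return _hotspot_mean_response(sensor, a, sigma_px, fraction) - target_dff

    glo, ghi = g(lo), g(hi)
    if glo >= 0:
        return lo
    if ghi <= 0:
        return hi
    return float(brentq(g, lo, hi, xtol=1e-12, rtol=1e-12))


def _site_truth(site: ReleaseSite, sensor: SensorParams, pixel_size_um: float,
                fraction: float) -> SiteTruth:
    sigma_px = site.sigma_um / pixel_size_um
    resp, mask = _response_patch(sensor, site.amplitude_um, sigma_px, fraction)
    r = resp.shape[0] // 2
    n_px = int(mask.sum())
    return SiteTruth(
        site=site,
        center_peak_dff=float(resp[r, r]),
        hotspot_peak_dff=float(resp[mask].mean()),
        area_um2=n_px * pixel_size_um ** 2,
        n_pixels=n_px,
    )


def sample_sites(preset: GroupPreset, geometry: MovieGeometry,
                 protocol: StimulusProtocol, rng: np.random.Generator,
                 sensor: SensorParams, *, min_separation_px: float = 12.0,
                 fraction: float = 0.5) -> list[SiteTruth]:
    """Draw one FOV's worth of release sites from a group preset.

    The per-movie site count is a rounded normal draw (truncated at 0);
    hotspot-level peak dF/F0 and half-max area are lognormal draws with the
    preset mean/SD.  Centres are placed uniformly with a minimum pairwise
    separation (random sequential placement; after 200 failed proposals the
    farthest-from-existing proposal is accepted so generation never stalls).
    """
    n = max(0, int(round(rng.normal(preset.mean_count, preset.sd_count))))
    mu_h, sg_h = lognormal_params(preset.mean_peak_dff, preset.sd_peak_dff)
    mu_a, sg_a = lognormal_params(preset.mean_area_um2, preset.sd_area_um2)
    stim_start, stim_end = protocol.repeat_windows()[0]

    truths: list[SiteTruth] = []
    placed: list[tuple[float, float]] = []
    for _ in range(n):
        h = float(rng.lognormal(mu_h, sg_h))
        h = min(h, 0.8 * sensor.dfmax)
        area = float(rng.lognormal(mu_a, sg_a))
        sigma_um = sigma_for_area(area, fraction)
        sigma_px = sigma_um / geometry.pixel_size_um
        # clamp rare huge draws so the site (3 sigma + margin) fits the FOV
        max_sigma_px = (min(geometry.height, geometry.width) / 2.0 - 2.0) / 3.0
        sigma_px = min(sigma_px, max_sigma_px)
        sigma_um = sigma_px * geometry.pixel_size_um
        margin = int(np.ceil(3.0 * sigma_px)) + 1

        best: Optional[tuple[int, int]] = None
        best_d = -1.0
        for _try in range(200):
            rr = int(rng.integers(margin, geometry.height - margin))
            cc = int(rng.integers(margin, geometry.width - margin))
            d = min((np.hypot(rr - pr, cc - pc) for pr, pc in placed),
                    default=np.inf)
            if d >= min_separation_px:
                best = (rr, cc)
                break
            if d > best_d:
                best, best_d = (rr, cc), d
        assert best is not None
        placed.append(best)

        onset = float(rng.uniform(stim_start, stim_end))
        amp = amplitude_for_hotspot_peak(h, sigma_px, sensor, fraction)
        site = ReleaseSite(best[0], best[1], amp, sigma_um, onset,
                           preset.clearance_tau_s)
        truths.append(_site_truth(site, sensor, geometry.pixel_size_um, fraction))
    return truths


def _site_time_course(site: ReleaseSite, onset_s: float, times: np.ndarray,
                      scale: float = 1.0) -> np.ndarray:
    """Unit time course: 0 before onset, then exp decay from the first frame
    at/after onset (the one-frame rise of an instantaneous sensor)."""
    f = np.zeros_like(times)
    active = times >= onset_s - 1e-12
    if np.any(active):
        t0 = times[active][0]
        f[active] = scale * np.exp(-(times[active] - t0) / site.clearance_tau_s)
    return f


def simulate_movie(config: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a movie from ``config`` and return it with its ground truth.

    Either ``config.sites`` is given explicitly or ``config.preset`` names a
    group whose sites are sampled (seeded).  Identical configs produce
    bit-identical stacks.
    """
    geom, proto = config.geometry, config.protocol
    proto.validate_against(geom)
    rng = np.random.default_rng(config.seed)

    if config.sites is not None:
        for s in config.sites:
            if not (0 <= s.row < geom.height and 0 <= s.col < geom.width):
                raise ValueError(f"site centre {(s.row, s.col)} outside the frame")
        truths = [_site_truth(s, config.sensor, geom.pixel_size_um,
                              config.truth_fraction) for s in config.sites]
    elif config.preset is not None:
        truths = sample_sites(PRESETS[config.preset], geom, proto, rng,
                              config.sensor,
                              min_separation_px=config.min_separation_px,
                              fraction=config.truth_fraction)
    else:
        truths = []

    times = geom.frame_times()
    conc = np.zeros((geom.n_frames, geom.height, geom.width), dtype=np.float64)
    windows = proto.repeat_windows()
    for truth in truths:
        site = truth.site
        sigma_px = site.sigma_um / geom.pixel_size_um
        r = max(3, int(np.ceil(4.0 * sigma_px)))
        r0, r1 = max(0, site.row - r), min(geom.height, site.row + r + 1)
        c0, c1 = max(0, site.col - r), min(geom.width, site.col + r + 1)
        yy = np.arange(r0, r1, dtype=np.float64) - site.row
        xx = np.arange(c0, c1, dtype=np.float64) - site.col
        kernel = np.exp(-(yy[:, None] ** 2 + xx[None, :] ** 2)
                        / (2.0 * sigma_px ** 2))
        tcourse = np.zeros_like(times)
        rel_onset = site.onset_s - windows[0][0]
        for k, (w0, _w1) in enumerate(windows):
            if k == 0:
                scale = 1.0
            else:
                # per-epoch amplitude jitter, mean 1
                cv = config.repeat_amplitude_cv
                if cv > 0:
                    mu, sg = lognormal_params(1.0, cv)
                    scale = float(rng.lognormal(mu, sg))
                else:
                    scale = 1.0
            tcourse += _site_time_course(site, w0 + rel_onset, times, scale)
        conc[:, r0:r1, c0:c1] += (site.amplitude_um
                                  * tcourse[:, None, None] * kernel[None, :, :])

    clean = config.baseline_level * (1.0 + response(config.sensor, conc))
    if config.shot_noise:
        frames = rng.poisson(clean).astype(np.float64)
    else:
        frames = clean
    if config.read_noise_sd > 0:
        frames = frames + rng.normal(0.0, config.read_noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None)

    stack = MovieStack(frames, geom, proto)
    return stack, GroundTruth(truths, config.preset, config.seed)


def simulate_dose_response(params: SensorParams,
                           concentrations_um: Optional[Sequence[float]] = None,
                           noise_cv: float = 0.0, seed: int = 0):
    """Seeded dose-response table with multiplicative Gaussian noise.

    ``responses = response(params, c) * (1 + eps)`` with eps ~ N(0, noise_cv^2).
    The default concentration grid spans 1 nM - 1 mM (12 log-spaced points),
    the range over which the sensor was characterised.
    """
    from .sensor import DoseResponseCurve  # local import to avoid cycle noise
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if concentrations_um is None:
        concentrations_um = np.logspace(-3, 3, 12)
    c = np.asarray(concentrations_um, dtype=np.float64)
    y = response(params, c)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        y = y * (1.0 + rng.normal(0.0, noise_cv, size=y.shape))
    return DoseResponseCurve(c, y)


def simulate_clearance_trace(tau_s: float, peak_dff: float = 1.0,
                             frame_rate_hz: float = 5.0, duration_s: float = 30.0,
                             noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Exponential clearance transient sampled at the camera frame rate.

    trace(t) = peak_dff * exp(-t / tau) + N(0, noise_sd), t = 0, 1/rate, ...
    """
    if tau_s <= 0 or duration_s <= 0:
        raise ValueError("tau_s and duration_s must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(int(round(duration_s * frame_rate_hz))) / frame_rate_hz
    trace = peak_dff * np.exp(-t / tau_s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)
    return trace
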