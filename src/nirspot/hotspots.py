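"""Detection and refinement of dopamine release hotspots in a dF/F0 stack.

Pipeline: per-pixel derivative scoring within the stimulus evaluation window
-> local-maximum seeds above a noise-derived threshold -> half-maximum region
growing -> ROI trace / peak / temporal FWHM -> rule-based refinement filters
(repeat-peak variation < 500 %, area >= 1.64 um^2 i.e. three 0.74-um pixels,
and automated noise exclusion: peak SNR, peak presence inside the window,
high-frequency power fraction).  Every stage is deterministic; ties are
broken by (row, col).

The ROI construction (half-max growth from derivative-localised seeds) is a
transparent reimplementation of the described procedure, not a port of any
matrix-factorisation code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.ndimage import uniform_filter1d

from .dff import DffStack
from .movie import DEFAULT_PIXEL_SIZE_UM

log = logging.getLogger(__name__)

#: Minimum accepted hotspot area: three combined pixels at 0.74 um/px.
MIN_HOTSPOT_PIXELS = 3
DEFAULT_MIN_AREA_UM2 = MIN_HOTSPOT_PIXELS * DEFAULT_PIXEL_SIZE_UM ** 2  # = 1.6428
#: Maximum allowed peak-height variation across stimulation repeats (%).
DEFAULT_VARIATION_LIMIT_PCT = 500.0

_EIGHT = np.ones((3, 3), dtype=bool)  # 8-connectivity structure


@dataclass
class DetectionParams:
    """Tunable knobs of the hotspot detector; defaults follow the analysis
    conventions of the recording setup (0.74 um pixels, 5 fps)."""

    derivative_smoothing: int = 3          # frames; moving-average before d/dt
    score_smoothing_px: int = 3            # odd box side for spatial score smoothing
    min_separation_px: float = 8.0         # greedy seed exclusion radius
    roi_growth_fraction: float = 0.5       # half-max region growing
    variation_limit_pct: float = DEFAULT_VARIATION_LIMIT_PCT
    min_area_um2: float = DEFAULT_MIN_AREA_UM2
    snr_min: float = 3.0                   # seed threshold + trace SNR floor
    min_peak_dff: float = 0.05             # absolute amplitude floor for seeds
    peak_window_pad_s: float = 2.0         # evaluation window = stim + pad
    highfreq_cutoff_hz: float = 1.0
    max_highfreq_power_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.derivative_smoothing < 1:
            raise ValueError("derivative_smoothing must be >= 1")
        if self.score_smoothing_px < 1 or self.score_smoothing_px % 2 == 0:
            raise ValueError("score_smoothing_px must be odd and >= 1")
        if not 0 < self.roi_growth_fraction <= 1:
            raise ValueError("roi_growth_fraction must be in (0, 1]")
        for name in ("min_separation_px", "variation_limit_pct", "min_area_um2",
                     "snr_min", "peak_window_pad_s", "highfreq_cutoff_hz",
                     "max_highfreq_power_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Hotspot:
    """One detected release ROI with its trace and QC record."""

    id: int
    seed: tuple[int, int]
    roi: list[tuple[int, int]]         # sorted (row, col) pixels, 8-connected
    area_um2: float
    trace: np.ndarray                  # mean dF/F0 over the ROI per frame
    peak_dff: float                    # max of trace inside the eval window
    peak_time_s: float
    fwhm_s: float
    fwhm_one_sided: bool
    repeat_peaks: list[float]
    qc: dict = field(default_factory=dict)
    accepted: bool = False
    rejection_reasons: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "id": self.id, "row": self.seed[0], "col": self.seed[1],
            "area_um2": self.area_um2, "n_pixels": len(self.roi),
            "peak_dff": self.peak_dff, "peak_time_s": self.peak_time_s,
            "fwhm_s": self.fwhm_s, "fwhm_one_sided": self.fwhm_one_sided,
            "variation_ok": self.qc.get("variation_ok"),
            "size_ok": self.qc.get("size_ok"),
            "noise_ok": self.qc.get("noise_ok"),
            "accepted": self.accepted,
            "rejection_reason": ";".join(self.rejection_reasons),
        }


@dataclass
class DetectionResult:
    accepted: list[Hotspot]
    rejected: list[Hotspot]
    n_seeds: int
    score_threshold: float

    @property
    def candidates(self) -> list[Hotspot]:
        return self.accepted + self.rejected


# ---------------------------------------------------------------------------
# windows and per-pixel maps


def evaluation_window(stack: DffStack, params: DetectionParams,
                      window: Optional[tuple[int, int]] = None) -> tuple[int, int]:
    """Frame range [f0, f1) from stimulation onset to last stimulus end + pad."""
    if window is not None:
        f0, f1 = window
    else:
        if stack.protocol is None:
            raise ValueError("DffStack has no stimulation protocol and no "
                             "explicit evaluation window was given")
        rate = stack.frame_rate_hz
        f0 = int(np.floor(stack.protocol.stim_start_s * rate))
        f1 = int(np.ceil((stack.protocol.last_stim_end_s
                          + params.peak_window_pad_s) * rate)) + 1
    f0 = max(0, f0)
    f1 = min(stack.n_frames, f1)
    if f1 - f0 < 2:
        raise ValueError("evaluation window shorter than 2 frames")
    return f0, f1


def _smoothed(stack: DffStack, params: DetectionParams) -> np.ndarray:
    if params.derivative_smoothing == 1:
        return stack.dff
    return uniform_filter1d(stack.dff, size=params.derivative_smoothing,
                            axis=0, mode="nearest")


def _max_derivative(sm: np.ndarray, rate: float, f0: int, f1: int) -> np.ndarray:
    # derivative index k refers to the step sm[k] -> sm[k+1]; the step into
    # the first stimulated frame is index f0-1, hence the window extension
    d = np.diff(sm, axis=0) * rate
    a = max(f0 - 1, 0)
    b = min(f1 - 1, d.shape[0])
    return d[a:b].max(axis=0)


def _spatial_smooth(map2d: np.ndarray, size: int, valid: np.ndarray) -> np.ndarray:
    """Box-smooth a per-pixel map spatially; invalid pixels contribute 0 and
    come back as -inf."""
    if size == 1:
        out = map2d.copy()
    else:
        from scipy.ndimage import uniform_filter
        filled = np.where(valid, map2d, 0.0)
        out = uniform_filter(filled, size=size, mode="nearest")
    out[~valid] = -np.inf
    return out


def score_map(stack: DffStack, params: Optional[DetectionParams] = None,
              window: Optional[tuple[int, int]] = None) -> np.ndarray:
    """Per-pixel maximum temporal derivative of the (smoothed) dF/F0 trace
    within the evaluation window, in 1/s.  Invalid pixels score -inf."""
    params = params or DetectionParams()
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames to score derivatives")
    f0, f1 = evaluation_window(stack, params, window)
    sm = _smoothed(stack, params)
    score = _max_derivative(sm, stack.frame_rate_hz, f0, f1)
    return _spatial_smooth(score, params.score_smoothing_px, stack.valid)


def peak_map(stack: DffStack, params: Optional[DetectionParams] = None,
             window: Optional[tuple[int, int]] = None) -> np.ndarray:
    """Per-pixel maximum of the smoothed dF/F0 within the evaluation window."""
    params = params or DetectionParams()
    f0, f1 = evaluation_window(stack, params, window)
    sm = _smoothed(stack, params)
    pk = sm[f0:f1].max(axis=0)
    pk[~stack.valid] = -np.inf
    return pk


def _prestim_window(stack: DffStack, params: DetectionParams,
                    eval_window: tuple[int, int]) -> Optional[tuple[int, int]]:
    """Pre-stimulus frame range, length-matched to the evaluation window when
    possible so max-over-window statistics are comparable."""
    if stack.protocol is None:
        return None
    fs = int(np.floor(stack.protocol.stim_start_s * stack.frame_rate_hz))
    if fs < 3:
        return None
    length = min(eval_window[1] - eval_window[0], fs)
    return fs - length, fs


def mad_sigma(values: np.ndarray) -> float:
    """Robust sigma: 1.4826 * median absolute deviation."""
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(v - np.median(v))))


# ---------------------------------------------------------------------------
# seeds and ROIs


def find_seeds(score: np.ndarray, params: Optional[DetectionParams] = None,
               noise_score: Optional[np.ndarray] = None,
               peak: Optional[np.ndarray] = None) -> list[tuple[int, int]]:
    """Spatial 8-neighbour local maxima of the score map above threshold.

    Threshold = median + snr_min * MAD-sigma of ``noise_score`` (the same
    statistic computed over a pre-stimulus window), or 0 without one; seeds
    must score strictly above it.  When ``peak`` is given, seeds must also
    reach the absolute amplitude floor ``min_peak_dff`` -- the automated
    counterpart of excluding low-amplitude noise signals.  Greedy
    ``min_separation_px`` suppression in order of descending score, ties by
    (row, col).
    """
    params = params or DetectionParams()
    score = np.asarray(score, dtype=np.float64)
    threshold = 0.0
    if noise_score is not None:
        finite = noise_score[np.isfinite(noise_score)]
        if finite.size:
            threshold = float(np.median(finite)) + params.snr_min * mad_sigma(finite)

    h, w = score.shape
    padded = np.full((h + 2, w + 2), -np.inf)
    padded[1:-1, 1:-1] = np.where(np.isfinite(score), score, -np.inf)
    neigh = np.full_like(score, -np.inf)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            np.maximum(neigh, padded[1 + dr:h + 1 + dr, 1 + dc:w + 1 + dc],
                       out=neigh)
    is_max = np.isfinite(score) & (score >= neigh) & (score > threshold)
    if peak is not None:
        is_max &= peak >= params.min_peak_dff

    cand = [(float(score[r, c]), r, c) for r, c in zip(*np.nonzero(is_max))]
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    seeds: list[tuple[int, int]] = []
    min_sep2 = params.min_separation_px ** 2
    for _s, r, c in cand:
        if all((r - sr) ** 2 + (c - sc) ** 2 >= min_sep2 for sr, sc in seeds):
            seeds.append((r, c))
    return seeds


def grow_roi(stack: DffStack, seed: tuple[int, int],
             params: Optional[DetectionParams] = None,
             window: Optional[tuple[int, int]] = None,
             smoothed: Optional[np.ndarray] = None,
             floor: float = 0.0) -> list[tuple[int, int]]:
    """8-connected half-maximum region around ``seed``.

    The region is grown on the smoothed dF/F0 *snapshot at the seed's peak
    frame* (the frame of maximal smoothed dF/F0 at the seed within the
    evaluation window): pixels whose snapshot value reaches
    ``roi_growth_fraction`` x the seed's value (and any absolute noise
    ``floor``).  Growing on the release-time snapshot rather than each
    pixel's own windowed maximum keeps the background at single-frame noise
    level, so regions do not percolate through noise in dense fields.  For a
    noiseless separable release field the snapshot region equals the
    half-max region of the spatial profile.  Returns sorted (row, col)
    pixels; always contains the seed.
    """
    params = params or DetectionParams()
    f0, f1 = evaluation_window(stack, params, window)
    if smoothed is None:
        smoothed = _smoothed(stack, params)
    seed_trace = smoothed[f0:f1, seed[0], seed[1]]
    if not np.all(np.isfinite(seed_trace)):
        raise ValueError(f"seed {seed} lies on an invalid pixel")
    t_peak = f0 + int(np.argmax(seed_trace))
    snap = smoothed[t_peak]
    thr = max(params.roi_growth_fraction * snap[seed], floor)
    mask = np.isfinite(snap) & (snap >= thr)
    mask[seed] = True
    labels, _n = cc_label(mask, structure=_EIGHT)
    roi_mask = labels == labels[seed]
    return sorted(zip(*np.nonzero(roi_mask)))


def _nearest_seed_map(seeds: list[tuple[int, int]],
                      shape: tuple[int, int]) -> np.ndarray:
    """Index of the nearest seed per pixel (squared Euclidean; ties go to the
    earlier = higher-score seed).  Empty seed list gives an all -1 map."""
    out = np.full(shape, -1, dtype=np.intp)
    if not seeds:
        return out
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    best = np.full(shape, np.inf)
    for i, (sr, sc) in enumerate(seeds):
        d2 = (rr - sr) ** 2 + (cc - sc) ** 2
        better = d2 < best
        out[better] = i
        best[better] = d2[better]
    return out


def _restrict_to_cell(roi: list[tuple[int, int]], seed: tuple[int, int],
                      nearest: np.ndarray, index: int,
                      shape: tuple[int, int]) -> list[tuple[int, int]]:
    mask = np.zeros(shape, dtype=bool)
    for r, c in roi:
        if nearest[r, c] == index:
            mask[r, c] = True
    mask[seed] = True
    labels, _n = cc_label(mask, structure=_EIGHT)
    return sorted(zip(*np.nonzero(labels == labels[seed])))


# ---------------------------------------------------------------------------
# trace characterisation


def temporal_fwhm(trace: np.ndarray, frame_rate_hz: float,
                  baseline: Optional[float] = None,
                  prestim_frames: Optional[int] = None) -> tuple[float, bool]:
    """Full width at half maximum of a temporal transient, in seconds.

    Half level = baseline + (max - baseline)/2, with the baseline taken as
    the pre-stimulus median (``prestim_frames``), an explicit value, or 0.
    Crossings are linearly interpolated between samples.  If the trace never
    crosses the half level on one side of the peak the width is one-sided:
    the available half-width is doubled and the flag returned True.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size < 3:
        raise ValueError("trace too short for a width estimate")
    if baseline is None:
        baseline = float(np.median(trace[:prestim_frames])) if prestim_frames else 0.0
    ipk = int(np.argmax(trace))
    peak = trace[ipk]
    if peak <= baseline:
        raise ValueError("trace has no positive excursion above baseline")
    half = baseline + 0.5 * (peak - baseline)

    def cross(side: int) -> Optional[float]:
        i = ipk
        while 0 <= i + side < trace.size:
            j = i + side
            if trace[j] < half:
                # linear interpolation between frames i and j
                frac = (trace[i] - half) / (trace[i] - trace[j])
                return (i + side * frac) / frame_rate_hz
            i = j
        return None

    t_pk = ipk / frame_rate_hz
    left, right = cross(-1), cross(+1)
    if left is not None and right is not None:
        return right - left, False
    if left is None and right is None:
        raise ValueError("trace never crosses the half level on either side")
    width = (t_pk - left) if right is None else (right - t_pk)
    return 2.0 * width, True


def _highfreq_power_fraction(trace: np.ndarray, frame_rate_hz: float,
                             cutoff_hz: float) -> float:
    x = np.asarray(trace, dtype=np.float64)
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    if power.sum() <= 0:
        return 0.0
    freqs = np.fft.rfftfreq(x.size, d=1.0 / frame_rate_hz)
    return float(power[freqs > cutoff_hz].sum() / power.sum())


# ---------------------------------------------------------------------------
# filters and the full detector


def filter_hotspots(candidates: list[Hotspot],
                    params: Optional[DetectionParams] = None,
                    n_repeats: int = 1, frame_rate_hz: float = 5.0,
                    prestim_frames: Optional[int] = None,
                    eval_window: Optional[tuple[int, int]] = None,
                    ) -> tuple[list[Hotspot], list[Hotspot]]:
    """Apply the refinement rules; returns (accepted, rejected).

    (a) repeat variation: 100*(max-min)/min across per-repeat peaks must stay
        below ``variation_limit_pct`` (only when n_repeats > 1);
    (b) size: area >= ``min_area_um2`` (inclusive, so three pixels pass);
    (c) noise: peak SNR vs the pre-stimulus MAD >= snr_min, the trace's
        global maximum must fall inside the evaluation window, and at most
        ``max_highfreq_power_fraction`` of spectral power above the cutoff.
    Every candidate lands in exactly one of the two output lists, with its
    rejection reasons recorded.
    """
    params = params or DetectionParams()
    accepted: list[Hotspot] = []
    rejected: list[Hotspot] = []
    for hs in candidates:
        reasons: list[str] = []

        variation_ok = True
        if n_repeats > 1 and len(hs.repeat_peaks) >= 2:
            peaks = np.asarray(hs.repeat_peaks, dtype=np.float64)
            if peaks.min() <= 0:
                variation_ok = False
                reasons.append("variation_undefined_nonpositive_repeat_peak")
            else:
                variation = 100.0 * (peaks.max() - peaks.min()) / peaks.min()
                if variation >= params.variation_limit_pct:
                    variation_ok = False
                    reasons.append(f"variation_{variation:.0f}pct")

        size_ok = hs.area_um2 >= params.min_area_um2
        if not size_ok:
            reasons.append("area_below_threshold")

        noise_ok = True
        if prestim_frames and prestim_frames >= 3:
            pre = hs.trace[:prestim_frames]
            sigma = mad_sigma(pre)
            med = float(np.median(pre))
            snr = np.inf if sigma == 0 and hs.peak_dff > med else \
                (hs.peak_dff - med) / sigma if sigma > 0 else 0.0
            if snr < params.snr_min:
                noise_ok = False
                reasons.append("low_snr")
        if eval_window is not None:
            imax = int(np.argmax(hs.trace))
            if not (eval_window[0] <= imax < eval_window[1]):
                noise_ok = False
                reasons.append("no_peak_in_window")
        hf = _highfreq_power_fraction(hs.trace, frame_rate_hz,
                                      params.highfreq_cutoff_hz)
        if hf > params.max_highfreq_power_fraction:
            noise_ok = False
            reasons.append("highfreq_noise")

        hs.qc = {"variation_ok": variation_ok, "size_ok": size_ok,
                 "noise_ok": noise_ok}
        hs.accepted = variation_ok and size_ok and noise_ok
        hs.rejection_reasons = reasons
        (accepted if hs.accepted else rejected).append(hs)
    return accepted, rejected


def detect_hotspots(stack: DffStack,
                    params: Optional[DetectionParams] = None,
                    window: Optional[tuple[int, int]] = None) -> DetectionResult:
    """End-to-end hotspot detection on a dF/F0 stack.

    score_map -> find_seeds -> grow_roi -> trace/peak/FWHM -> filter_hotspots.
    Deterministic given inputs.
    """
    params = params or DetectionParams()
    if stack.geometry is None:
        raise ValueError("DffStack carries no geometry")
    rate = stack.frame_rate_hz
    px_area = stack.geometry.pixel_area_um2
    ew = evaluation_window(stack, params, window)
    sm = _smoothed(stack, params)

    score = _spatial_smooth(_max_derivative(sm, rate, ew[0], ew[1]),
                            params.score_smoothing_px, stack.valid)
    pk = sm[ew[0]:ew[1]].max(axis=0)
    pk[~stack.valid] = -np.inf

    pre = _prestim_window(stack, params, ew)
    noise_score = None
    roi_floor = 0.0
    threshold = 0.0
    if pre is not None:
        noise_score = _spatial_smooth(_max_derivative(sm, rate, pre[0], pre[1]),
                                      params.score_smoothing_px, stack.valid)
        finite = noise_score[np.isfinite(noise_score)]
        if finite.size:
            threshold = float(np.median(finite)) + params.snr_min * mad_sigma(finite)
        # single-frame noise level of the smoothed dF/F0, for the ROI floor
        pre_vals = sm[pre[0]:pre[1]][:, stack.valid].ravel()
        if pre_vals.size:
            roi_floor = float(np.median(pre_vals)) + params.snr_min * mad_sigma(pre_vals)

    seeds = find_seeds(score, params, noise_score=noise_score, peak=pk)

    n_repeats = stack.protocol.n_repeats if stack.protocol is not None else 1
    prestim_frames = pre[1] if pre is not None else None
    nearest = _nearest_seed_map(seeds, score.shape)
    candidates: list[Hotspot] = []
    for i, seed in enumerate(seeds):
        roi = grow_roi(stack, seed, params, window=window, smoothed=sm,
                       floor=roi_floor)
        # contested pixels go to the nearest seed (ties to the higher-score
        # one), so overlapping release fields are partitioned rather than
        # double-counted; keep the connected part containing the seed
        roi = _restrict_to_cell(roi, seed, nearest, i, score.shape)
        rows = np.fromiter((p[0] for p in roi), dtype=np.intp, count=len(roi))
        cols = np.fromiter((p[1] for p in roi), dtype=np.intp, count=len(roi))
        trace = np.nanmean(stack.dff[:, rows, cols], axis=1)
        seg = trace[ew[0]:ew[1]]
        ipk = ew[0] + int(np.argmax(seg))
        peak_dff = float(trace[ipk])

        repeat_peaks: list[float] = []
        if n_repeats > 1 and stack.protocol is not None:
            for w0, w1 in stack.protocol.repeat_windows():
                a = int(np.floor(w0 * rate))
                b = min(stack.n_frames,
                        int(np.ceil((w1 + params.peak_window_pad_s) * rate)) + 1)
                repeat_peaks.append(float(trace[a:b].max()))

        try:
            fwhm, one_sided = temporal_fwhm(trace, rate,
                                            prestim_frames=prestim_frames)
        except ValueError:
            fwhm, one_sided = np.nan, True

        candidates.append(Hotspot(
            id=i, seed=seed, roi=roi, area_um2=len(roi) * px_area,
            trace=trace, peak_dff=peak_dff, peak_time_s=ipk / rate,
            fwhm_s=fwhm, fwhm_one_sided=one_sided, repeat_peaks=repeat_peaks,
        ))

    accepted, rejected = filter_hotspots(
        candidates, params, n_repeats=n_repeats, frame_rate_hz=rate,
        prestim_frames=prestim_frames, eval_window=ew)
    log.info("hotspot detection: %d seeds -> %d accepted, %d rejected (%s)",
             len(seeds), len(accepted), len(rejected),
             _reason_counts(rejected))
    return DetectionResult(accepted=accepted, rejected=rejected,
                           n_seeds=len(seeds), score_threshold=threshold)


def _reason_counts(rejected: list[Hotspot]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for hs in rejected:
        for reason in hs.rejection_reasons:
            key = "variation" if reason.startswith("variation_") else reason
            counts[key] = counts.get(key, 0) + 1
    return counts
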