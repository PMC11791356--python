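"""Brute-force reference implementation of hotspot detection.

Re-implements the detection rules with explicit per-pixel Python loops and
no shared code with the package (apart from numpy arrays as containers), so
it can serve as an independent oracle on tiny movies.  Intentionally slow
and simple.
"""

from __future__ import annotations

import math
import statistics

import numpy as np


def _movavg_nearest(xs: list[float], w: int) -> list[float]:
    if w == 1:
        return list(xs)
    n = len(xs)
    half = w // 2
    out = []
    for t in range(n):
        acc = 0.0
        for k in range(t - half, t + half + 1):
            kk = min(max(k, 0), n - 1)
            acc += xs[kk]
        out.append(acc / w)
    return out


def _mad_sigma(vals: list[float]) -> float:
    if not vals:
        return 0.0
    med = statistics.median(vals)
    return 1.4826 * statistics.median([abs(v - med) for v in vals])


def reference_detect(dff: np.ndarray, frame_rate: float, pixel_size_um: float,
                     stim_start_s: float, stim_end_s: float, params) -> dict:
    """Run the full detection rule set naively; returns seeds, rois and
    accept/reject decisions keyed by seed."""
    nt, nr, nc = dff.shape
    f0 = math.floor(stim_start_s * frame_rate)
    f1 = min(nt, math.ceil((stim_end_s + params.peak_window_pad_s) * frame_rate) + 1)

    # per-pixel temporal smoothing
    sm = np.empty_like(dff)
    for r in range(nr):
        for c in range(nc):
            sm[:, r, c] = _movavg_nearest(list(dff[:, r, c]),
                                          params.derivative_smoothing)

    def max_deriv(a: int, b: int) -> np.ndarray:
        out = np.empty((nr, nc))
        lo, hi = max(a - 1, 0), min(b - 1, nt - 1)
        for r in range(nr):
            for c in range(nc):
                best = -math.inf
                for k in range(lo, hi):
                    d = (sm[k + 1, r, c] - sm[k, r, c]) * frame_rate
                    best = max(best, d)
                out[r, c] = best
        return out

    def box_smooth(m: np.ndarray) -> np.ndarray:
        s = params.score_smoothing_px
        if s == 1:
            return m.copy()
        half = s // 2
        out = np.empty_like(m)
        for r in range(nr):
            for c in range(nc):
                acc = 0.0
                for dr in range(-half, half + 1):
                    for dc in range(-half, half + 1):
                        rr = min(max(r + dr, 0), nr - 1)
                        cc = min(max(c + dc, 0), nc - 1)
                        acc += m[rr, cc]
                out[r, c] = acc / (s * s)
        return out

    score = box_smooth(max_deriv(f0, f1))
    pk = np.empty((nr, nc))
    for r in range(nr):
        for c in range(nc):
            pk[r, c] = max(sm[f0:f1, r, c])

    # pre-stimulus window, length-matched
    length = min(f1 - f0, f0)
    pre0, pre1 = f0 - length, f0
    noise_score = box_smooth(max_deriv(pre0, pre1))
    flat = [float(v) for v in noise_score.ravel()]
    threshold = statistics.median(flat) + params.snr_min * _mad_sigma(flat)
    pre_vals = [float(v) for v in sm[pre0:pre1].ravel()]
    roi_floor = statistics.median(pre_vals) + params.snr_min * _mad_sigma(pre_vals)

    # local maxima above threshold and amplitude floor
    cands = []
    for r in range(nr):
        for c in range(nc):
            ok = score[r, c] > threshold and pk[r, c] >= params.min_peak_dff
            if not ok:
                continue
            ismax = True
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and score[rr, cc] > score[r, c]:
                        ismax = False
            if ismax:
                cands.append((float(score[r, c]), r, c))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    seeds = []
    for _s, r, c in cands:
        if all((r - sr) ** 2 + (c - sc) ** 2 >= params.min_separation_px ** 2
               for sr, sc in seeds):
            seeds.append((r, c))

    def nearest_seed(r: int, c: int) -> int:
        best, best_d = -1, math.inf
        for i, (sr, sc) in enumerate(seeds):
            d = (r - sr) ** 2 + (c - sc) ** 2
            if d < best_d:
                best, best_d = i, d
        return best

    def component(mask: np.ndarray, seed: tuple) -> list:
        todo, seen = [seed], {seed}
        while todo:
            r, c = todo.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < nr and 0 <= cc < nc and (rr, cc) not in seen
                            and mask[rr, cc]):
                        seen.add((rr, cc))
                        todo.append((rr, cc))
        return sorted(seen)

    results = {}
    for i, seed in enumerate(seeds):
        trace_seed = [sm[t, seed[0], seed[1]] for t in range(f0, f1)]
        t_star = f0 + trace_seed.index(max(trace_seed))
        snap = sm[t_star]
        thr = max(params.roi_growth_fraction * snap[seed], roi_floor)
        mask = snap >= thr
        mask[seed] = True
        roi = component(mask, seed)
        cell = np.zeros((nr, nc), dtype=bool)
        for (r, c) in roi:
            if nearest_seed(r, c) == i:
                cell[r, c] = True
        cell[seed] = True
        roi = component(cell, seed)

        trace = np.array([float(np.mean([dff[t, r, c] for (r, c) in roi]))
                          for t in range(nt)])
        seg = list(trace[f0:f1])
        ipk = f0 + seg.index(max(seg))
        peak = trace[ipk]
        area = len(roi) * pixel_size_um ** 2

        reasons = []
        size_ok = area >= params.min_area_um2
        if not size_ok:
            reasons.append("size")
        pre_trace = [float(v) for v in trace[:pre1]]
        sigma = _mad_sigma(pre_trace)
        med = statistics.median(pre_trace)
        if sigma == 0:
            snr = math.inf if peak > med else 0.0
        else:
            snr = (peak - med) / sigma
        noise_ok = snr >= params.snr_min
        if not noise_ok:
            reasons.append("snr")
        gmax = int(np.argmax(trace))
        if not (f0 <= gmax < f1):
            noise_ok = False
            reasons.append("peak_outside")
        x = trace - trace.mean()
        power = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(nt, d=1.0 / frame_rate)
        if power.sum() > 0:
            frac = power[freqs > params.highfreq_cutoff_hz].sum() / power.sum()
            if frac > params.max_highfreq_power_fraction:
                noise_ok = False
                reasons.append("highfreq")
        results[seed] = {
            "roi": roi, "area": area, "peak": float(peak),
            "accepted": size_ok and noise_ok, "reasons": reasons,
        }
    return {"seeds": seeds, "by_seed": results, "threshold": threshold}
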