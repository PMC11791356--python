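"""Per-FOV hotspot summaries, size categories, clearance kinetics, and group
comparisons (Student's t / one-way ANOVA with Tukey HSD)."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

#: Hotspot size category bounds in um^2: small < 9, middle 9-36 (inclusive
#: on both bounds), large > 36.  Equivalently 3 um and 6 um in edge length.
SIZE_BOUNDS_UM2 = (9.0, 36.0)

#: p-value star coding thresholds, most stringent first.
STAR_LEVELS = ((0.001, "****"), (0.005, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float) -> str:
    for level, mark in STAR_LEVELS:
        if p < level:
            return mark
    return "ns"


def size_categories(areas_um2: Sequence[float],
                    bounds_um2: tuple[float, float] = SIZE_BOUNDS_UM2) -> dict[str, int]:
    """Bin hotspot areas into small/middle/large counts.

    Boundary rule: middle is closed, i.e. an area exactly at a bound counts
    as middle.  Conserves the total count and ignores input ordering.
    """
    lo, hi = bounds_um2
    a = np.asarray(list(areas_um2), dtype=np.float64)
    if a.size and a.min() < 0:
        raise ValueError("areas must be non-negative")
    return {
        "small": int((a < lo).sum()),
        "middle": int(((a >= lo) & (a <= hi)).sum()),
        "large": int((a > hi).sum()),
    }


@dataclass
class FovSummary:
    """Aggregate hotspot statistics of one movie (field of view)."""

    movie_id: str
    group: str
    n_hotspots: int
    mean_peak_dff: float
    sd_peak_dff: float
    mean_area_um2: float
    sd_area_um2: float
    size_counts: dict[str, int]
    size_fractions: dict[str, float]
    sd_defined: bool = True

    def to_row(self) -> dict:
        row = {"movie_id": self.movie_id, "group": self.group,
               "n_hotspots": self.n_hotspots,
               "mean_peak_dff": self.mean_peak_dff,
               "sd_peak_dff": self.sd_peak_dff,
               "mean_area_um2": self.mean_area_um2,
               "sd_area_um2": self.sd_area_um2,
               "sd_defined": self.sd_defined}
        for k in ("small", "middle", "large"):
            row[f"n_{k}"] = self.size_counts[k]
            row[f"frac_{k}"] = self.size_fractions[k]
        return row


def summarize_fov(hotspots, geometry=None, group: str = "",
                  movie_id: str = "") -> FovSummary:
    """Deterministic aggregation of accepted hotspots from one movie.

    SD uses the unbiased (ddof=1) estimator; with a single hotspot the SD is
    undefined and reported as 0 with ``sd_defined=False``.
    """
    peaks = np.asarray([h.peak_dff for h in hotspots], dtype=np.float64)
    areas = np.asarray([h.area_um2 for h in hotspots], dtype=np.float64)
    n = peaks.size
    sd_defined = n >= 2
    counts = size_categories(areas)
    fracs = {k: (v / n if n else 0.0) for k, v in counts.items()}
    return FovSummary(
        movie_id=movie_id, group=group, n_hotspots=n,
        mean_peak_dff=float(peaks.mean()) if n else 0.0,
        sd_peak_dff=float(peaks.std(ddof=1)) if sd_defined else 0.0,
        mean_area_um2=float(areas.mean()) if n else 0.0,
        sd_area_um2=float(areas.std(ddof=1)) if sd_defined else 0.0,
        size_counts=counts, size_fractions=fracs, sd_defined=sd_defined,
    )


def summaries_to_frame(summaries: Sequence[FovSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


# ---------------------------------------------------------------------------
# clearance kinetics


@dataclass
class ClearanceFit:
    """Single-exponential decay fit a*exp(-t/tau) + b of a clearance trace."""

    tau_s: float
    amplitude: float
    offset: float
    rss: float
    r2: float
    converged: bool
    message: str = "ok"


def fit_clearance(trace: np.ndarray, frame_rate_hz: float,
                  fit_start: Optional[int] = None,
                  min_r2: float = 0.2) -> ClearanceFit:
    """Fit ``a * exp(-t/tau) + b`` to a trace from its peak onwards.

    ``fit_start`` defaults to the argmax of the trace; at least 5 frames must
    follow it.  Initialised from a log-linear regression on the
    offset-subtracted tail.  ``converged`` is honest: it requires optimiser
    success, tau > 0, a > 0, and the exponential explaining at least
    ``min_r2`` of the variance after the peak -- a flat or white-noise trace
    fails rather than returning a spurious tau.
    """
    trace = np.asarray(trace, dtype=np.float64)
    start = int(np.argmax(trace)) if fit_start is None else int(fit_start)
    y = trace[start:]
    if y.size < 6:
        raise ValueError("need at least 5 frames after the peak to fit a decay")
    t = np.arange(y.size) / frame_rate_hz

    fail = ClearanceFit(np.nan, np.nan, np.nan, np.nan, 0.0, False, "")
    b0 = float(y.min())
    z = y - b0
    mask = z > max(1e-12, 0.05 * float(z.max(initial=0.0)))
    if mask.sum() < 3 or z.max(initial=0.0) <= 0:
        fail.message = "no decaying excursion above the offset"
        return fail
    slope, intercept = np.polyfit(t[mask], np.log(z[mask]), 1)
    if slope >= 0:
        fail.message = "trace does not decay"
        return fail
    tau0 = -1.0 / slope
    a0 = float(np.exp(intercept))

    def model(tt, a, tau, b):
        # exponent clipped so optimiser excursions to tiny/negative tau
        # cannot overflow
        return a * np.exp(np.clip(-tt / tau, -700.0, 700.0)) + b

    try:
        popt, _ = curve_fit(model, t, y, p0=(a0, tau0, b0), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        fail.message = f"fit failed: {exc}"
        return fail
    a, tau, b = (float(v) for v in popt)
    resid = y - model(t, a, tau, b)
    rss = float(np.sum(resid ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    ok = tau > 0 and a > 0 and r2 >= min_r2
    return ClearanceFit(tau, a, b, rss, r2, ok,
                        "ok" if ok else "decay model does not describe the trace")


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class GroupComparison:
    test: str
    statistic: float
    df: tuple
    p_value: float
    group_labels: list[str]
    means: list[float]
    sems: list[float]
    ns: list[int]
    stars: str
    posthoc: list[dict] = field(default_factory=list)
    flag: str = ""

    def to_dict(self) -> dict:
        return {
            "test": self.test, "statistic": self.statistic,
            "df": list(self.df), "p_value": self.p_value,
            "groups": [
                {"label": l, "mean": m, "sem": s, "n": n}
                for l, m, s, n in zip(self.group_labels, self.means,
                                      self.sems, self.ns)
            ],
            "stars": self.stars, "posthoc": self.posthoc, "flag": self.flag,
        }


def _describe(samples):
    arrays = [np.asarray(s, dtype=np.float64) for s in samples]
    ns = [a.size for a in arrays]
    means = [float(a.mean()) for a in arrays]
    sems = [float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else 0.0
            for a in arrays]
    return arrays, ns, means, sems


def compare_groups(*samples, labels: Optional[Sequence[str]] = None,
                   welch: bool = False) -> GroupComparison:
    """Two-tailed Student's t (pooled variance) for two groups; one-way ANOVA
    with Tukey's HSD post-hoc for three or more.

    ``welch=True`` switches the two-group test to Welch's unequal-variance t.
    Degenerate two-group input (zero variance in both groups with equal
    means) returns t = 0, p = 1 with a flag by convention.
    """
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    arrays, ns, means, sems = _describe(samples)
    if any(n < 2 for n in ns):
        raise ValueError("each group needs n >= 2")
    labels = list(labels) if labels is not None else \
        [f"group{i + 1}" for i in range(len(samples))]

    if len(arrays) == 2:
        a, b = arrays
        n1, n2 = ns
        if welch:
            v1, v2 = a.var(ddof=1), b.var(ddof=1)
            se2 = v1 / n1 + v2 / n2
            if se2 == 0:
                return GroupComparison("welch_t", 0.0, (float(n1 + n2 - 2),), 1.0,
                                       labels, means, sems, ns, "ns",
                                       flag="zero variance in both groups")
            t = (means[0] - means[1]) / np.sqrt(se2)
            df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1))
                             + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
            name = "welch_t"
        else:
            sp2 = (((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
                   / (n1 + n2 - 2))
            df = float(n1 + n2 - 2)
            if sp2 == 0:
                if means[0] == means[1]:
                    return GroupComparison("student_t", 0.0, (df,), 1.0, labels,
                                           means, sems, ns, "ns",
                                           flag="zero variance in both groups")
                t = np.inf if means[0] > means[1] else -np.inf
                return GroupComparison("student_t", float(t), (df,), 0.0,
                                       labels, means, sems, ns, stars(0.0),
                                       flag="zero variance, unequal means")
            t = (means[0] - means[1]) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            name = "student_t"
        p = float(2.0 * sps.t.sf(abs(t), df))
        return GroupComparison(name, float(t), (float(df),), p, labels, means,
                               sems, ns, stars(p))

    # one-way ANOVA
    grand = np.concatenate(arrays).mean()
    ssb = sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    ssw = sum(float(((a - m) ** 2).sum()) for a, m in zip(arrays, means))
    k = len(arrays)
    n_tot = sum(ns)
    dfb, dfw = k - 1, n_tot - k
    if ssw == 0:
        raise ValueError("zero within-group variance; ANOVA undefined")
    msw = ssw / dfw
    f = (ssb / dfb) / msw
    p = float(sps.f.sf(f, dfb, dfw))

    posthoc = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p_ij = float(sps.studentized_range.sf(q, k, dfw))
            posthoc.append({"a": labels[i], "b": labels[j], "diff": diff,
                            "q": float(q), "p": p_ij, "stars": stars(p_ij)})
    return GroupComparison("anova_tukey", float(f), (float(dfb), float(dfw)),
                           p, labels, means, sems, ns, stars(p), posthoc)
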