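"""Nanosensor transduction model: dopamine concentration -> fractional fluorescence.

The (GT)6-ssDNA-wrapped SWCNT nanosensor turns on its NIR-II fluorescence when
dopamine adsorbs to the DNA corona.  Its dose response is well described by a
one-site Langmuir binding isotherm (rectangular hyperbola),

    dF/F0(c) = dfmax * c / (c + Kd),

with dissociation constant ``Kd`` (concentration at half-maximal response) and
saturation amplitude ``dfmax``.  The module fits this isotherm to measured
dose-response tables, evaluates it, reads dF/F0 off emission spectra at the
(9,4)-chirality peak, and normalises analyte-specificity panels.

Units: concentrations in micromolar (uM), wavelengths in nm, dF/F0
dimensionless (multiply by 100 for percent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

#: Dissociation constant of the sensor-dopamine interaction (uM).
DEFAULT_KD_UM = 15.0
#: Saturation amplitude of the fractional response.  Derived, not printed:
#: solving the isotherm through the reported pair (dF/F0 = 5.60 at 100 uM,
#: Kd = 15 uM) gives dfmax = 5.6 * (100 + 15) / 100 = 6.44.
DEFAULT_DFMAX = 6.44
#: SWCNT extinction coefficient at 632 nm, (mg/L)^-1 cm^-1.
EXTINCTION_632NM = 0.036
#: Default spectral window (nm) containing the (9,4)-chirality emission peak
#: near 1130 nm used for solution-phase dF/F0 readout.
DEFAULT_PEAK_WINDOW_NM = (1100.0, 1160.0)


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs (not for fit failures)."""


@dataclass(frozen=True)
class SensorParams:
    """Langmuir transduction constants of the nanosensor.

    Parameters
    ----------
    kd_um:
        Dissociation constant in uM; concentration at half-maximal response.
    dfmax:
        Dimensionless maximal fractional fluorescence change (dF/F0 at
        saturation).
    hill:
        Hill exponent.  The sensor is modelled as one-site (no reported
        cooperativity), so this defaults to 1; it is exposed for sensitivity
        analyses only.
    """

    kd_um: float = DEFAULT_KD_UM
    dfmax: float = DEFAULT_DFMAX
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.kd_um <= 0:
            raise ValueError(f"kd_um must be positive, got {self.kd_um!r}")
        if self.dfmax <= 0:
            raise ValueError(f"dfmax must be positive, got {self.dfmax!r}")
        if self.hill <= 0:
            raise ValueError(f"hill must be positive, got {self.hill!r}")


def response(params: SensorParams, c):
    """Fractional fluorescence change dF/F0 at dopamine concentration ``c`` (uM).

    Monotone non-decreasing in ``c``; 0 at c = 0, ``dfmax/2`` exactly at
    c = Kd, and approaches ``dfmax`` from below as c -> infinity.  Accepts a
    scalar or array; negative concentrations raise ``ValueError``.
    """
    c_arr = np.asarray(c, dtype=np.float64)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be non-negative")
    if params.hill == 1.0:
        out = params.dfmax * c_arr / (c_arr + params.kd_um)
    else:
        ch = np.power(c_arr, params.hill)
        out = params.dfmax * ch / (ch + params.kd_um ** params.hill)
    return float(out) if np.isscalar(c) or c_arr.ndim == 0 else out


def inverse_response(params: SensorParams, dff: float) -> float:
    """Concentration (uM) producing a given dF/F0; inverse of :func:`response`.

    ``dff`` must lie in [0, dfmax).
    """
    if not 0 <= dff < params.dfmax:
        raise ValueError(f"dff must be in [0, dfmax={params.dfmax}), got {dff!r}")
    if dff == 0:
        return 0.0
    base = params.kd_um ** params.hill * dff / (params.dfmax - dff)
    return float(base ** (1.0 / params.hill))


@dataclass
class DoseResponseCurve:
    """Measured dose-response table: dF/F0 versus dopamine concentration.

    ``concentrations_um`` must be strictly increasing and non-negative; an
    optional per-point replicate standard deviation enables weighted fitting.
    """

    concentrations_um: np.ndarray
    responses: np.ndarray
    replicate_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.concentrations_um = np.asarray(self.concentrations_um, dtype=np.float64)
        self.responses = np.asarray(self.responses, dtype=np.float64)
        if self.concentrations_um.ndim != 1:
            raise CalibrationError("concentrations must be a 1-D sequence")
        if self.concentrations_um.shape != self.responses.shape:
            raise CalibrationError("concentrations and responses differ in length")
        if np.any(self.concentrations_um < 0):
            raise CalibrationError("concentrations must be non-negative")
        if np.any(np.diff(self.concentrations_um) <= 0):
            raise CalibrationError("concentrations must be strictly increasing")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=np.float64)
            if self.replicate_sd.shape != self.responses.shape:
                raise CalibrationError("replicate_sd length mismatch")
            if np.any(self.replicate_sd <= 0):
                raise CalibrationError("replicate_sd must be positive")

    @classmethod
    def from_csv(cls, path) -> "DoseResponseCurve":
        """Read a 2-3 column CSV (concentration_uM, dff[, sd])."""
        df = pd.read_csv(path)
        cols = [c.strip().lower() for c in df.columns]
        df.columns = cols
        if "concentration_um" not in cols or "dff" not in cols:
            raise CalibrationError(
                f"expected columns concentration_uM,dff[,sd]; got {list(df.columns)}"
            )
        sd = df["sd"].to_numpy() if "sd" in cols else None
        return cls(df["concentration_um"].to_numpy(), df["dff"].to_numpy(), sd)

    def to_csv(self, path) -> None:
        data = {"concentration_uM": self.concentrations_um, "dff": self.responses}
        if self.replicate_sd is not None:
            data["sd"] = self.replicate_sd
        pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class IsothermFit:
    """Result of fitting the Langmuir isotherm to a dose-response curve."""

    params: Optional[SensorParams]
    rss: float
    ok: bool
    message: str
    n_points: int

    def to_dict(self) -> dict:
        d = {"ok": self.ok, "message": self.message, "rss": self.rss,
             "n_points": self.n_points}
        if self.params is not None:
            d.update(kd_um=self.params.kd_um, dfmax=self.params.dfmax,
                     hill=self.params.hill)
        return d


def fit_isotherm(curve: DoseResponseCurve,
                 init: Optional[SensorParams] = None) -> IsothermFit:
    """Least-squares fit of the one-site isotherm to a dose-response curve.

    Unweighted unless the curve carries replicate standard deviations, in
    which case the fit is inverse-variance weighted.  Initialisation:
    dfmax0 = max(response), kd0 = the concentration whose response is nearest
    dfmax0 / 2.  Degenerate inputs (fewer than three distinct positive
    concentrations, non-positive responses everywhere, optimiser failure)
    yield ``ok=False`` with a diagnostic message rather than an exception.
    """
    c = curve.concentrations_um
    y = curve.responses
    positive = c > 0
    if np.unique(c[positive]).size < 3:
        return IsothermFit(None, np.nan, False,
                           "need at least 3 distinct positive concentrations",
                           c.size)
    ymax = float(y.max())
    if ymax <= 0:
        return IsothermFit(None, np.nan, False,
                           "responses are non-positive everywhere; nothing to fit",
                           c.size)

    if init is None:
        dfmax0 = ymax
        kd0 = float(c[positive][np.argmin(np.abs(y[positive] - dfmax0 / 2.0))])
        kd0 = max(kd0, float(c[positive].min()))
    else:
        dfmax0, kd0 = init.dfmax, init.kd_um

    def model(cc, kd, dfmax):
        return dfmax * cc / (cc + kd)

    sigma = curve.replicate_sd
    try:
        popt, _ = curve_fit(
            model, c, y, p0=(kd0, dfmax0), sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return IsothermFit(None, np.nan, False, f"fit failed: {exc}", c.size)

    kd_fit, dfmax_fit = float(popt[0]), float(popt[1])
    resid = y - model(c, kd_fit, dfmax_fit)
    rss = float(np.sum(resid ** 2))
    if not np.isfinite(kd_fit) or not np.isfinite(dfmax_fit):
        return IsothermFit(None, rss, False, "fit diverged", c.size)
    if kd_fit >= 10 * c[positive].max():
        return IsothermFit(SensorParams(kd_fit, dfmax_fit), rss, False,
                           "half-saturation not bracketed by the data", c.size)
    return IsothermFit(SensorParams(kd_fit, dfmax_fit), rss, True, "ok", c.size)


@dataclass
class EmissionSpectrum:
    """NIR emission spectrum on a common wavelength grid (900-1500 nm typical)."""

    wavelengths_nm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.wavelengths_nm.shape != self.intensities.shape:
            raise CalibrationError("wavelength and intensity grids differ in length")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise CalibrationError("wavelengths must be strictly increasing")
        if np.any(self.intensities < 0):
            raise CalibrationError("intensities must be non-negative")

    @classmethod
    def from_csv(cls, path) -> "EmissionSpectrum":
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        return cls(df["wavelength_nm"].to_numpy(), df["intensity"].to_numpy())


def peak_response(spec0: EmissionSpectrum, spec1: EmissionSpectrum,
                  window_nm: tuple[float, float] = DEFAULT_PEAK_WINDOW_NM) -> float:
    """dF/F0 at the baseline spectrum's peak inside ``window_nm``.

    Locates the wavelength of maximal ``spec0`` intensity inside the window
    (ties broken toward the shorter wavelength) and returns
    ``(spec1 - spec0) / spec0`` at that wavelength.  Both spectra must share
    the same grid and the window must intersect it.
    """
    if not np.array_equal(spec0.wavelengths_nm, spec1.wavelengths_nm):
        raise CalibrationError("spectra are not on identical wavelength grids")
    lo, hi = window_nm
    sel = (spec0.wavelengths_nm >= lo) & (spec0.wavelengths_nm <= hi)
    if not np.any(sel):
        raise CalibrationError(f"window {window_nm} lies outside the wavelength grid")
    idx = np.flatnonzero(sel)
    peak = idx[np.argmax(spec0.intensities[idx])]
    f0 = spec0.intensities[peak]
    if f0 <= 0:
        raise CalibrationError("zero baseline intensity at the spectral peak")
    return float((spec1.intensities[peak] - f0) / f0)


def selectivity_table(responses: Mapping[str, float]) -> pd.DataFrame:
    """Analyte responses normalised to dopamine.

    The table must contain a ``"DA"`` entry with positive response.  Rows are
    ordered with DA first, then by descending normalised response, ties broken
    alphabetically; this ordering is deterministic by construction.
    """
    if "DA" not in responses:
        raise CalibrationError("selectivity panel must contain a 'DA' entry")
    da = float(responses["DA"])
    if da <= 0:
        raise CalibrationError("DA response must be positive")
    rows = [{"analyte": name, "dff": float(v), "normalized": float(v) / da}
            for name, v in responses.items()]
    rows.sort(key=lambda r: (r["analyte"] != "DA", -r["normalized"], r["analyte"]))
    return pd.DataFrame(rows).reset_index(drop=True)


def concentration_from_absorbance(a632: float, path_cm: float = 1.0,
                                  extinction: float = EXTINCTION_632NM) -> float:
    """SWCNT mass concentration (mg/L) from absorbance at 632 nm (Beer-Lambert)."""
    return a632 / (extinction * path_cm)


def simulate_isotherm(params: SensorParams,
                      concentrations_um: Sequence[float]) -> DoseResponseCurve:
    """Noise-free model-generated dose-response curve (convenience for tests)."""
    c = np.asarray(concentrations_um, dtype=np.float64)
    return DoseResponseCurve(c, response(params, c))
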