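"""Raman characterization of disordered carbonaceous material.

Calibration against the crystalline-silicon line (520.7 cm-1), off-ROI
reference + polynomial baseline correction, simultaneous multi-band fitting
(D, G, carbon-chain subbands, C-H stretch, 2D'), multi-excitation band
dispersion in cm-1/eV, the D/G height ratio, and the mean in-plane sp2
cluster size La via either the nanocrystalline relation
La(A) = sqrt(I(D)/I(G) / C'(E)) or the graphitic relation
La(A) = C(lambda) / (I(D)/I(G)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from lmfit import models as lm
from scipy import stats
from scipy.optimize import nnls as _nnls

__all__ = [
    "RamanSpectrum",
    "PeakModel",
    "BandFitResult",
    "DispersionFit",
    "LaEstimate",
    "CarbonSummary",
    "BandMap",
    "DEFAULT_BAND_WINDOWS",
    "MAIN_BANDS",
    "UV_BANDS",
    "SI_LINE_CM1",
    "to_photon_energy",
    "calibrate",
    "baseline_correct",
    "fit_bands",
    "dispersion",
    "intensity_ratio",
    "estimate_la",
    "map_band",
    "summarize_carbon",
    "measure_line_position",
]

SI_LINE_CM1 = 520.7
_HC_EV_NM = 1239.842

DEFAULT_BAND_WINDOWS: dict[str, tuple[float, float]] = {
    "sub1266": (1200.0, 1320.0),
    "D": (1320.0, 1410.0),
    "sub1450": (1410.0, 1520.0),
    "G": (1560.0, 1660.0),
    "CH2960": (2900.0, 3050.0),
    "twoDprime3220": (3150.0, 3300.0),
}
MAIN_BANDS = ("sub1266", "D", "sub1450", "G")
UV_BANDS = ("CH2960", "twoDprime3220")

# FR nanocrystalline constant C'(2.41 eV) in A^-2 and TK constant C(514 nm) in A.
DEFAULT_C_PRIME_A2 = 0.0055
DEFAULT_C_TK_A = 44.0


def to_photon_energy(wavelength_nm: float) -> float:
    """Photon energy in eV: E = 1239.842 / lambda(nm)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return _HC_EV_NM / wavelength_nm


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RamanSpectrum:
    """Wavenumber/intensity trace tagged with its excitation wavelength."""

    wavenumber_cm1: np.ndarray
    intensity: np.ndarray
    excitation_nm: float
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.wavenumber_cm1 = np.asarray(self.wavenumber_cm1, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber_cm1.shape != self.intensity.shape:
            raise ValueError("axis and intensity shapes differ")
        if np.any(np.diff(self.wavenumber_cm1) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if self.excitation_nm <= 0:
            raise ValueError("excitation wavelength must be positive")

    @property
    def photon_energy_ev(self) -> float:
        return to_photon_energy(self.excitation_nm)


@dataclass
class PeakModel:
    """A fitted band: position, width, height and line shape."""

    center_cm1: float
    fwhm_cm1: float
    height: float
    shape: str = "lorentzian"

    @property
    def area(self) -> float:
        if self.shape == "lorentzian":
            return self.height * math.pi * self.fwhm_cm1 / 2.0
        if self.shape == "gaussian":
            sigma = self.fwhm_cm1 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            return self.height * sigma * math.sqrt(2.0 * math.pi)
        # pseudo-Voigt with equal mixing
        return 0.5 * (self.height * math.pi * self.fwhm_cm1 / 2.0) + 0.5 * (
            self.height * self.fwhm_cm1 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            * math.sqrt(2.0 * math.pi)
        )


@dataclass
class BandFitResult:
    """Simultaneous band fit: peaks keyed by band name plus diagnostics."""

    peaks: dict[str, PeakModel]
    residual_rms: float
    success: bool
    uncertainties: dict[str, dict[str, float | None]] = field(default_factory=dict)
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class DispersionFit:
    """OLS of band position on excitation photon energy."""

    band: str
    slope_cm1_per_ev: float
    intercept_at_eref_cm1: float
    residual_rms: float
    n_points: int


@dataclass
class LaEstimate:
    """sp2 cluster size with the regime and calibration constants used."""

    la_nm: float
    regime: str
    idig: float
    constants: dict


@dataclass
class CarbonSummary:
    """The quantitative carbon characterization at the 514 nm anchor."""

    pos_d_cm1: float
    pos_g_cm1: float
    fwhm_g_cm1: float
    idig: float
    la_nm: float
    regime: str
    disp_d_cm1_per_ev: float | None = None
    disp_g_cm1_per_ev: float | None = None
    constants: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pos_d_cm1": self.pos_d_cm1,
            "pos_g_cm1": self.pos_g_cm1,
            "fwhm_g_cm1": self.fwhm_g_cm1,
            "idig": self.idig,
            "la_nm": self.la_nm,
            "regime": self.regime,
            "disp_d_cm1_per_ev": self.disp_d_cm1_per_ev,
            "disp_g_cm1_per_ev": self.disp_g_cm1_per_ev,
            "constants": dict(self.constants),
            "flags": list(self.flags),
        }


@dataclass
class BandMap:
    """Fitted band intensity on a regular um grid."""

    intensity: np.ndarray
    xs_um: np.ndarray
    ys_um: np.ndarray
    band: str
    excitation_nm: float


# ---------------------------------------------------------------------------
# calibration and baseline
# ---------------------------------------------------------------------------

def measure_line_position(spectrum: RamanSpectrum, window: tuple[float, float]) -> float:
    """Sub-sample line position by parabolic interpolation of the maximum."""
    x, y = spectrum.wavenumber_cm1, spectrum.intensity
    sel = (x >= window[0]) & (x <= window[1])
    if sel.sum() < 3:
        raise ValueError("window holds fewer than 3 samples")
    xs, ysel = x[sel], y[sel]
    i = int(np.argmax(ysel))
    if i == 0 or i == len(xs) - 1:
        return float(xs[i])
    y0, y1, y2 = ysel[i - 1], ysel[i], ysel[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(xs[i])
    offset = 0.5 * (y0 - y2) / denom
    return float(xs[i] + offset * (xs[i + 1] - xs[i]))


def calibrate(spectrum: RamanSpectrum, measured_si_position_cm1: float) -> RamanSpectrum:
    """Rigidly shift the axis so the Si reference line sits at 520.7 cm-1.

    Idempotent: an already-calibrated spectrum is returned unchanged.  A
    measured position outside [480, 560] cm-1 is rejected (the wrong peak
    was probably picked).
    """
    if spectrum.calibrated:
        return replace(spectrum)
    if not 480.0 <= measured_si_position_cm1 <= 560.0:
        raise ValueError(
            f"measured Si position {measured_si_position_cm1:.1f} cm-1 outside "
            "[480, 560]: wrong line selected?"
        )
    shift = SI_LINE_CM1 - measured_si_position_cm1
    return RamanSpectrum(
        wavenumber_cm1=spectrum.wavenumber_cm1 + shift,
        intensity=spectrum.intensity.copy(),
        excitation_nm=spectrum.excitation_nm,
        calibrated=True,
    )


def default_exclusion_windows(pad_cm1: float = 20.0) -> list[tuple[float, float]]:
    """Band windows padded by 20 cm-1 on each side (baseline exclusion zones)."""
    return [(lo - pad_cm1, hi + pad_cm1) for lo, hi in DEFAULT_BAND_WINDOWS.values()]


def _outside(axis: np.ndarray, windows: Sequence[tuple[float, float]]) -> np.ndarray:
    sel = np.ones(len(axis), dtype=bool)
    for lo, hi in windows:
        sel &= ~((axis >= lo) & (axis <= hi))
    return sel


def baseline_correct(
    spectrum: RamanSpectrum,
    reference: RamanSpectrum | None = None,
    poly_order: int = 3,
    exclusion_windows: Sequence[tuple[float, float]] | None = None,
) -> RamanSpectrum:
    """Remove luminescence and scatter background.

    If an off-ROI ``reference`` spectrum is supplied, its intensity is scaled
    by least squares on the band-free points and subtracted first; a
    polynomial of ``poly_order`` fitted on the points outside the exclusion
    windows is then removed everywhere.
    """
    x, y = spectrum.wavenumber_cm1, spectrum.intensity.astype(float).copy()
    windows = default_exclusion_windows() if exclusion_windows is None else list(exclusion_windows)
    free = _outside(x, windows)
    if free.sum() < poly_order + 2:
        raise ValueError("exclusion windows leave too few points for the baseline fit")
    if reference is not None:
        if reference.wavenumber_cm1.shape != x.shape or not np.allclose(
            reference.wavenumber_cm1, x, atol=1e-6
        ):
            raise ValueError("reference axis does not match spectrum axis")
        ref = reference.intensity.astype(float)
        denom = float(np.dot(ref[free], ref[free]))
        scale = float(np.dot(ref[free], y[free])) / denom if denom > 0 else 0.0
        y = y - scale * ref
    # polynomial on the band-free region, in a scaled coordinate for conditioning
    coeffs = np.polynomial.polynomial.polyfit(x[free] / 1000.0, y[free], poly_order)
    y = y - np.polynomial.polynomial.polyval(x / 1000.0, coeffs)
    return RamanSpectrum(
        wavenumber_cm1=x.copy(),
        intensity=y,
        excitation_nm=spectrum.excitation_nm,
        calibrated=spectrum.calibrated,
    )


# ---------------------------------------------------------------------------
# band fitting
# ---------------------------------------------------------------------------

_SHAPE_MODELS = {
    "lorentzian": lm.LorentzianModel,
    "gaussian": lm.GaussianModel,
    "pseudo_voigt": lm.PseudoVoigtModel,
}


def _fit_region(axis: np.ndarray, windows: Mapping[str, tuple[float, float]],
                pad: float = 60.0) -> np.ndarray:
    sel = np.zeros(len(axis), dtype=bool)
    for lo, hi in windows.values():
        sel |= (axis >= lo - pad) & (axis <= hi + pad)
    return sel


def fit_bands(
    spectrum: RamanSpectrum,
    band_windows: Mapping[str, tuple[float, float]] | None = None,
    shapes: Mapping[str, str] | None = None,
) -> BandFitResult:
    """Simultaneous nonlinear least-squares fit of the requested bands.

    Default windows cover the four main bands (sub1266, D, sub1450, G);
    pass windows including ``CH2960`` / ``twoDprime3220`` for UV spectra.
    All bands default to Lorentzian line shapes; centers are constrained to
    their windows; a free constant absorbs residual baseline.  A spectrum
    that is flat inside every window yields ``success=False`` with no
    parameters.
    """
    if not spectrum.calibrated:
        raise ValueError("spectrum must be calibrated before band fitting")
    windows = dict(band_windows) if band_windows is not None else {
        k: DEFAULT_BAND_WINDOWS[k] for k in MAIN_BANDS
    }
    shapes = dict(shapes) if shapes is not None else {}
    x, y = spectrum.wavenumber_cm1, spectrum.intensity
    region = _fit_region(x, windows)
    if region.sum() < 5 * len(windows):
        raise ValueError("axis does not sample the requested band windows")
    xr, yr = x[region], y[region]

    span = float(np.ptp(yr)) if len(yr) else 0.0
    if span <= max(1e-9, 1e-6 * max(1.0, abs(float(np.median(yr))))):
        return BandFitResult(peaks={}, residual_rms=0.0, success=False,
                             windows=windows)

    # data-driven starting point: centers at the in-window maxima, heights by
    # non-negative unmixing of unit-height Lorentzian templates (overlapping
    # bands otherwise pull each other into local minima)
    inits: dict[str, tuple[float, float, float]] = {}
    templates = []
    for name, (lo, hi) in windows.items():
        in_win = (xr >= lo) & (xr <= hi)
        if in_win.any():
            c0 = float(xr[in_win][np.argmax(yr[in_win])])
        else:
            c0 = 0.5 * (lo + hi)
        sigma0 = 0.35 * (hi - lo)
        inits[name] = (c0, sigma0, 0.0)
        templates.append(sigma0**2 / ((xr - c0) ** 2 + sigma0**2))
    t_mat = np.column_stack(templates + [np.ones_like(xr)])
    h0s, _ = _nnls(t_mat, yr)
    for idx, name in enumerate(windows):
        c0, sigma0, _ = inits[name]
        inits[name] = (c0, sigma0, max(float(h0s[idx]), span * 0.01))

    model = lm.ConstantModel(prefix="bg_")
    params = model.make_params(c=float(h0s[-1]))
    for name, (lo, hi) in windows.items():
        shape = shapes.get(name, "lorentzian")
        try:
            comp = _SHAPE_MODELS[shape](prefix=f"{name}_")
        except KeyError:
            raise ValueError(f"unknown line shape {shape!r} for band {name}")
        model = model + comp
        c0, sigma0, h0 = inits[name]
        p = comp.make_params()
        p[f"{name}_center"].set(value=c0, min=lo, max=hi)
        # width capped at twice the window: a band may be broad, but must not
        # swallow its neighbours
        p[f"{name}_sigma"].set(value=sigma0, min=2.0, max=float(hi - lo))
        if shape == "lorentzian":
            amp0 = h0 * math.pi * sigma0
        else:
            amp0 = h0 * sigma0 * math.sqrt(2.0 * math.pi)
        p[f"{name}_amplitude"].set(value=max(amp0, 1e-6), min=0.0)
        params.update(p)

    result = model.fit(yr, params, x=xr)
    peaks: dict[str, PeakModel] = {}
    uncertainties: dict[str, dict[str, float | None]] = {}
    for name in windows:
        shape = shapes.get(name, "lorentzian")
        center = float(result.params[f"{name}_center"].value)
        fwhm = float(result.params[f"{name}_fwhm"].value)
        height = float(result.params[f"{name}_height"].value)
        peaks[name] = PeakModel(center_cm1=center, fwhm_cm1=fwhm,
                                height=height, shape=shape)
        uncertainties[name] = {
            "center": result.params[f"{name}_center"].stderr,
            "fwhm": result.params[f"{name}_fwhm"].stderr,
            "height": result.params[f"{name}_height"].stderr,
        }
    rms = float(np.sqrt(np.mean(result.residual**2)))
    return BandFitResult(peaks=peaks, residual_rms=rms,
                         success=bool(result.success),
                         uncertainties=uncertainties, windows=windows)


# ---------------------------------------------------------------------------
# multi-wavelength analysis
# ---------------------------------------------------------------------------

def dispersion(
    fits: Sequence[tuple[BandFitResult, float]],
    band: str,
    e_ref_ev: float | None = None,
) -> DispersionFit:
    """Band-position dispersion: OLS slope of Pos(band) on photon energy (eV)."""
    points = []
    for fit, excitation_nm in fits:
        if band in fit.peaks and fit.success:
            points.append((to_photon_energy(excitation_nm), fit.peaks[band].center_cm1))
    if len(points) < 2:
        raise ValueError(f"dispersion of {band} needs >= 2 excitations, got {len(points)}")
    e = np.array([p[0] for p in points])
    pos = np.array([p[1] for p in points])
    if len(points) == 2:  # closed-form two-point slope
        slope = (pos[1] - pos[0]) / (e[1] - e[0])
        intercept = pos[0] - slope * e[0]
        resid = 0.0
    else:
        res = stats.linregress(e, pos)
        slope, intercept = float(res.slope), float(res.intercept)
        resid = float(np.sqrt(np.mean((pos - (slope * e + intercept)) ** 2)))
    e_ref = to_photon_energy(514.0) if e_ref_ev is None else e_ref_ev
    return DispersionFit(
        band=band,
        slope_cm1_per_ev=float(slope),
        intercept_at_eref_cm1=float(slope * e_ref + intercept),
        residual_rms=resid,
        n_points=len(points),
    )


def intensity_ratio(fit: BandFitResult) -> float:
    """I(D)/I(G): ratio of the fitted D and G peak heights."""
    for band in ("D", "G"):
        if band not in fit.peaks:
            raise ValueError(f"band {band} missing from the fit")
    if not fit.success:
        raise ValueError("cannot form I(D)/I(G) from a failed fit")
    return fit.peaks["D"].height / fit.peaks["G"].height


def estimate_la(
    idig: float,
    photon_energy_ev: float | None = None,
    regime: str = "auto",
    fwhm_g_cm1: float | None = None,
    c_prime_a2: float = DEFAULT_C_PRIME_A2,
    c_tk_a: float = DEFAULT_C_TK_A,
    energy_scaled_c_prime: bool = False,
) -> LaEstimate:
    """Mean sp2 cluster size La from I(D)/I(G).

    Nanocrystalline regime (``nanocrystalline_FR``): La(A) =
    sqrt(idig / C'(E)) with C'(2.41 eV) = 0.0055 A^-2 (optionally scaled
    as E^-4 for other excitation energies).  Graphitic regime
    (``graphitic_TK``): La(A) = C(lambda)/idig with C(514 nm) = 44 A.
    ``regime="auto"`` selects the nanocrystalline branch when FWHM(G) >=
    40 cm-1 (broad G is the nanocrystalline signature).
    """
    if idig <= 0:
        raise ValueError("I(D)/I(G) must be positive")
    e = to_photon_energy(514.0) if photon_energy_ev is None else photon_energy_ev
    if regime == "auto":
        if fwhm_g_cm1 is None:
            raise ValueError("regime='auto' requires fwhm_g_cm1")
        regime = "nanocrystalline_FR" if fwhm_g_cm1 >= 40.0 else "graphitic_TK"
    if regime == "nanocrystalline_FR":
        c_prime = c_prime_a2
        if energy_scaled_c_prime:
            c_prime = c_prime_a2 * (e / to_photon_energy(514.0)) ** 4
        la_a = math.sqrt(idig / c_prime)
        constants = {"c_prime_A2": c_prime, "photon_energy_eV": e}
    elif regime == "graphitic_TK":
        la_a = c_tk_a / idig
        constants = {"c_tk_A": c_tk_a}
    else:
        raise ValueError(f"unknown regime {regime!r}")
    return LaEstimate(la_nm=la_a / 10.0, regime=regime, idig=idig,
                      constants=constants)


def map_band(
    grid,
    band: str = "G",
    reference: RamanSpectrum | None = None,
    poly_order: int = 3,
    band_windows: Mapping[str, tuple[float, float]] | None = None,
) -> BandMap:
    """Fit one band at every grid point and return its height map.

    Each point is baseline-corrected then band-fitted; the map records the
    fitted height, or 0 where the fit fails (e.g. band-free matrix points).
    Grid coordinates are carried through in um.
    """
    windows = {band: DEFAULT_BAND_WINDOWS[band]} if band_windows is None else dict(band_windows)
    ny, nx = grid.shape
    out = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            spec = grid.spectra[i][j]
            corrected = baseline_correct(spec, reference=reference, poly_order=poly_order)
            try:
                fit = fit_bands(corrected, band_windows=windows)
            except ValueError:
                fit = BandFitResult(peaks={}, residual_rms=0.0, success=False)
            if fit.success and band in fit.peaks:
                out[i, j] = max(fit.peaks[band].height, 0.0)
    return BandMap(intensity=out, xs_um=np.asarray(grid.xs_um),
                   ys_um=np.asarray(grid.ys_um), band=band,
                   excitation_nm=grid.excitation_nm)


def summarize_carbon(
    fits_by_wavelength: Mapping[float, BandFitResult],
    band_map: BandMap | None = None,
    c_prime_a2: float = DEFAULT_C_PRIME_A2,
    c_tk_a: float = DEFAULT_C_TK_A,
) -> CarbonSummary:
    """Assemble the carbon summary: 514 nm anchors, dispersions, La.

    Positions, FWHM(G) and I(D)/I(G) are read from the 514 nm fit (required);
    dispersions use every supplied excitation and are flagged absent when
    only one wavelength is available; La uses the automatic regime choice
    driven by FWHM(G).
    """
    if 514.0 not in {float(k) for k in fits_by_wavelength}:
        raise ValueError("a 514 nm fit is required to anchor the summary")
    fits = {float(k): v for k, v in fits_by_wavelength.items()}
    anchor = fits[514.0]
    for band in ("D", "G"):
        if band not in anchor.peaks:
            raise ValueError(f"514 nm fit lacks the {band} band")
    pos_d = anchor.peaks["D"].center_cm1
    pos_g = anchor.peaks["G"].center_cm1
    fwhm_g = anchor.peaks["G"].fwhm_cm1
    idig = intensity_ratio(anchor)
    la = estimate_la(idig, photon_energy_ev=to_photon_energy(514.0),
                     regime="auto", fwhm_g_cm1=fwhm_g,
                     c_prime_a2=c_prime_a2, c_tk_a=c_tk_a)
    flags: list[str] = []
    disp_d = disp_g = None
    pairs = [(fit, wl) for wl, fit in sorted(fits.items())]
    if len(fits) >= 2:
        disp_d = dispersion(pairs, "D").slope_cm1_per_ev
        disp_g = dispersion(pairs, "G").slope_cm1_per_ev
    else:
        flags.append("single excitation: dispersions not estimable")
    return CarbonSummary(
        pos_d_cm1=pos_d,
        pos_g_cm1=pos_g,
        fwhm_g_cm1=fwhm_g,
        idig=idig,
        la_nm=la.la_nm,
        regime=la.regime,
        disp_d_cm1_per_ev=disp_d,
        disp_g_cm1_per_ev=disp_g,
        constants=la.constants,
        flags=flags,
    )
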