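"""Seeded synthetic specimens: geometry masks, TCSPC cubes and Raman spectra.

The generator emulates the measurement situation of a permineralized early
land plant colonized by an arbuscular mycorrhizal fungus, imaged in a
petrographic thin section:

* labelled geometry masks at a micron-per-pixel scale — discs/annuli for
  spores and spore walls, tubes for hyphae, a dilated random branched tree
  for arbuscules, ellipses for vesicles;
* per-pixel TCSPC photon-count cubes in which each tissue class decays as an
  amplitude-weighted triple exponential (picosecond-range component dominant
  in fungal structures and conducting-tissue vesicles, a long >6 ns
  component dominant in other plant tissue, an intermediate-lifetime dim
  background), reconvolved with a finite-width IRF and observed under
  Poisson noise;
* Raman spectra of disordered sp2 carbon: D/G bands plus carbon-chain
  subbands on a luminescent baseline, with band centers shifting linearly in
  excitation photon energy at a per-band dispersion (cm-1/eV), anchored at
  the 514 nm photon energy;
* spatial Raman maps sampled on a regular micron grid over a labelled mask.

Every generated object is traceable to a :class:`GroundTruth` record and
identical (spec, seed) pairs reproduce bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .flim import FLIMCube, IRFModel, default_irf
from .raman import RamanSpectrum, to_photon_energy

__all__ = [
    "Structure",
    "SceneSpec",
    "DecayClassParams",
    "FLIMAcquisition",
    "Band",
    "RamanMaterial",
    "GroundTruth",
    "RamanMapGrid",
    "CLASS_IDS",
    "generate_structure_masks",
    "generate_flim_cube",
    "generate_raman_spectrum",
    "generate_raman_map",
    "default_decay_params",
    "default_acquisition",
    "default_scene",
    "default_materials",
    "arbuscule_material",
    "vesicle_material",
    "background_material",
    "silicon_reference_material",
    "diagnosis_spore_disc",
    "diagnosis_spore_with_wall",
    "diagnosis_spore_wall_annulus",
]

TISSUE_CLASSES = ("background", "fungal", "plant_vesicle", "plant_other")
CLASS_IDS = {name: i for i, name in enumerate(TISSUE_CLASSES)}

E_REF_EV = to_photon_energy(514.0)  # dispersion anchor: 514 nm photon energy


# ---------------------------------------------------------------------------
# scene geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Structure:
    """One drawable structure: shape name, geometry in um, tissue class.

    Geometry keys by shape (all um):
      disc: cx, cy, radius
      annulus: cx, cy, inner_radius, thickness
      ellipse: cx, cy, semi_major, semi_minor, angle_deg
      tube: x0, y0, x1, y1, width
      branched_tree: cx, cy, depth (int), segment_length, width, spread_deg
    """

    shape: str
    tissue_class: str
    geometry: dict

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "annulus", "tube", "branched_tree", "ellipse"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")
        for key, val in self.geometry.items():
            if key.endswith("deg") or key in ("cx", "cy", "x0", "y0", "x1", "y1"):
                continue
            if not val > 0:
                raise ValueError(f"{self.shape}: geometry parameter {key} must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of a synthetic specimen image."""

    width_px: int = 160
    height_px: int = 160
    pixel_size_um: float = 0.5
    structures: tuple[Structure, ...] = ()
    photons_per_pixel: float = 1000.0
    background_photons_per_pixel: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.photons_per_pixel < 0 or self.background_photons_per_pixel < 0:
            raise ValueError("photon budgets must be non-negative")
        object.__setattr__(self, "structures", tuple(self.structures))


def _pixel_grid(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    s = spec.pixel_size_um
    ys = (np.arange(spec.height_px) + 0.5) * s
    xs = (np.arange(spec.width_px) + 0.5) * s
    return np.meshgrid(xs, ys)


def _segment_mask(xx, yy, x0, y0, x1, y1, width):
    px, py = xx - x0, yy - y0
    dx, dy = x1 - x0, y1 - y0
    L2 = dx * dx + dy * dy
    t = np.clip((px * dx + py * dy) / L2, 0.0, 1.0) if L2 > 0 else 0.0
    d2 = (px - t * dx) ** 2 + (py - t * dy) ** 2
    return d2 <= (width / 2.0) ** 2


def _tree_segments(g: dict, rng: np.random.Generator) -> list[tuple[float, float, float, float]]:
    """Random binary-tree skeleton used as a space-filling arbuscule stand-in."""
    depth = int(g.get("depth", 4))
    length = g["segment_length"]
    spread = math.radians(g.get("spread_deg", 38.0))
    segs: list[tuple[float, float, float, float]] = []

    def grow(x, y, angle, d, l):
        if d == 0:
            return
        x1 = x + l * math.cos(angle)
        y1 = y + l * math.sin(angle)
        segs.append((x, y, x1, y1))
        for sgn in (-1.0, 1.0):
            jitter = rng.uniform(-0.3, 0.3)
            grow(x1, y1, angle + sgn * spread + jitter, d - 1, l * 0.8)

    grow(g["cx"], g["cy"], math.radians(g.get("angle_deg", -90.0)), depth, length)
    return segs


def _render_structure(st: Structure, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    xx, yy = _pixel_grid(spec)
    g = st.geometry
    if st.shape == "disc":
        return (xx - g["cx"]) ** 2 + (yy - g["cy"]) ** 2 <= g["radius"] ** 2
    if st.shape == "annulus":
        r2 = (xx - g["cx"]) ** 2 + (yy - g["cy"]) ** 2
        r_in, r_out = g["inner_radius"], g["inner_radius"] + g["thickness"]
        return (r2 > r_in**2) & (r2 <= r_out**2)
    if st.shape == "ellipse":
        ang = math.radians(g.get("angle_deg", 0.0))
        dx, dy = xx - g["cx"], yy - g["cy"]
        u = dx * math.cos(ang) + dy * math.sin(ang)
        v = -dx * math.sin(ang) + dy * math.cos(ang)
        return (u / g["semi_major"]) ** 2 + (v / g["semi_minor"]) ** 2 <= 1.0
    if st.shape == "tube":
        return _segment_mask(xx, yy, g["x0"], g["y0"], g["x1"], g["y1"], g["width"])
    # branched_tree
    mask = np.zeros(xx.shape, dtype=bool)
    for x0, y0, x1, y1 in _tree_segments(g, rng):
        mask |= _segment_mask(xx, yy, x0, y0, x1, y1, g["width"])
    return mask


def _structure_bounds(st: Structure) -> tuple[float, float, float, float] | None:
    """Conservative (xmin, ymin, xmax, ymax) in um, or None if only checkable after render."""
    g = st.geometry
    if st.shape == "disc":
        r = g["radius"]
        return g["cx"] - r, g["cy"] - r, g["cx"] + r, g["cy"] + r
    if st.shape == "annulus":
        r = g["inner_radius"] + g["thickness"]
        return g["cx"] - r, g["cy"] - r, g["cx"] + r, g["cy"] + r
    if st.shape == "ellipse":
        r = max(g["semi_major"], g["semi_minor"])
        return g["cx"] - r, g["cy"] - r, g["cx"] + r, g["cy"] + r
    if st.shape == "tube":
        h = g["width"] / 2.0
        return (min(g["x0"], g["x1"]) - h, min(g["y0"], g["y1"]) - h,
                max(g["x0"], g["x1"]) + h, max(g["y0"], g["y1"]) + h)
    return None


def generate_structure_masks(spec: SceneSpec, by: str = "class") -> np.ndarray:
    """Render the labelled mask (uint8).

    With ``by="class"`` pixel values are CLASS_IDS tissue codes; with
    ``by="structure"`` each structure gets its own label (index + 1, 0 =
    background).  Structures are drawn in order; where they overlap, later
    structures win.  A structure that does not fit inside the image frame is
    rejected with an error naming it.
    """
    if by not in ("class", "structure"):
        raise ValueError("by must be 'class' or 'structure'")
    frame_w = spec.width_px * spec.pixel_size_um
    frame_h = spec.height_px * spec.pixel_size_um
    label = np.zeros((spec.height_px, spec.width_px), dtype=np.uint8)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA5]))
    for i, st in enumerate(spec.structures):
        bounds = _structure_bounds(st)
        name = f"structure {i} ({st.shape}, {st.tissue_class})"
        if bounds is not None:
            x0, y0, x1, y1 = bounds
            if x0 < 0 or y0 < 0 or x1 > frame_w or y1 > frame_h:
                raise ValueError(f"{name} exceeds the {frame_w:g} x {frame_h:g} um frame")
        mask = _render_structure(st, spec, rng)
        if bounds is None:
            edge = mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
            if edge:
                raise ValueError(f"{name} exceeds the image frame (touches the border)")
        label[mask] = CLASS_IDS[st.tissue_class] if by == "class" else i + 1
    return label


# ---------------------------------------------------------------------------
# decay parameters and FLIM cube generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecayClassParams:
    """Amplitude fractions and lifetimes of a tissue class decay (K <= 3).

    ``amplitudes`` are pre-exponential fractions summing to 1; the photon
    share of component k is proportional to a_k * tau_k.  Lifetimes are
    stored ascending.
    """

    amplitudes: tuple[float, ...]
    lifetimes_ns: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.amplitudes, dtype=float)
        tau = np.asarray(self.lifetimes_ns, dtype=float)
        if a.shape != tau.shape or a.size == 0 or a.size > 3:
            raise ValueError("need matching amplitude/lifetime tuples, K in 1..3")
        if np.any(a < 0) or abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("amplitudes must be non-negative and sum to 1")
        if np.any(tau <= 0):
            raise ValueError("lifetimes must be positive")
        order = np.argsort(tau)
        object.__setattr__(self, "amplitudes", tuple(a[order]))
        object.__setattr__(self, "lifetimes_ns", tuple(tau[order]))

    @property
    def tau_avg_intensity_ns(self) -> float:
        a = np.asarray(self.amplitudes)
        tau = np.asarray(self.lifetimes_ns)
        return float(np.sum(a * tau**2) / np.sum(a * tau))


def default_decay_params() -> dict[str, DecayClassParams]:
    """Per-class triple-exponential defaults.

    Fungal structures and conducting-tissue vesicles are dominated by the
    0.3 ns picosecond-range component, other plant tissue by the long 6.5 ns
    component (intensity-weighted average > 6 ns), and the dim background by
    an intermediate 2.0 ns component (the intermediate value is a documented
    placeholder; see config comments).
    """
    taus = (0.3, 2.0, 6.5)
    return {
        "fungal": DecayClassParams((0.97, 0.02, 0.01), taus),
        "plant_vesicle": DecayClassParams((0.96, 0.025, 0.015), taus),
        "plant_other": DecayClassParams((0.02, 0.08, 0.90), taus),
        "background": DecayClassParams((0.05, 0.90, 0.05), taus),
    }


@dataclass(frozen=True)
class FLIMAcquisition:
    """TCSPC timing: laser period (20 MHz -> 50 ns) split into n_bins."""

    period_ns: float = 50.0
    n_bins: int = 1024
    pixel_size_um: float = 0.5
    excitation_nm: float = 440.0

    @property
    def bin_width_ns(self) -> float:
        return self.period_ns / self.n_bins


def default_acquisition() -> FLIMAcquisition:
    return FLIMAcquisition()


@dataclass
class GroundTruth:
    """Truth record for a generated scene: labels, decay truth, material truth."""

    label_mask: np.ndarray
    tau_avg_map_ns: np.ndarray | None = None
    decay_params: dict[str, DecayClassParams] | None = None
    materials: dict[str, "RamanMaterial"] | None = None
    photons_map: np.ndarray | None = None
    seed: int | None = None

    def class_mask(self, *classes: str) -> np.ndarray:
        ids = [CLASS_IDS[c] for c in classes]
        return np.isin(self.label_mask, ids)


def expected_class_decay(
    params: DecayClassParams,
    acquisition: FLIMAcquisition,
    irf: IRFModel,
) -> np.ndarray:
    """Unit-total expected decay histogram of one tissue class.

    Amplitude-weighted exponential sum on the bin centers, circularly
    convolved with the IRF (truncation to one period with renormalization;
    inter-pulse wrap of the 6.5 ns component is < 0.1% and is folded in by
    the circular convolution).
    """
    from .flim import _circular_convolve  # shared primitive

    t = (np.arange(acquisition.n_bins) + 0.5) * acquisition.bin_width_ns
    decay = np.zeros(acquisition.n_bins)
    for a, tau in zip(params.amplitudes, params.lifetimes_ns):
        if tau >= acquisition.period_ns:
            raise ValueError(
                f"lifetime {tau} ns >= period {acquisition.period_ns} ns: "
                "model ill-posed in one window"
            )
        decay += a * np.exp(-t / tau)
    h = irf.sample(acquisition.n_bins, acquisition.bin_width_ns)
    model = np.clip(_circular_convolve(h, decay), 0.0, None)
    return model / model.sum()


def generate_flim_cube(
    mask: np.ndarray,
    params: dict[str, DecayClassParams] | None = None,
    irf: IRFModel | None = None,
    acquisition: FLIMAcquisition | None = None,
    photons_per_pixel: float = 1000.0,
    background_photons_per_pixel: float = 50.0,
    seed: int = 0,
    noiseless: bool = False,
) -> tuple[FLIMCube, GroundTruth]:
    """Generate a TCSPC cube over a labelled mask.

    Each pixel's expected histogram is its class decay template scaled to the
    class photon budget; counts are Poisson draws unless ``noiseless`` is
    set, in which case the expectations are returned exactly (the
    cross-module oracle for the fitting code).
    """
    params = params if params is not None else default_decay_params()
    irf = irf if irf is not None else default_irf()
    acq = acquisition if acquisition is not None else default_acquisition()
    mask = np.asarray(mask)
    h, w = mask.shape

    budgets = {name: (background_photons_per_pixel if name == "background"
                      else photons_per_pixel) for name in TISSUE_CLASSES}
    dtype = float if noiseless else np.int32
    counts = np.zeros((acq.n_bins, h, w), dtype=dtype)
    tau_map = np.zeros((h, w))
    photons_map = np.zeros((h, w))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xF11]))

    for name, class_id in CLASS_IDS.items():
        sel = mask == class_id
        n_px = int(sel.sum())
        if n_px == 0 or name not in params:
            continue
        template = expected_class_decay(params[name], acq, irf)
        expected = budgets[name] * template
        if noiseless:
            counts[:, sel] = expected[:, None]
        else:
            counts[:, sel] = rng.poisson(expected[:, None], size=(acq.n_bins, n_px))
        tau_map[sel] = params[name].tau_avg_intensity_ns
        photons_map[sel] = budgets[name]

    cube = FLIMCube(
        counts=counts,
        bin_width_ns=acq.bin_width_ns,
        period_ns=acq.period_ns,
        pixel_size_um=acq.pixel_size_um,
        excitation_nm=acq.excitation_nm,
    )
    truth = GroundTruth(
        label_mask=mask.copy(),
        tau_avg_map_ns=tau_map,
        decay_params=dict(params),
        photons_map=photons_map,
        seed=seed,
    )
    return cube, truth


# ---------------------------------------------------------------------------
# Raman materials and spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Band:
    """One Raman band: center at the 514 nm anchor energy, dispersion in cm-1/eV."""

    name: str
    center0_cm1: float
    dispersion_cm1_per_ev: float
    fwhm_cm1: float
    height: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.fwhm_cm1 <= 0:
            raise ValueError("FWHM must be positive")
        if self.height < 0:
            raise ValueError("height must be non-negative")
        if self.shape not in ("lorentzian", "gaussian", "pseudo_voigt"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def center_at(self, excitation_nm: float) -> float:
        return self.center0_cm1 + self.dispersion_cm1_per_ev * (
            to_photon_energy(excitation_nm) - E_REF_EV
        )

    def profile(self, axis: np.ndarray, excitation_nm: float) -> np.ndarray:
        c = self.center_at(excitation_nm)
        g = self.fwhm_cm1 / 2.0
        lor = self.height * g**2 / ((axis - c) ** 2 + g**2)
        if self.shape == "lorentzian":
            return lor
        sigma = self.fwhm_cm1 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        gau = self.height * np.exp(-0.5 * ((axis - c) / sigma) ** 2)
        if self.shape == "gaussian":
            return gau
        return 0.5 * lor + 0.5 * gau


@dataclass(frozen=True)
class RamanMaterial:
    """Band list + luminescent baseline + noise model of one material."""

    name: str
    bands: tuple[Band, ...] = ()
    baseline_poly: tuple[float, ...] = (0.0,)  # ascending coeffs in (x/1000 cm-1)
    luminescence_amp: float = 0.0
    luminescence_center_cm1: float = 2200.0
    luminescence_fwhm_cm1: float = 1500.0
    noise_model: str = "poisson"               # poisson | gaussian | none
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.name != "background" and self.bands is not None:
            object.__setattr__(self, "bands", tuple(self.bands))

    def baseline(self, axis: np.ndarray) -> np.ndarray:
        x = axis / 1000.0
        out = np.zeros_like(axis, dtype=float)
        for p, coef in enumerate(self.baseline_poly):
            out += coef * x**p
        if self.luminescence_amp:
            sigma = self.luminescence_fwhm_cm1 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            out += self.luminescence_amp * np.exp(
                -0.5 * ((axis - self.luminescence_center_cm1) / sigma) ** 2
            )
        return out

    def model(self, axis: np.ndarray, excitation_nm: float) -> np.ndarray:
        out = self.baseline(axis)
        for band in self.bands:
            out += band.profile(axis, excitation_nm)
        return out


_DEFAULT_BASELINE = (120.0, 30.0, -8.0, 0.8)   # gentle cubic in (cm-1 / 1000)
_DEFAULT_LUM = 300.0


def _carbon_bands(disp_d: float, disp_g: float, idig: float) -> tuple[Band, ...]:
    g_height = 1000.0
    return (
        Band("sub1266", 1266.0, 0.0, 70.0, 0.25 * g_height),
        Band("D", 1358.0, disp_d, 110.0, idig * g_height),
        Band("sub1450", 1450.0, 0.0, 90.0, 0.20 * g_height),
        Band("G", 1608.0, disp_g, 56.0, g_height),
        Band("CH2960", 2960.0, 0.0, 60.0, 0.12 * g_height),
        Band("twoDprime3220", 3220.0, 0.0, 80.0, 0.10 * g_height),
    )


def arbuscule_material() -> RamanMaterial:
    """Disordered sp2 carbon of the fungal arbuscules.

    D/G at 1358/1608 cm-1 with FWHM(G) 56 cm-1 and height ratio 0.55 at the
    514 nm anchor; dispersions 4.1 (D) and 8.3 (G) cm-1/eV; carbon-chain
    subbands near 1266 and 1450 cm-1 (the 1450 default; a 1433 cm-1 reading
    at 514 nm also appears in the literature for such material); C-H stretch
    and 2D' bands near 2960 and 3220 cm-1.
    """
    return RamanMaterial(
        name="arbuscule",
        bands=_carbon_bands(disp_d=4.1, disp_g=8.3, idig=0.55),
        baseline_poly=_DEFAULT_BASELINE,
        luminescence_amp=_DEFAULT_LUM,
    )


def vesicle_material() -> RamanMaterial:
    """Carbon of the conducting-tissue vesicles: same bands, steeper dispersions."""
    return RamanMaterial(
        name="vesicle",
        bands=_carbon_bands(disp_d=8.2, disp_g=10.3, idig=0.55),
        baseline_poly=_DEFAULT_BASELINE,
        luminescence_amp=_DEFAULT_LUM,
    )


def background_material() -> RamanMaterial:
    """Off-structure matrix: luminescent baseline only, no carbon bands."""
    return RamanMaterial(
        name="background",
        bands=(),
        baseline_poly=_DEFAULT_BASELINE,
        luminescence_amp=_DEFAULT_LUM,
    )


def silicon_reference_material() -> RamanMaterial:
    """Crystalline-silicon wavenumber standard: a single line at 520.7 cm-1."""
    return RamanMaterial(
        name="silicon",
        bands=(Band("Si", 520.7, 0.0, 6.0, 5000.0),),
        baseline_poly=(50.0,),
    )


def default_materials() -> dict[str, RamanMaterial]:
    return {
        "fungal": arbuscule_material(),
        "plant_vesicle": vesicle_material(),
        "plant_other": background_material(),
        "background": background_material(),
    }


def default_raman_axis() -> np.ndarray:
    """Spectral scan range 0-3400 cm-1 at 1 cm-1 steps."""
    return np.arange(0.0, 3400.0 + 0.5, 1.0)


def generate_raman_spectrum(
    material: RamanMaterial,
    excitation_nm: float,
    axis: np.ndarray | None = None,
    seed: int = 0,
    noise: str | None = None,
    axis_offset_cm1: float = 0.0,
) -> RamanSpectrum:
    """Generate one spectrum of ``material`` at the given excitation.

    ``noise`` overrides the material's noise model ("poisson", "gaussian",
    "none"); ``axis_offset_cm1`` displaces the wavenumber axis rigidly to
    emulate an uncalibrated spectrometer (the spectrum is then flagged
    uncalibrated).
    """
    if excitation_nm <= 0:
        raise ValueError("excitation wavelength must be positive")
    axis = default_raman_axis() if axis is None else np.asarray(axis, dtype=float)
    if axis.ndim != 1 or len(axis) < 2 or np.any(np.diff(axis) <= 0):
        raise ValueError("axis must be strictly increasing")
    intensity = material.model(axis, excitation_nm)
    mode = material.noise_model if noise is None else noise
    if mode == "poisson":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4A]))
        intensity = rng.poisson(np.clip(intensity, 0.0, None)).astype(float)
    elif mode == "gaussian":
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x4A]))
        intensity = intensity + rng.normal(0.0, material.noise_sigma, size=len(axis))
    elif mode != "none":
        raise ValueError(f"unknown noise mode {mode!r}")
    return RamanSpectrum(
        wavenumber_cm1=axis + axis_offset_cm1,
        intensity=intensity,
        excitation_nm=excitation_nm,
        calibrated=axis_offset_cm1 == 0.0,
    )


@dataclass
class RamanMapGrid:
    """Spectra on a regular um grid: spectra[i][j] at (ys_um[i], xs_um[j])."""

    spectra: list
    xs_um: np.ndarray
    ys_um: np.ndarray
    labels: np.ndarray
    step_um: float
    excitation_nm: float

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.ys_um), len(self.xs_um)


def generate_raman_map(
    mask: np.ndarray,
    materials: dict[str, RamanMaterial] | None = None,
    step_um: float = 10.0,
    pixel_size_um: float = 0.5,
    excitation_nm: float = 514.0,
    axis: np.ndarray | None = None,
    seed: int = 0,
    noise: str | None = None,
) -> RamanMapGrid:
    """Sample one spectrum per grid point over a labelled mask.

    The grid runs at ``step_um`` intervals (default 10 um, the mapping design
    used for G-band maps of the plant axis); each point takes the material of
    the underlying tissue label.
    """
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    mask = np.asarray(mask)
    materials = materials if materials is not None else default_materials()
    id_to_class = {v: k for k, v in CLASS_IDS.items()}
    h, w = mask.shape if mask.size else (0, 0)
    if mask.size == 0:
        warnings.warn("empty mask: returning an empty Raman map grid")
        return RamanMapGrid([], np.array([]), np.array([]),
                            np.array([], dtype=np.uint8).reshape(0, 0),
                            step_um, excitation_nm)
    xs = np.arange(step_um / 2.0, w * pixel_size_um, step_um)
    ys = np.arange(step_um / 2.0, h * pixel_size_um, step_um)
    labels = np.zeros((len(ys), len(xs)), dtype=np.uint8)
    spectra: list[list[RamanSpectrum]] = []
    for i, y in enumerate(ys):
        row = []
        for j, x in enumerate(xs):
            pi = min(int(y / pixel_size_um), h - 1)
            pj = min(int(x / pixel_size_um), w - 1)
            label = int(mask[pi, pj])
            labels[i, j] = label
            mat = materials[id_to_class[label]]
            row.append(generate_raman_spectrum(
                mat, excitation_nm, axis=axis,
                seed=int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0] % (2**31)),
                noise=noise,
            ))
        spectra.append(row)
    return RamanMapGrid(spectra, xs, ys, labels, step_um, excitation_nm)


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

def default_scene(seed: int = 0) -> SceneSpec:
    """The default two-tissue specimen scene (80 x 80 um at 0.5 um/px).

    A branched arbuscule-like fungal tree, an elongate conducting-tissue
    vesicle, a disc of other plant tissue, and dim background elsewhere.
    """
    structures = (
        Structure("disc", "plant_other", {"cx": 40.0, "cy": 57.0, "radius": 15.0}),
        Structure("branched_tree", "fungal",
                  {"cx": 22.0, "cy": 38.0, "depth": 4, "segment_length": 7.0,
                   "width": 4.5, "spread_deg": 38.0, "angle_deg": -80.0}),
        Structure("ellipse", "plant_vesicle",
                  {"cx": 58.0, "cy": 22.0, "semi_major": 10.0, "semi_minor": 8.0,
                   "angle_deg": 25.0}),
    )
    return SceneSpec(width_px=160, height_px=160, pixel_size_um=0.5,
                     structures=structures, photons_per_pixel=1000.0,
                     background_photons_per_pixel=50.0, seed=seed)


def diagnosis_spore_disc(pixel_size_um: float = 0.2) -> SceneSpec:
    """Disc fixture at the diagnosed spore diameter (74 um)."""
    r = 37.0
    margin = 4.0
    side_um = 2 * (r + margin)
    n = int(math.ceil(side_um / pixel_size_um))
    c = n * pixel_size_um / 2.0
    return SceneSpec(
        width_px=n, height_px=n, pixel_size_um=pixel_size_um,
        structures=(Structure("disc", "fungal", {"cx": c, "cy": c, "radius": r}),),
    )


def diagnosis_spore_with_wall(pixel_size_um: float = 0.2) -> SceneSpec:
    """Spore lumen disc plus its 3.1-um wall annulus, as two structures."""
    thickness = 3.1
    r_out = 37.0
    margin = 4.0
    side_um = 2 * (r_out + margin)
    n = int(math.ceil(side_um / pixel_size_um))
    c = n * pixel_size_um / 2.0
    return SceneSpec(
        width_px=n, height_px=n, pixel_size_um=pixel_size_um,
        structures=(
            Structure("disc", "fungal",
                      {"cx": c, "cy": c, "radius": r_out - thickness}),
            Structure("annulus", "fungal",
                      {"cx": c, "cy": c, "inner_radius": r_out - thickness,
                       "thickness": thickness}),
        ),
    )


def diagnosis_spore_wall_annulus(pixel_size_um: float = 0.1) -> SceneSpec:
    """Annulus fixture: 3.1-um wall on a 74-um spore outline."""
    thickness = 3.1
    r_out = 37.0
    r_in = r_out - thickness
    margin = 2.0
    side_um = 2 * (r_out + margin)
    n = int(math.ceil(side_um / pixel_size_um))
    c = n * pixel_size_um / 2.0
    return SceneSpec(
        width_px=n, height_px=n, pixel_size_um=pixel_size_um,
        structures=(Structure("annulus", "fungal",
                              {"cx": c, "cy": c, "inner_radius": r_in,
                               "thickness": thickness}),),
    )
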