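"""Synthetic two-instrument LIBS data generator.

Emulates the measurement setting the pipeline targets: three classes of
medicinal-plant samples (Mutong, Guan-mutong, Chuan-mutong) sharing one
atomic/molecular line list, measured by

* a low-resolution CCD fiber spectrometer (190-1100 nm, ~0.25 nm FWHM,
  sensitivity weighted toward the infrared), and
* a high-resolution echelle ICCD spectrometer (200-850 nm, ~0.015 nm FWHM,
  UV-weighted sensitivity with a periodic order-overlap "ripple").

Each spectrum is a sum of Gaussian emission lines multiplied by class- and
sample-dependent intensity factors and the instrument's spectral response,
plus additive and signal-proportional Gaussian noise. Class differences are
concentrated in three bands (CN 381-388 nm, weak metal lines 402-403 nm,
K I 766-770 nm), mirroring where discriminative wavelengths cluster in real
plant LIBS data. The generator also simulates standard-lamp measurements
(certified 350-1000 nm reference x response), which is what the correction
stage consumes, and can plant a minority of corrupted "outlier" spectra
(global intensity collapse or broadband baseline surge) flagged in metadata
for ground truth.

Line shapes are purely Gaussian and no plasma physics (Saha-Boltzmann,
self-absorption, matrix effects) is modeled: the quantities under test are
resolution/response transfer and the downstream statistics, not emission
physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .spectra import LabeledSpectrumSet, Spectrum

__all__ = [
    "SpectralLine",
    "LineList",
    "InstrumentModel",
    "ClassProfile",
    "default_line_list",
    "low_res_instrument",
    "high_res_instrument",
    "default_class_profiles",
    "lamp_reference",
    "render_spectrum",
    "simulate_dataset",
    "simulate_lamp",
    "EMPHASIZED_BANDS",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548

#: Wavelength bands (nm) where inter-class intensity differences concentrate.
EMPHASIZED_BANDS: dict[str, tuple[float, float]] = {
    "cn": (381.0, 388.5),
    "metal": (402.0, 403.2),
    "k": (766.0, 770.5),
}


@dataclass(frozen=True)
class SpectralLine:
    species: str
    wavelength_nm: float
    intensity: float  # base relative line strength (> 0)


@dataclass
class LineList:
    """Emission line table seeding both peak annotation and the simulator."""

    entries: list[SpectralLine]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.intensity <= 0:
                raise ValueError(f"line {e.species} {e.wavelength_nm}: intensity <= 0")

    def __len__(self) -> int:
        return len(self.entries)

    def wavelengths(self) -> np.ndarray:
        return np.array([e.wavelength_nm for e in self.entries])

    def intensities(self) -> np.ndarray:
        return np.array([e.intensity for e in self.entries])

    def species(self) -> list[str]:
        return [e.species for e in self.entries]

    def restrict(self, lo: float, hi: float) -> "LineList":
        return LineList([e for e in self.entries if lo <= e.wavelength_nm <= hi])

    def exclude_species(self, species: Sequence[str]) -> "LineList":
        drop = set(species)
        return LineList([e for e in self.entries if e.species not in drop])


# The 20 principal peak features (species, nm, base relative strength).
_PRINCIPAL_LINES = [
    ("C-N", 383.84, 2.0),
    ("C-N", 387.68, 1.6),
    ("Ca I", 392.35, 1.1),
    ("Ca II", 396.85, 1.8),
    ("Fe I", 402.96, 0.9),
    ("Ca I", 422.67, 1.5),
    ("Ca I", 429.89, 0.9),
    ("Ca I", 445.48, 0.8),
    ("Ca III", 455.33, 0.7),
    ("V I", 460.61, 0.7),
    ("C2", 517.90, 0.8),
    ("V I", 526.61, 0.7),
    ("Ca I", 558.19, 0.8),
    ("Na I", 588.99, 1.5),
    ("Ca I", 612.22, 0.9),
    ("Ca I", 616.22, 0.8),
    ("Ca I", 643.91, 0.9),
    ("Ca I", 646.26, 1.0),
    ("K I", 766.49, 3.0),
    ("K I", 769.90, 2.0),
]

# Weak fine structure: resolved by the echelle instrument, merged into band
# shoulders at low resolution (CN violet system rotational structure and weak
# metal lines flanking Fe I 402.96 / Ca II 396.85).
_SATELLITE_LINES = [
    ("C-N", 381.72, 0.18),
    ("C-N", 382.00, 0.18),
    ("C-N", 382.57, 0.15),
    ("C-N", 382.86, 0.20),
    ("C-N", 383.14, 0.22),
    ("Fe I", 402.41, 0.18),
    ("Fe I", 402.69, 0.22),
    ("Ca I", 395.90, 0.18),
]

# Ambient lines present in plant LIBS but excluded from feature selection
# (interference from atmospheric O2 / H2O).
_AMBIENT_LINES = [
    ("H", 656.28, 1.2),
    ("O", 777.19, 1.4),
]


def default_line_list(
    satellites: bool = True, ambient: bool = True
) -> LineList:
    """The bundled line table: 20 principal peaks (+ fine structure, + O/H)."""
    rows = list(_PRINCIPAL_LINES)
    if satellites:
        rows += _SATELLITE_LINES
    if ambient:
        rows += _AMBIENT_LINES
    rows.sort(key=lambda r: r[1])
    return LineList([SpectralLine(*r) for r in rows])


def principal_wavelengths() -> np.ndarray:
    """Wavelengths (nm) of the 20 principal peak features, ascending."""
    return np.array(sorted(wl for _, wl, _ in _PRINCIPAL_LINES))


@dataclass
class InstrumentModel:
    """Parametric spectrometer model.

    The spectral response is linear in wavelength between ``response_start``
    (at ``range_nm[0]``) and ``response_end`` (at ``range_nm[1]``), optionally
    multiplied by a sinusoidal ripple ``1 + amp*sin(2*pi*(lam-lo)/period)``
    mimicking echelle order overlap. ``shift_nm`` is a rigid wavelength
    registration offset of this instrument relative to truth. Noise is
    Gaussian with per-point sigma ``sqrt(sigma_add^2 + (sigma_prop*I)^2)``.
    """

    name: str
    range_nm: tuple[float, float]
    n_points: int
    fwhm_nm: float
    response_start: float = 1.0
    response_end: float = 1.0
    ripple_amp: float = 0.0
    ripple_period_nm: float = 8.0
    shift_nm: float = 0.0
    sigma_add: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.range_nm
        if not lo < hi:
            raise ValueError("range_nm must satisfy lo < hi")
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be > 0")
        if abs(self.ripple_amp) >= 1.0:
            raise ValueError("ripple amplitude must keep the response positive")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.range_nm[0], self.range_nm[1], self.n_points)

    def response(self, wavelengths: np.ndarray) -> np.ndarray:
        lo, hi = self.range_nm
        lam = np.asarray(wavelengths, dtype=float)
        r = self.response_start + (self.response_end - self.response_start) * (
            (lam - lo) / (hi - lo)
        )
        if self.ripple_amp:
            r = r * (
                1.0
                + self.ripple_amp
                * np.sin(2.0 * np.pi * (lam - lo) / self.ripple_period_nm)
            )
        if np.any(r <= 0):
            raise ValueError("response must be positive over the instrument range")
        return r

    def with_(self, **kwargs) -> "InstrumentModel":
        return replace(self, **kwargs)


def low_res_instrument(**overrides) -> InstrumentModel:
    """Default low-resolution CCD model: 190-1100 nm, 0.25 nm FWHM, IR-weighted."""
    base = InstrumentModel(
        name="L-R",
        range_nm=(190.0, 1100.0),
        n_points=4096,
        fwhm_nm=0.25,
        response_start=0.5,
        response_end=1.5,
        sigma_add=60.0,
        sigma_prop=0.02,
    )
    return replace(base, **overrides) if overrides else base


def high_res_instrument(shift_nm: float = 0.15, **overrides) -> InstrumentModel:
    """Default high-resolution echelle ICCD model: 200-850 nm, 0.015 nm FWHM,
    UV-weighted response with 15% ripple (8 nm period), registration shift."""
    base = InstrumentModel(
        name="H-R",
        range_nm=(200.0, 850.0),
        n_points=87000,
        fwhm_nm=0.018,
        response_start=1.5,
        response_end=0.4,
        ripple_amp=0.15,
        ripple_period_nm=8.0,
        shift_nm=shift_nm,
        sigma_add=6000.0,
        sigma_prop=0.02,
    )
    return replace(base, **overrides) if overrides else base


def draw_shift(rng: np.random.Generator, lo: float = 0.05, hi: float = 0.3) -> float:
    """Draw a registration offset with magnitude in [lo, hi] nm, random sign."""
    return float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))


@dataclass
class ClassProfile:
    """Per-class line-intensity statistics.

    A sample (slice) of this class multiplies each line's base strength by
    ``exp(offset + N(0, sigma_sample))`` where ``offset`` is the class's
    log-offset for the emphasized band containing the line (0 elsewhere);
    individual shots add a further ``exp(N(0, sigma_shot))`` jitter.
    """

    name: str
    band_offsets: dict[str, float] = field(default_factory=dict)
    sigma_sample: float = 0.15
    sigma_shot: float = 0.05

    def line_log_offsets(self, line_wavelengths: np.ndarray) -> np.ndarray:
        off = np.zeros(len(line_wavelengths))
        for band, delta in self.band_offsets.items():
            lo, hi = EMPHASIZED_BANDS[band]
            off[(line_wavelengths >= lo) & (line_wavelengths <= hi)] += delta
        return off


def default_class_profiles() -> list[ClassProfile]:
    """Three classes separated by a Latin square of +-0.3 log-offsets over the
    emphasized bands; lines outside those bands are class-neutral."""
    return [
        ClassProfile("Mutong", {"cn": +0.3, "metal": 0.0, "k": -0.3}),
        ClassProfile("Guan-mutong", {"cn": -0.3, "metal": +0.3, "k": 0.0}),
        ClassProfile("Chuan-mutong", {"cn": 0.0, "metal": -0.3, "k": +0.3}),
    ]


def lamp_reference(
    n_points: int = 651, range_nm: tuple[float, float] = (350.0, 1000.0)
) -> Spectrum:
    """Certified standard-lamp irradiance curve: a smooth quasi-blackbody
    (Planck, 3000 K) on 350-1000 nm, scaled to unit maximum. Only ratios
    against measured lamp spectra matter, so the absolute scale is arbitrary."""
    lam = np.linspace(range_nm[0], range_nm[1], n_points)
    x = 14_387_768.0 / (lam * 3000.0)  # hc / (lambda k T)
    irr = lam**-5 / np.expm1(x)
    irr = irr / irr.max()
    return Spectrum(lam, irr, instrument_id="reference", meta={"source": "lamp"})


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _line_basis(model: InstrumentModel, lines: LineList) -> tuple[np.ndarray, LineList]:
    """Unit-area Gaussian profile of each in-range line on the model grid.

    Lines outside the instrument range are silently dropped. Profiles are
    evaluated only within +-6 sigma of each (shifted) center for speed.
    """
    lo, hi = model.range_nm
    kept = lines.restrict(lo, hi)
    if len(kept) == 0:
        raise ValueError("no lines fall within the instrument range")
    grid = model.grid
    step = grid[1] - grid[0]
    sigma = model.fwhm_nm * FWHM_TO_SIGMA
    basis = np.zeros((len(kept), grid.size))
    half = max(int(np.ceil(6.0 * sigma / step)), 2)
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for i, line in enumerate(kept.entries):
        center = line.wavelength_nm + model.shift_nm
        j = int(round((center - grid[0]) / step))
        a, b = max(j - half, 0), min(j + half + 1, grid.size)
        if a >= b:
            continue
        basis[i, a:b] = norm * np.exp(-0.5 * ((grid[a:b] - center) / sigma) ** 2)
    return basis, kept


def _noise_sigma(model: InstrumentModel, signal: np.ndarray) -> np.ndarray:
    return np.sqrt(model.sigma_add**2 + (model.sigma_prop * np.abs(signal)) ** 2)


def render_spectrum(
    profile: ClassProfile,
    model: InstrumentModel,
    seed: int,
    line_list: LineList | None = None,
    source_scale: float = 5000.0,
    noise: bool = True,
) -> Spectrum:
    """Render one spectrum of a fresh sample of ``profile`` on ``model``.

    The trace is ``sum_l A_l * Gauss(lam - lam_l - shift; fwhm) * response(lam)``
    with ``A_l = source_scale * base_l * exp(offset_l + sample + shot jitter)``,
    plus noise when enabled. Deterministic for a fixed seed.
    """
    lines = line_list if line_list is not None else default_line_list()
    basis, kept = _line_basis(model, lines)
    rng = np.random.default_rng(seed)
    logf = kept.wavelengths()
    offsets = profile.line_log_offsets(logf)
    factors = np.exp(
        offsets
        + rng.normal(0.0, profile.sigma_sample, len(kept))
        + rng.normal(0.0, profile.sigma_shot, len(kept))
    )
    amps = source_scale * kept.intensities() * factors
    signal = (amps @ basis) * model.response(model.grid)
    if noise and (model.sigma_add > 0 or model.sigma_prop > 0):
        signal = signal + rng.normal(0.0, 1.0, signal.size) * _noise_sigma(
            model, signal
        )
    return Spectrum(
        model.grid,
        signal,
        instrument_id=model.name,
        meta={"class": profile.name, "seed": int(seed)},
    )


def simulate_dataset(
    profiles: Sequence[ClassProfile],
    model: InstrumentModel,
    n_per_class: int,
    outlier_fraction: float = 0.0,
    seed: int = 0,
    n_samples_per_class: int = 10,
    line_list: LineList | None = None,
    source_scale: float = 5000.0,
) -> LabeledSpectrumSet:
    """Generate a balanced labeled dataset on one instrument.

    Spectra are organized as ``n_samples_per_class`` samples (slices) per
    class, shots in acquisition order within each sample; sample-level line
    factors are shared by the shots of a sample. A fraction of spectra is
    corrupted — global intensity collapse by U(0.05, 0.2), or a broadband
    baseline surge — and flagged in ``meta['outlier']`` for ground truth.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not 0.0 <= outlier_fraction < 0.5:
        raise ValueError("outlier_fraction must be in [0, 0.5)")
    lines = line_list if line_list is not None else default_line_list()
    basis, kept = _line_basis(model, lines)
    rng = np.random.default_rng(seed)
    wl = kept.wavelengths()
    base = kept.intensities()

    n_total = n_per_class * len(profiles)
    amps = np.empty((n_total, len(kept)))
    labels: list[str] = []
    meta: list[dict] = []
    row = 0
    for profile in profiles:
        offsets = profile.line_log_offsets(wl)
        # distribute shots over samples as evenly as possible
        counts = np.full(n_samples_per_class, n_per_class // n_samples_per_class)
        counts[: n_per_class % n_samples_per_class] += 1
        for s_idx, count in enumerate(counts):
            sample_log = offsets + rng.normal(0.0, profile.sigma_sample, len(kept))
            for shot in range(int(count)):
                shot_log = sample_log + rng.normal(
                    0.0, profile.sigma_shot, len(kept)
                )
                amps[row] = source_scale * base * np.exp(shot_log)
                labels.append(profile.name)
                meta.append(
                    {
                        "sample": f"{profile.name}-{s_idx:02d}",
                        "shot": shot,
                        "outlier": False,
                    }
                )
                row += 1

    signal = amps @ basis
    signal *= model.response(model.grid)[None, :]

    # plant outliers before the noise pass: corruption affects the signal,
    # detector noise stays at its nominal level
    n_out = int(round(outlier_fraction * n_total))
    out_idx = rng.choice(n_total, size=n_out, replace=False) if n_out else np.array(
        [], dtype=int
    )
    grid = model.grid
    for i in out_idx:
        mode = rng.choice(["collapse", "surge"])
        if mode == "collapse":
            # a weak/defocused ablation shot: overall intensity collapses and
            # the plasma excitation balance deviates, scattering line ratios
            bad_amps = amps[i] * rng.lognormal(0.0, 0.6, amps.shape[1])
            signal[i] = (bad_amps @ basis) * model.response(grid)
            signal[i] *= rng.uniform(0.05, 0.2)
        else:
            span = grid[-1] - grid[0]
            center = rng.uniform(grid[0] + 0.2 * span, grid[-1] - 0.1 * span)
            width = rng.uniform(30.0, 100.0)
            amp = rng.uniform(1.0, 3.0) * signal[i].max()
            signal[i] += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
        meta[i]["outlier"] = True
        meta[i]["outlier_mode"] = str(mode)

    if model.sigma_add > 0 or model.sigma_prop > 0:
        # chunked to bound transient memory on dense high-res grids
        for a in range(0, n_total, 128):
            b = min(a + 128, n_total)
            block = signal[a:b]
            block += rng.normal(0.0, 1.0, block.shape) * _noise_sigma(model, block)

    return LabeledSpectrumSet(grid, signal, labels, model.name, meta)


def simulate_lamp(
    model: InstrumentModel,
    reference: Spectrum,
    noise_rel: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Measure the standard lamp with ``model``: reference x response (+ ripple)
    on the model grid restricted to the overlap with the lamp's certified range,
    plus optional small relative noise.

    The lamp is a smooth broadband source, so instrumental line broadening is
    negligible and the measurement is the response-weighted reference itself.
    """
    if np.any(reference.intensities <= 0):
        raise ValueError("lamp reference must be strictly positive")
    lo = max(model.range_nm[0], reference.wavelengths[0])
    hi = min(model.range_nm[1], reference.wavelengths[-1])
    if lo >= hi:
        raise ValueError(
            "instrument range and lamp certified range do not overlap"
        )
    grid = model.grid
    mask = (grid >= lo) & (grid <= hi)
    lam = grid[mask]
    ref = np.interp(lam, reference.wavelengths, reference.intensities)
    measured = ref * model.response(lam)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        measured = measured + rng.normal(0.0, noise_rel, lam.size) * measured
    return Spectrum(
        lam, measured, instrument_id=model.name, meta={"source": "lamp"}
    )
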