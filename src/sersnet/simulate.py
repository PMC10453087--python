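"""Synthetic SERS spectra of PAH mixtures on a plasmonic substrate.

Generates benzo(a)pyrene (BaP), naphthalene (Nap) and pyrene (Pyr) mixture
spectra with the statistical structure the downstream classification assumes:

* each analyte contributes Lorentzian bands at its characteristic
  wavenumbers (BaP 524/607/1231/1376, Nap 505/1372, Pyr 587/1233/1399 cm^-1);
* band amplitude follows a competitive-Langmuir adsorption response, so an
  analyte's signal saturates with its own concentration and is suppressed by
  co-adsorbing competitors (the "competitive adsorption" effect that makes
  mixture identification non-trivial);
* a broad fluorescence hump plus slight linear tilt models the flexible
  substrate's background;
* replicate-to-replicate variability is a multiplicative log-normal factor
  (substrate hot-spot variation) plus additive Gaussian shot noise,
  calibrated so 10-replicate peak-intensity RSD lands in the 7-10% band.

The default design is 4 mixture classes x 20 samples x 5 replicates
= 400 spectra, with per-analyte concentrations drawn from the standard
dilution ladder 10, 8, 5, 2.5, 1, 0.5, 0.1, 0.05 ug/mL.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .spectra import DEFAULT_GRID, RamanSpectrum, WavenumberGrid

__all__ = [
    "ANALYTES",
    "CLASSES",
    "CLASS_CONSTITUENTS",
    "AnalytePeakLibrary",
    "GeneratorConfig",
    "MixtureSample",
    "default_peak_libraries",
    "signal_amplitude",
    "generate_spectrum",
    "generate_dataset",
    "replicate_series",
    "strongest_peak",
    "config_hash",
]

ANALYTES = ("BaP", "Nap", "Pyr")

#: The four mixture classes; single-analyte classes are deliberately absent.
CLASSES = ("BaP+Pyr", "BaP+Nap", "Pyr+Nap", "BaP+Pyr+Nap")

CLASS_CONSTITUENTS: dict[str, tuple[str, ...]] = {
    "BaP+Pyr": ("BaP", "Pyr"),
    "BaP+Nap": ("BaP", "Nap"),
    "Pyr+Nap": ("Pyr", "Nap"),
    "BaP+Pyr+Nap": ("BaP", "Pyr", "Nap"),
}


@dataclass(frozen=True)
class AnalytePeakLibrary:
    """Characteristic bands of one analyte.

    ``peaks`` holds (center cm^-1, relative amplitude in (0, 1], FWHM cm^-1);
    ``scale`` multiplies all of the analyte's amplitudes (Nap's bands are
    weaker than BaP/Pyr's because its C-C modes are less polarisable).
    """

    name: str
    peaks: tuple[tuple[float, float, float], ...]
    scale: float = 1.0

    def __post_init__(self) -> None:
        for center, amp, fwhm in self.peaks:
            if not (300.0 <= center <= 1800.0):
                raise ValueError(f"{self.name}: peak center {center} outside 300-1800")
            if amp <= 0 or amp > 1:
                raise ValueError(f"{self.name}: relative amplitude must be in (0, 1]")
            if fwhm <= 0:
                raise ValueError(f"{self.name}: FWHM must be positive")

    @property
    def strongest_center(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]


def default_peak_libraries(fwhm: float = 10.0) -> dict[str, AnalytePeakLibrary]:
    """Band positions and relative intensities of the three PAHs."""
    return {
        "BaP": AnalytePeakLibrary(
            "BaP",
            ((524.0, 0.55, fwhm), (607.0, 1.0, fwhm),
             (1231.0, 0.5, fwhm), (1376.0, 0.65, fwhm)),
        ),
        "Nap": AnalytePeakLibrary(
            "Nap",
            ((505.0, 0.55, fwhm), (1372.0, 1.0, fwhm)),
            scale=0.6,
        ),
        "Pyr": AnalytePeakLibrary(
            "Pyr",
            ((587.0, 1.0, fwhm), (1233.0, 0.5, fwhm), (1399.0, 0.7, fwhm)),
        ),
    }


def strongest_peak(analyte: str, config: "GeneratorConfig | None" = None) -> float:
    """Wavenumber of the analyte's strongest characteristic band."""
    libs = (config or GeneratorConfig()).peak_libraries
    return libs[analyte].strongest_center


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-spectrum model.

    Defaults reproduce the study design: 4 classes x 20 samples x 5
    replicates, concentrations from the printed dilution ladder, saturation
    constant K = 1 ug/mL, equal pairwise competition strengths, and noise
    levels giving a sub-10% replicate RSD.
    """

    peak_libraries: dict[str, AnalytePeakLibrary] = field(
        default_factory=default_peak_libraries
    )
    concentration_ladder: tuple[float, ...] = (10.0, 8.0, 5.0, 2.5, 1.0, 0.5, 0.1, 0.05)
    saturation_k: float = 1.0  # ug/mL; half-saturation of the Langmuir response
    competition_strengths: dict[str, float] = field(
        default_factory=lambda: {a: 1.0 for a in ANALYTES}
    )
    baseline_amplitude: float = 0.1      # fluorescence hump, fraction of peak signal
    baseline_center: float = 1300.0      # cm^-1
    baseline_fwhm: float = 900.0         # cm^-1
    baseline_tilt: float = 0.02          # linear tilt, fraction of peak signal
    noise_sd: float = 0.01               # additive Gaussian, fraction of peak signal
    replicate_log_sd: float = 0.08       # log-scale sd of the multiplicative factor
    concentration_design: str = "shared" # "shared": constituents co-diluted per
                                         # sample; "independent": each drawn alone
    replicates_per_sample: int = 5
    samples_per_class: int = 20
    grid: WavenumberGrid = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.saturation_k <= 0:
            raise ValueError("saturation constant K must be positive")
        if self.concentration_design not in ("shared", "independent"):
            raise ValueError(
                "concentration_design must be 'shared' or 'independent'"
            )
        for name, value in (
            ("noise_sd", self.noise_sd),
            ("replicate_log_sd", self.replicate_log_sd),
            ("baseline_amplitude", self.baseline_amplitude),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peak_libraries"] = {
            k: {"peaks": list(map(list, v.peaks)), "scale": v.scale}
            for k, v in self.peak_libraries.items()
        }
        d["grid"] = {"start": self.grid.start, "stop": self.grid.stop,
                     "n_points": self.grid.n_points}
        return d


def config_hash(config: GeneratorConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class MixtureSample:
    """One physical sample: a mixture class, its per-analyte concentrations
    (ug/mL; zero for absent analytes) and the replicate spectra acquired on it."""

    sample_id: str
    label: str
    concentrations: dict[str, float]
    replicates: list[RamanSpectrum]

    def __post_init__(self) -> None:
        present = tuple(a for a in ANALYTES if self.concentrations.get(a, 0.0) > 0)
        expected = tuple(sorted(CLASS_CONSTITUENTS[self.label]))
        if tuple(sorted(present)) != expected:
            raise ValueError(
                f"{self.sample_id}: nonzero analytes {present} do not match "
                f"class {self.label}"
            )


# ---------------------------------------------------------------------------
# Signal model
# ---------------------------------------------------------------------------

def signal_amplitude(
    concentration: float, competitor_load: float, config: GeneratorConfig
) -> float:
    """Competitive-Langmuir amplitude factor in [0, 1).

    amp = c / (K + c + competitor_load), where ``competitor_load`` is the
    competition-weighted sum of co-adsorbing analyte concentrations. Zero
    concentration contributes nothing; the response saturates towards 1 and
    is strictly suppressed by competitors.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if competitor_load < 0:
        raise ValueError("competitor load must be >= 0")
    if concentration == 0:
        return 0.0
    return concentration / (config.saturation_k + concentration + competitor_load)


def _lorentzian(w: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    # Unit peak height; FWHM parameterisation.
    half = fwhm / 2.0
    return half**2 / ((w - center) ** 2 + half**2)


def _baseline(w: np.ndarray, config: GeneratorConfig, ref: float) -> np.ndarray:
    """Fluorescence hump plus linear tilt, scaled to ``ref`` (the spectrum's
    peak analyte signal): background on these substrates rides on the same
    enhancement as the analyte signal, so it tracks the signal scale."""
    if ref == 0 or (config.baseline_amplitude == 0 and config.baseline_tilt == 0):
        return np.zeros_like(w)
    hump = config.baseline_amplitude * np.exp(
        -4.0 * np.log(2.0) * ((w - config.baseline_center) / config.baseline_fwhm) ** 2
    )
    span = w[-1] - w[0]
    tilt = config.baseline_tilt * (w[-1] - w) / span
    return ref * (hump + tilt)


def _as_rng(rng_state: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def generate_spectrum(
    concentrations: Mapping[str, float],
    config: GeneratorConfig | None = None,
    rng_state: np.random.Generator | int | None = None,
) -> RamanSpectrum:
    """Simulate one SERS spectrum of the given mixture.

    intensity(v) = r * sum_analytes amp_a * sum_peaks relamp * L(v) +
    baseline(v) + noise(v), clipped at zero, where r is the per-spectrum
    log-normal replicate factor (median 1) and amp_a the competitive-Langmuir
    amplitude. Baseline amplitude and noise sd are fractions of the
    spectrum's peak analyte signal (r included): background and shot noise on
    a SERS substrate ride on the same plasmonic enhancement as the analyte
    bands, so both track the signal scale. A blank (all concentrations zero)
    is therefore exactly zero. Deterministic given ``rng_state``.
    """
    config = config or GeneratorConfig()
    rng = _as_rng(rng_state)
    for name in concentrations:
        if name not in config.peak_libraries:
            raise ValueError(f"unknown analyte: {name!r}")
        if concentrations[name] < 0:
            raise ValueError(f"negative concentration for {name}")

    w = config.grid.wavenumbers
    signal = np.zeros_like(w)
    for name, c in concentrations.items():
        load = sum(
            config.competition_strengths.get(other, 1.0) * concentrations.get(other, 0.0)
            for other in concentrations
            if other != name
        )
        amp = signal_amplitude(c, load, config)
        if amp == 0:
            continue
        lib = config.peak_libraries[name]
        for center, relamp, fwhm in lib.peaks:
            signal += amp * lib.scale * relamp * _lorentzian(w, center, fwhm)

    r = float(np.exp(rng.normal(0.0, config.replicate_log_sd))) \
        if config.replicate_log_sd > 0 else 1.0
    ref = float(r * signal.max()) if signal.size else 0.0
    noise = (
        rng.normal(0.0, config.noise_sd * ref, w.shape)
        if config.noise_sd > 0 and ref > 0
        else 0.0
    )
    intensities = np.clip(r * signal + _baseline(w, config, ref) + noise, 0.0, None)
    return RamanSpectrum(grid=config.grid, intensities=intensities)


def replicate_series(
    concentrations: Mapping[str, float],
    n: int,
    config: GeneratorConfig | None = None,
    rng_state: np.random.Generator | int | None = None,
) -> list[RamanSpectrum]:
    """n replicate acquisitions of one sample, differing only in the replicate
    factor and noise draws (used for the stability/RSD protocol)."""
    if n < 2:
        raise ValueError("a replicate series needs n >= 2")
    config = config or GeneratorConfig()
    rng = _as_rng(rng_state)
    out = []
    for i in range(n):
        s = generate_spectrum(concentrations, config, rng)
        s.replicate_id = f"r{i}"
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[list[MixtureSample], dict]:
    """The full labelled dataset plus its provenance manifest.

    For each class, ``samples_per_class`` samples at ``replicates_per_sample``
    spectra each; defaults give 400 spectra, 100 per class. Under the default
    ``shared`` design each sample is one co-diluted mixture: all constituents
    sit at the sample's dilution level, and the levels cycle through the
    ladder so every class covers the full 10-0.05 ug/mL range. The
    ``independent`` design instead draws each constituent's concentration
    separately (with replacement, seeded) from the ladder.
    """
    config = config or GeneratorConfig()
    if not config.concentration_ladder:
        raise ValueError("concentration ladder must be non-empty")
    if config.samples_per_class < 1 or config.replicates_per_sample < 1:
        raise ValueError("samples_per_class and replicates_per_sample must be >= 1")

    rng = np.random.default_rng(config.seed)
    ladder = np.asarray(config.concentration_ladder, dtype=float)
    samples: list[MixtureSample] = []
    for label in CLASSES:
        constituents = CLASS_CONSTITUENTS[label]
        for i in range(config.samples_per_class):
            conc = {a: 0.0 for a in ANALYTES}
            if config.concentration_design == "shared":
                level = float(ladder[i % len(ladder)])
                for a in constituents:
                    conc[a] = level
            else:
                for a in constituents:
                    conc[a] = float(rng.choice(ladder))
            sample_id = f"{label}_s{i:02d}"
            reps = []
            for j in range(config.replicates_per_sample):
                s = generate_spectrum(conc, config, rng)
                s.label = label
                s.sample_id = sample_id
                s.replicate_id = f"r{j}"
                reps.append(s)
            samples.append(MixtureSample(sample_id, label, conc, reps))

    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "classes": list(CLASSES),
        "samples_per_class": config.samples_per_class,
        "replicates_per_sample": config.replicates_per_sample,
        "n_spectra": sum(len(s.replicates) for s in samples),
        "config": config.to_dict(),
    }
    return samples, manifest


def flatten_spectra(samples: Sequence[MixtureSample]) -> list[RamanSpectrum]:
    """All replicate spectra of a dataset in deterministic order."""
    return [rep for s in samples for rep in s.replicates]
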