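"""Synthetic serum population generator.

Draws lipoprotein subclass concentrations from a correlated log-normal
mixture (a base stratum and a hypertriglyceridemic stratum), derives exact
ground-truth analyte values (TC, TG, HDL-C, apoB), and renders the lipid
methyl/methylene region of each sample's 1H-NMR spectrum as a sum of
Lorentzian lines plus nuisance signals (lactate, alanine, branched-chain
amino acids), a polynomial baseline, and Gaussian noise.

The model is deliberately simple: nine subclasses (3 per lipoprotein class,
large to small) with size-graded line positions. Concentrations are the only
source of analyte information; every truth is an exact linear functional of
the concentration vector, which makes closed-form oracles possible for all
downstream calibration machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from .spectra import Spectrum

__all__ = [
    "SUBCLASS_NAMES",
    "SubclassProfile",
    "NuisanceSignal",
    "PopulationConfig",
    "SyntheticSample",
    "ConfigError",
    "compute_true_analytes",
    "sample_population",
    "render_spectrum",
    "add_interferent",
    "lorentzian",
]

logger = logging.getLogger(__name__)

#: Canonical subclass order: large->small VLDL, LDL, HDL.
SUBCLASS_NAMES = ("V1", "V2", "V3", "L1", "L2", "L3", "H1", "H2", "H3")

_MAX_REJECTION_TRIES = 10_000


class ConfigError(ValueError):
    """Invalid population configuration."""


@dataclass(frozen=True)
class SubclassProfile:
    """Spectral signature and lipid composition of one lipoprotein subclass.

    ``chol_coeff``/``tg_coeff``/``apob_coeff`` are mg/dL of analyte carried
    per concentration unit; ``ch3_amp``/``ch2_amp`` are signal height per
    mg/dL of total lipid (chol + tg) carried. ``linewidth`` is the Lorentzian
    half-width at half-maximum in ppm.
    """

    name: str
    ch3_center: float
    ch2_center: float
    linewidth: float
    chol_coeff: float
    tg_coeff: float
    apob_coeff: float
    ch3_amp: float
    ch2_amp: float

    def __post_init__(self) -> None:
        if self.name not in SUBCLASS_NAMES:
            raise ConfigError(f"unknown subclass name {self.name!r}")
        for attr in ("chol_coeff", "tg_coeff", "apob_coeff", "ch3_amp", "ch2_amp"):
            if getattr(self, attr) < 0:
                raise ConfigError(f"{self.name}: {attr} must be >= 0")
        if not self.ch3_center < self.ch2_center:
            raise ConfigError(f"{self.name}: ch3_center must be < ch2_center")
        if self.linewidth <= 0:
            raise ConfigError(f"{self.name}: linewidth must be > 0")
        is_hdl = self.name.startswith("H")
        if is_hdl != (self.apob_coeff == 0):
            raise ConfigError(
                f"{self.name}: apob_coeff must be 0 exactly for HDL subclasses"
            )


@dataclass(frozen=True)
class NuisanceSignal:
    """A sharp non-lipoprotein multiplet with randomized per-sample amplitude."""

    name: str
    centers: tuple[float, ...]
    amplitude: float
    amp_log_sd: float
    width: float

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.amp_log_sd < 0 or self.width <= 0:
            raise ConfigError(f"nuisance {self.name!r}: invalid parameters")


@dataclass(frozen=True)
class PopulationConfig:
    """Everything needed to sample and render a synthetic population."""

    profiles: tuple[SubclassProfile, ...]
    log_mean: np.ndarray           # base-stratum log-medians, canonical order
    log_sd: np.ndarray
    correlation: np.ndarray        # 9x9, symmetric positive-definite
    hyper_log_shift: np.ndarray    # added to log_mean in the high-TG stratum
    stratum_fraction: float = 0.15
    tg_threshold: float = 250.0
    nuisance: tuple[NuisanceSignal, ...] = ()
    baseline_coeffs: tuple[float, ...] = (0.0,)
    noise_sd: float = 0.005
    ppm_jitter_sd: float = 0.002
    seed: int = 42
    grid_ppm_max: float = 1.66
    grid_ppm_min: float = 0.44
    grid_points: int = 4096
    _chol: np.ndarray = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if tuple(p.name for p in self.profiles) != SUBCLASS_NAMES:
            raise ConfigError("profiles must cover all 9 subclasses in canonical order")
        for name, arr in (
            ("log_mean", self.log_mean),
            ("log_sd", self.log_sd),
            ("hyper_log_shift", self.hyper_log_shift),
        ):
            a = np.asarray(arr, dtype=float)
            if a.shape != (9,):
                raise ConfigError(f"{name} must have 9 entries")
            object.__setattr__(self, name, a)
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (9, 9) or not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigError("correlation must be a symmetric 9x9 matrix")
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigError("correlation matrix is not positive-definite") from exc
        object.__setattr__(self, "correlation", corr)
        object.__setattr__(self, "_chol", chol)
        if np.any(self.log_sd < 0):
            raise ConfigError("log_sd entries must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.ppm_jitter_sd < 0:
            raise ConfigError("ppm_jitter_sd must be >= 0")
        if not 0.0 <= self.stratum_fraction <= 1.0:
            raise ConfigError("stratum_fraction must lie in [0, 1]")
        if self.grid_points < 2 or self.grid_ppm_max <= self.grid_ppm_min:
            raise ConfigError("invalid render grid")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dict(cls, raw: dict) -> "PopulationConfig":
        try:
            profiles = tuple(
                SubclassProfile(name=name, **raw["subclasses"][name])
                for name in SUBCLASS_NAMES
            )
            pop = raw["population"]
            median = np.array([pop["median"][n] for n in SUBCLASS_NAMES], dtype=float)
            if np.any(median <= 0):
                raise ConfigError("subclass medians must be > 0")
            log_sd = np.array([pop["log_sd"][n] for n in SUBCLASS_NAMES], dtype=float)
            factor = np.array(
                [pop.get("hyper_median_factor", {}).get(n, 1.0) for n in SUBCLASS_NAMES],
                dtype=float,
            )
            if np.any(factor <= 0):
                raise ConfigError("hyper_median_factor entries must be > 0")
            nuisance = tuple(
                NuisanceSignal(
                    name=item["name"],
                    centers=tuple(item["centers"]),
                    amplitude=float(item["amplitude"]),
                    amp_log_sd=float(item["amp_log_sd"]),
                    width=float(item["width"]),
                )
                for item in raw.get("nuisance", [])
            )
            grid = raw.get("render_grid", {})
            return cls(
                profiles=profiles,
                log_mean=np.log(median),
                log_sd=log_sd,
                correlation=np.asarray(pop["correlation"], dtype=float),
                hyper_log_shift=np.log(factor),
                stratum_fraction=float(raw.get("stratum_fraction", 0.15)),
                tg_threshold=float(raw.get("tg_threshold", 250.0)),
                nuisance=nuisance,
                baseline_coeffs=tuple(raw.get("baseline_coeffs", [0.0])),
                noise_sd=float(raw.get("noise_sd", 0.005)),
                ppm_jitter_sd=float(raw.get("ppm_jitter_sd", 0.002)),
                seed=int(raw.get("seed", 42)),
                grid_ppm_max=float(grid.get("ppm_max", 1.66)),
                grid_ppm_min=float(grid.get("ppm_min", 0.44)),
                grid_points=int(grid.get("n_points", 4096)),
            )
        except KeyError as exc:
            raise ConfigError(f"missing config key: {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        with open(str(path), encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls, seed: int | None = None) -> "PopulationConfig":
        """The packaged default population; optionally override the seed."""
        text = (
            resources.files("nmrelp").joinpath("data/default_population.yaml")
            .read_text(encoding="utf-8")
        )
        cfg = cls.from_dict(yaml.safe_load(text))
        if seed is not None:
            cfg = replace(cfg, seed=int(seed))
        return cfg


@dataclass
class SyntheticSample:
    """One synthetic serum sample: concentrations, exact truths, lazy spectrum."""

    concentrations: np.ndarray
    true_tc: float
    true_tg: float
    true_hdl_c: float
    true_apob: float
    sample_id: str = ""
    in_hyper_stratum: bool = False
    config: PopulationConfig | None = None
    render_seed: int | None = None
    _spectrum: Spectrum | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.shape != (9,) or np.any(c < 0):
            raise ValueError("concentrations must be 9 nonnegative values")
        self.concentrations = c
        for t in (self.true_tc, self.true_tg, self.true_hdl_c, self.true_apob):
            if t < 0:
                raise ValueError("true analyte values must be >= 0")
        if self.true_hdl_c > self.true_tc + 1e-9:
            raise ValueError("true_hdl_c cannot exceed true_tc")

    @property
    def spectrum(self) -> Spectrum:
        """Rendered spectrum (cached; deterministic given the render seed)."""
        if self._spectrum is None:
            if self.config is None:
                raise ValueError("sample has no config attached; cannot render")
            self._spectrum = render_spectrum(self, self.config)
        return self._spectrum


# ---------------------------------------------------------------------------
# Truths
# ---------------------------------------------------------------------------

def compute_true_analytes(
    concentrations, profiles
) -> tuple[float, float, float, float]:
    """Exact analyte truths (tc, tg, hdl_c, apob) from subclass concentrations.

    tc = sum c_s * chol_coeff_s over all subclasses; hdl_c restricts the sum
    to HDL subclasses; apob to VLDL+LDL.
    """
    c = np.asarray(concentrations, dtype=float)
    if c.shape != (9,):
        raise ValueError("expected 9 subclass concentrations")
    if np.any(c < 0):
        raise ValueError("concentrations must be nonnegative")
    profiles = tuple(profiles)
    if tuple(p.name for p in profiles) != SUBCLASS_NAMES:
        raise ValueError("profiles must cover all 9 subclasses in canonical order")
    chol = np.array([p.chol_coeff for p in profiles])
    tg = np.array([p.tg_coeff for p in profiles])
    apob = np.array([p.apob_coeff for p in profiles])
    is_hdl = np.array([p.name.startswith("H") for p in profiles])
    return (
        float(c @ chol),
        float(c @ tg),
        float(c[is_hdl] @ chol[is_hdl]),
        float(c[~is_hdl] @ apob[~is_hdl]),
    )


# ---------------------------------------------------------------------------
# Population sampling
# ---------------------------------------------------------------------------

def sample_population(n: int, config: PopulationConfig) -> list[SyntheticSample]:
    """Draw ``n`` samples; spectra are rendered lazily on first access.

    Each sample is a correlated log-normal draw from either the base stratum
    (conditioned on TG < threshold) or, with probability ``stratum_fraction``,
    the hypertriglyceridemic stratum (conditioned on TG >= threshold), so the
    high-TG fraction is exactly Binomial(n, stratum_fraction). Deterministic
    under a fixed config seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    tg_coeffs = np.array([p.tg_coeff for p in config.profiles])
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(n)
    samples: list[SyntheticSample] = []
    for i, child in enumerate(children):
        draw_ss, render_ss = child.spawn(2)
        rng = np.random.default_rng(draw_ss)
        hyper = bool(rng.random() < config.stratum_fraction)
        mu = config.log_mean + (config.hyper_log_shift if hyper else 0.0)
        conc = None
        for _ in range(_MAX_REJECTION_TRIES):
            z = config._chol @ rng.standard_normal(9)
            cand = np.exp(mu + config.log_sd * z)
            tg = float(cand @ tg_coeffs)
            if (tg >= config.tg_threshold) == hyper:
                conc = cand
                break
        if conc is None:
            raise ConfigError(
                "rejection sampling failed: the "
                f"{'high' if hyper else 'base'}-TG stratum places almost no mass "
                f"on its side of TG {'>=' if hyper else '<'} {config.tg_threshold}"
            )
        tc, tg, hdl, apob = compute_true_analytes(conc, config.profiles)
        samples.append(
            SyntheticSample(
                concentrations=conc,
                true_tc=tc,
                true_tg=tg,
                true_hdl_c=hdl,
                true_apob=apob,
                sample_id=f"syn{i:05d}",
                in_hyper_stratum=hyper,
                config=config,
                render_seed=int(render_ss.generate_state(1)[0] % (2**31)),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def lorentzian(ppm: np.ndarray, center: float, height: float, hwhm: float) -> np.ndarray:
    """Lorentzian line of peak ``height`` and half-width ``hwhm`` (ppm).

    Integrated area is pi * height * hwhm.
    """
    return height * hwhm**2 / ((ppm - center) ** 2 + hwhm**2)


def _render_grid(config: PopulationConfig) -> np.ndarray:
    return np.linspace(config.grid_ppm_max, config.grid_ppm_min, config.grid_points)


def render_spectrum(sample: SyntheticSample, config: PopulationConfig) -> Spectrum:
    """Render one sample's lipid-region spectrum.

    signal = subclass CH3/CH2 Lorentzians (height = concentration * amp *
    (chol_coeff + tg_coeff), centers jittered N(0, ppm_jitter_sd)) + nuisance
    multiplets with log-normal amplitudes + baseline polynomial + Gaussian
    noise with SD = noise_sd * median rendered line height.
    """
    ppm = _render_grid(config)
    rng = np.random.default_rng(
        sample.render_seed if sample.render_seed is not None else config.seed
    )
    signal = np.zeros_like(ppm)
    heights: list[float] = []
    for c_s, prof in zip(sample.concentrations, config.profiles):
        lipid = c_s * (prof.chol_coeff + prof.tg_coeff)
        for center, amp in ((prof.ch3_center, prof.ch3_amp), (prof.ch2_center, prof.ch2_amp)):
            jitter = rng.normal(0.0, config.ppm_jitter_sd) if config.ppm_jitter_sd > 0 else 0.0
            height = lipid * amp
            if height > 0:
                signal += lorentzian(ppm, center + jitter, height, prof.linewidth)
                heights.append(height)
    for nu in config.nuisance:
        amp = nu.amplitude * float(np.exp(rng.normal(0.0, nu.amp_log_sd)))
        for center in nu.centers:
            jitter = rng.normal(0.0, config.ppm_jitter_sd) if config.ppm_jitter_sd > 0 else 0.0
            if amp > 0:
                signal += lorentzian(ppm, center + jitter, amp, nu.width)
                heights.append(amp)
    baseline = np.polynomial.polynomial.polyval(ppm, config.baseline_coeffs)
    intensities = signal + baseline
    if config.noise_sd > 0 and heights:
        sd = config.noise_sd * float(np.median(heights))
        intensities = intensities + rng.normal(0.0, sd, size=ppm.size)
    return Spectrum(
        ppm_axis=ppm,
        intensities=intensities,
        sample_id=sample.sample_id,
        tube_type="synthetic",
    )


def add_interferent(
    spectrum: Spectrum, center: float, amplitude: float, width: float
) -> Spectrum:
    """Return a copy of ``spectrum`` with one extra Lorentzian line added."""
    if width <= 0:
        raise ValueError("interferent width must be > 0")
    return Spectrum(
        ppm_axis=spectrum.ppm_axis.copy(),
        intensities=spectrum.intensities
        + lorentzian(spectrum.ppm_axis, center, amplitude, width),
        sample_id=spectrum.sample_id,
        tube_type=spectrum.tube_type,
    )
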