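"""Spectrum data model, file I/O, and extraction of the lipid analysis region.

The assay operates on the lipid methyl/methylene region of serum 1H-NMR
spectra: 0.494-1.592 ppm sampled at 1600 points. Spectra are stored in the
NMR display convention (descending ppm); ascending files are normalized on
read. No apodization, phasing, baseline correction, or intensity
normalization is applied here -- the region extractor is a deterministic
linear resampler and nothing more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "REGION_MAX_PPM",
    "REGION_MIN_PPM",
    "REGION_POINTS",
    "CANONICAL_GRID",
    "TUBE_TYPES",
    "Spectrum",
    "FeatureVector",
    "SpectrumParseError",
    "RegionCoverageError",
    "read_spectrum",
    "write_spectrum",
    "extract_region",
]

#: Analysis region bounds (ppm) and point count of the canonical grid.
REGION_MAX_PPM = 1.592
REGION_MIN_PPM = 0.494
REGION_POINTS = 1600

#: Canonical descending grid: index 0 is 1.592 ppm, index 1599 is 0.494 ppm,
#: spacing (1.592 - 0.494)/1599. Endpoints inclusive.
CANONICAL_GRID = np.linspace(REGION_MAX_PPM, REGION_MIN_PPM, REGION_POINTS)

TUBE_TYPES = frozenset(
    {"greiner_serum", "plain_serum", "edta_plasma", "heparin_plasma", "synthetic"}
)

_SPACING_RTOL = 1e-9


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed into a valid Spectrum."""


class RegionCoverageError(ValueError):
    """Raised when a spectrum does not cover the full analysis region."""


@dataclass
class Spectrum:
    """A 1D NMR trace: uniformly spaced descending ppm axis plus intensities.

    Parameters
    ----------
    ppm_axis : ndarray
        Chemical shift values in ppm, strictly descending, uniform spacing.
    intensities : ndarray
        One intensity per ppm point, arbitrary instrument units, all finite.
    sample_id : str
        Free-text identifier.
    tube_type : str
        One of ``TUBE_TYPES``.
    """

    ppm_axis: np.ndarray
    intensities: np.ndarray
    sample_id: str = ""
    tube_type: str = "synthetic"

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm_axis, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if ppm.ndim != 1 or inten.ndim != 1:
            raise ValueError("ppm_axis and intensities must be 1-D")
        if ppm.size != inten.size:
            raise ValueError(
                f"length mismatch: {ppm.size} ppm points vs {inten.size} intensities"
            )
        if ppm.size < 2:
            raise ValueError("a Spectrum needs at least 2 points")
        if not np.all(np.isfinite(ppm)):
            raise ValueError("non-finite ppm values")
        if not np.all(np.isfinite(inten)):
            raise ValueError("non-finite intensity values")
        diffs = np.diff(ppm)
        if np.any(diffs >= 0):
            if np.all(diffs > 0):  # ascending input: normalize to descending
                ppm = ppm[::-1].copy()
                inten = inten[::-1].copy()
                diffs = np.diff(ppm)
            else:
                raise ValueError("ppm axis is not strictly monotone")
        step = diffs[0]
        if not np.allclose(diffs, step, rtol=_SPACING_RTOL, atol=0.0):
            raise ValueError("ppm spacing is not uniform within tolerance")
        if self.tube_type not in TUBE_TYPES:
            raise ValueError(f"unknown tube_type {self.tube_type!r}")
        self.ppm_axis = ppm
        self.intensities = inten

    @property
    def n_points(self) -> int:
        return int(self.ppm_axis.size)

    @property
    def ppm_step(self) -> float:
        """Absolute ppm spacing between adjacent points."""
        return float(self.ppm_axis[0] - self.ppm_axis[1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.tube_type == other.tube_type
            and np.array_equal(self.ppm_axis, other.ppm_axis)
            and np.array_equal(self.intensities, other.intensities)
        )

    def allclose(self, other: "Spectrum", rtol: float = 1e-12) -> bool:
        return (
            self.sample_id == other.sample_id
            and self.tube_type == other.tube_type
            and np.allclose(self.ppm_axis, other.ppm_axis, rtol=rtol, atol=0)
            and np.allclose(self.intensities, other.intensities, rtol=rtol, atol=1e-300)
        )


@dataclass
class FeatureVector:
    """The 1600-point analysis-region row fed to every PLS model."""

    values: np.ndarray
    grid: np.ndarray = field(default_factory=lambda: CANONICAL_GRID.copy())

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (REGION_POINTS,):
            raise ValueError(f"FeatureVector needs exactly {REGION_POINTS} values")
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite feature values")
        grid = np.asarray(self.grid, dtype=float)
        if grid.shape != (REGION_POINTS,) or not np.allclose(
            grid, CANONICAL_GRID, rtol=0, atol=1e-12
        ):
            raise ValueError("FeatureVector grid must be the canonical grid")
        self.values = vals
        self.grid = grid

    def to_spectrum(self, sample_id: str = "", tube_type: str = "synthetic") -> Spectrum:
        """Reconstruct a Spectrum living exactly on the canonical grid."""
        return Spectrum(
            ppm_axis=self.grid.copy(),
            intensities=self.values.copy(),
            sample_id=sample_id,
            tube_type=tube_type,
        )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_spectrum(path, format: str = "csv", sample_id: str | None = None,
                  tube_type: str = "synthetic") -> Spectrum:
    """Read a spectrum from disk.

    CSV dialect: header ``ppm,intensity``, '.' decimal point, UTF-8,
    '#'-prefixed comment lines. JCAMP-DX is read-only and limited to
    uncompressed (AFFN) ``##XYDATA=(X++(Y..Y))`` tables.
    """
    path = str(path)
    if format == "csv":
        ppm, inten = _read_csv(path)
    elif format == "jcamp":
        ppm, inten = _read_jcamp(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    sid = sample_id if sample_id is not None else _stem(path)
    try:
        return Spectrum(ppm, inten, sample_id=sid, tube_type=tube_type)
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc


def _stem(path: str) -> str:
    import os

    return os.path.splitext(os.path.basename(path))[0]


def _read_csv(path: str) -> tuple[np.ndarray, np.ndarray]:
    ppm: list[float] = []
    inten: list[float] = []
    header_seen = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                cols = [c.strip().lower() for c in line.split(",")]
                if cols[:2] != ["ppm", "intensity"]:
                    raise SpectrumParseError(
                        f"{path}: line {lineno}: expected header 'ppm,intensity', "
                        f"got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) < 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                ppm.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric cell in {line!r}"
                ) from None
    if not header_seen:
        raise SpectrumParseError(f"{path}: missing 'ppm,intensity' header")
    if len(ppm) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    return np.asarray(ppm), np.asarray(inten)


def _read_jcamp(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX reader: AFFN (X++(Y..Y)) XYDATA tables only."""
    firstx = lastx = xfactor = yfactor = None
    npoints = None
    ys: list[float] = []
    in_table = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                if in_table and line.upper().startswith("##END"):
                    in_table = False
                    break
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key == "FIRSTX":
                    firstx = float(value)
                elif key == "LASTX":
                    lastx = float(value)
                elif key == "XFACTOR":
                    xfactor = float(value)
                elif key == "YFACTOR":
                    yfactor = float(value)
                elif key == "NPOINTS":
                    npoints = int(float(value))
                elif key == "XYDATA":
                    if "X++(Y..Y)" not in value.replace(" ", ""):
                        raise SpectrumParseError(
                            f"{path}: line {lineno}: unsupported XYDATA form {value!r}"
                        )
                    in_table = True
                continue
            if in_table:
                tokens = line.replace(",", " ").split()
                try:
                    vals = [float(t) for t in tokens]
                except ValueError:
                    raise SpectrumParseError(
                        f"{path}: line {lineno}: non-numeric JCAMP data in {line!r}"
                    ) from None
                ys.extend(vals[1:])  # first token is the line's X value
    if firstx is None or lastx is None or npoints is None:
        raise SpectrumParseError(f"{path}: missing FIRSTX/LASTX/NPOINTS records")
    if len(ys) != npoints:
        raise SpectrumParseError(
            f"{path}: NPOINTS={npoints} but {len(ys)} Y values found"
        )
    xfactor = 1.0 if xfactor is None else xfactor
    yfactor = 1.0 if yfactor is None else yfactor
    ppm = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    inten = np.asarray(ys) * yfactor
    return ppm, inten


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write a Spectrum as CSV re-readable by :func:`read_spectrum`.

    Full float precision (repr) is used so the round trip is lossless to
    within 1e-12 relative tolerance.
    """
    with open(str(path), "w", encoding="utf-8") as fh:
        fh.write(f"# sample_id: {spectrum.sample_id}\n")
        fh.write(f"# tube_type: {spectrum.tube_type}\n")
        fh.write("ppm,intensity\n")
        for p, v in zip(spectrum.ppm_axis, spectrum.intensities):
            fh.write(f"{float(p)!r},{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def extract_region(spectrum: Spectrum) -> FeatureVector:
    """Resample the analysis region onto the canonical 1600-point grid.

    Linear interpolation of the input trace; when the input already lies on
    the canonical grid the values are copied verbatim (no interpolation
    error). The spectrum must cover [0.494, 1.592] ppm entirely.
    """
    ppm = spectrum.ppm_axis
    hi, lo = float(ppm[0]), float(ppm[-1])
    tol = 1e-12
    if hi < REGION_MAX_PPM - tol or lo > REGION_MIN_PPM + tol:
        missing = []
        if lo > REGION_MIN_PPM + tol:
            missing.append(f"low end short by {lo - REGION_MIN_PPM:.4f} ppm")
        if hi < REGION_MAX_PPM - tol:
            missing.append(f"high end short by {REGION_MAX_PPM - hi:.4f} ppm")
        raise RegionCoverageError(
            f"spectrum [{lo:.4f}, {hi:.4f}] ppm does not cover "
            f"[{REGION_MIN_PPM}, {REGION_MAX_PPM}] ppm ({'; '.join(missing)})"
        )
    if spectrum.n_points == REGION_POINTS and np.allclose(
        ppm, CANONICAL_GRID, rtol=0, atol=1e-12
    ):
        return FeatureVector(spectrum.intensities.copy())
    # np.interp needs ascending x
    vals = np.interp(CANONICAL_GRID[::-1], ppm[::-1], spectrum.intensities[::-1])
    return FeatureVector(vals[::-1].copy())
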