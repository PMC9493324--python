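"""Spectral domain types and operations.

Holds the in-memory model of instrument traces (fluorescence emission,
FTIR absorbance, CD signal), titration series built from them, and the
operations that reduce spectra to the scalars the binding analysis
consumes: peak extraction, peak-shift classification, Stern-Volmer
quench-ratio tabulation, and molar-ellipticity conversion for CD data.

All spectra are plain (axis, signal) pairs on a strictly increasing
grid.  Wavelength axes are in nm, wavenumber axes in cm^-1.  Long-format
CSV I/O is provided so titration bundles round-trip losslessly.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AxisKind",
    "Spectrum",
    "TitrationSeries",
    "PeakInfo",
    "ShiftCall",
    "ShiftDirection",
    "CDRecord",
    "find_peak",
    "classify_shift",
    "quench_ratios",
    "molar_ellipticity",
    "read_spectra_csv",
    "write_spectra_csv",
]

SPECTRA_CSV_COLUMNS = [
    "sample_id",
    "temperature_K",
    "quencher_conc_M",
    "axis_kind",
    "axis_value",
    "signal",
]


class AxisKind(str, enum.Enum):
    """Physical meaning of the spectral x-axis."""

    WAVELENGTH_NM = "wavelength_nm"
    WAVENUMBER_CM = "wavenumber_cm-1"


class SignalKind(str, enum.Enum):
    """What the y-axis records; fluorescence must be non-negative."""

    FLUORESCENCE = "fluorescence"
    ABSORBANCE = "absorbance"
    CD_DEGREES = "cd_degrees"


@dataclass(frozen=True)
class Spectrum:
    """One instrument trace: a signal sampled on a strictly increasing grid.

    Parameters
    ----------
    axis_kind
        Whether the grid is wavelength (nm) or wavenumber (cm^-1).
    axis
        Strictly increasing grid, length >= 3.
    signal
        Signal values, same length as ``axis``; fluorescence intensities
        (a.u.) must be non-negative, CD signals in degrees may be negative.
    temperature
        Sample temperature in kelvin.
    sample_id
        Free-text sample label.
    excitation_nm
        Excitation wavelength for fluorescence spectra, if any.
    signal_kind
        Declares the y-axis quantity so validation can be unit-aware.
    """

    axis_kind: AxisKind
    axis: np.ndarray
    signal: np.ndarray
    temperature: float
    sample_id: str = ""
    excitation_nm: float | None = None
    signal_kind: SignalKind = SignalKind.FLUORESCENCE

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        signal = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "axis_kind", AxisKind(self.axis_kind))
        object.__setattr__(self, "signal_kind", SignalKind(self.signal_kind))
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "signal", signal)
        if axis.ndim != 1 or signal.ndim != 1:
            raise ValueError("axis and signal must be one-dimensional")
        if axis.size != signal.size:
            raise ValueError("axis and signal must have equal length")
        if axis.size < 3:
            raise ValueError("a spectrum needs at least 3 points")
        if not np.all(np.diff(axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if not np.all(np.isfinite(axis)) or not np.all(np.isfinite(signal)):
            raise ValueError("axis and signal must be finite")
        if self.signal_kind is SignalKind.FLUORESCENCE and np.any(signal < 0):
            raise ValueError("fluorescence intensities must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive kelvin")

    def __len__(self) -> int:
        return int(self.axis.size)


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered spectra at one temperature across quencher concentrations.

    Exactly one spectrum must have ``quencher_conc == 0``: the unquenched
    F0 reference.  All spectra share one axis grid and one temperature.
    """

    spectra: tuple[Spectrum, ...]
    quencher_conc: np.ndarray  # mol/L, aligned with spectra

    def __post_init__(self) -> None:
        spectra = tuple(self.spectra)
        conc = np.asarray(self.quencher_conc, dtype=float)
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "quencher_conc", conc)
        if len(spectra) != conc.size:
            raise ValueError("one concentration per spectrum required")
        if len(spectra) == 0:
            raise ValueError("empty titration series")
        if not np.all(np.diff(conc) > 0):
            raise ValueError("concentrations must be strictly increasing and unique")
        if np.count_nonzero(conc == 0.0) != 1:
            raise ValueError("no F0 reference: exactly one quencher_conc == 0 required")
        ref = spectra[0]
        for s in spectra[1:]:
            if not np.array_equal(s.axis, ref.axis):
                raise ValueError("all spectra in a series must share one axis grid")
            if s.temperature != ref.temperature:
                raise ValueError("all spectra in a series must share one temperature")
            if s.axis_kind is not ref.axis_kind:
                raise ValueError("all spectra in a series must share one axis kind")

    @property
    def temperature(self) -> float:
        return self.spectra[0].temperature

    @property
    def sample_id(self) -> str:
        return self.spectra[0].sample_id

    @property
    def reference(self) -> Spectrum:
        """The zero-quencher (F0) spectrum."""
        idx = int(np.flatnonzero(self.quencher_conc == 0.0)[0])
        return self.spectra[idx]


class PeakMethod(str, enum.Enum):
    ARGMAX = "argmax"
    PARABOLIC = "parabolic"


@dataclass(frozen=True)
class PeakInfo:
    """Location and height of a spectral band maximum."""

    position: float  # axis units
    height: float  # signal units
    method: PeakMethod
    axis_kind: AxisKind
    boundary: bool = False  # maximum fell on the grid edge

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("peak height must be positive")


class ShiftDirection(str, enum.Enum):
    DOWNSHIFT = "downshift"
    UPSHIFT = "upshift"
    NONE = "none"


@dataclass(frozen=True)
class ShiftCall:
    """Signed peak displacement with its classification.

    ``delta`` is observed minus reference position on the stored axis.
    On a wavelength axis a downshift is a blue shift and an upshift a
    red shift; :meth:`describe` renders that convention.
    """

    direction: ShiftDirection
    delta: float
    axis_kind: AxisKind

    def describe(self) -> str:
        if self.direction is ShiftDirection.NONE:
            return "no shift"
        if self.axis_kind is AxisKind.WAVELENGTH_NM:
            color = "blue shift" if self.direction is ShiftDirection.DOWNSHIFT else "red shift"
            return f"{color} of {abs(self.delta):g} nm"
        unit = "cm^-1"
        return f"{self.direction.value} of {abs(self.delta):g} {unit}"


@dataclass(frozen=True)
class CDRecord:
    """A CD spectrum (theta in degrees) with the metadata needed for
    molar-ellipticity conversion: molar protein concentration C (mol/L),
    path length l (cm) and residue count R."""

    spectrum: Spectrum
    protein_conc: float  # mol/L
    path_length: float  # cm
    residue_count: int
    mean_residue_weight: float | None = None  # g/mol, metadata only

    def __post_init__(self) -> None:
        if self.protein_conc <= 0:
            raise ValueError("protein_conc must be positive")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")
        if self.residue_count < 1:
            raise ValueError("residue_count must be >= 1")

    @classmethod
    def from_millidegrees(
        cls,
        spectrum: Spectrum,
        protein_conc: float,
        path_length: float,
        residue_count: int,
        **kw,
    ) -> "CDRecord":
        """Build a record from an instrument trace in millidegrees."""
        deg = replace(spectrum, signal=spectrum.signal / 1000.0)
        return cls(deg, protein_conc, path_length, residue_count, **kw)


def _moving_average(signal: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the available shrunken window."""
    if window == 1:
        return signal
    half = window // 2
    padded = np.pad(signal, half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def find_peak(spectrum: Spectrum, window: int = 5) -> PeakInfo:
    """Locate the global signal maximum of a spectrum.

    The signal is smoothed with a centered moving average of ``window``
    grid points (odd, >= 1); the discrete maximum is then refined by a
    parabola through the three surrounding points when it is interior.
    A maximum on the grid edge is returned unrefined with
    ``boundary=True`` and a warning.

    Raises ``ValueError`` for a flat spectrum ("no peak"), an even or
    oversized window, or smoothing requested on a non-uniform grid.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window > len(spectrum):
        raise ValueError("window exceeds spectrum length")
    axis, signal = spectrum.axis, spectrum.signal
    if np.all(signal == signal[0]):
        raise ValueError("no peak: flat spectrum")
    if window > 1:
        steps = np.diff(axis)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError("smoothing window requires a uniform axis grid")
    smooth = _moving_average(signal, window)
    i = int(np.argmax(smooth))
    if i == 0 or i == len(smooth) - 1:
        warnings.warn("peak maximum at grid boundary", stacklevel=2)
        return PeakInfo(
            position=float(axis[i]),
            height=float(smooth[i]),
            method=PeakMethod.ARGMAX,
            axis_kind=spectrum.axis_kind,
            boundary=True,
        )
    x = axis[i - 1 : i + 2]
    y = smooth[i - 1 : i + 2]
    a, b, c = np.polyfit(x, y, 2)
    if a >= 0:  # degenerate neighbourhood, fall back to the grid point
        return PeakInfo(
            position=float(axis[i]),
            height=float(smooth[i]),
            method=PeakMethod.ARGMAX,
            axis_kind=spectrum.axis_kind,
        )
    pos = -b / (2 * a)
    height = a * pos * pos + b * pos + c
    return PeakInfo(
        position=float(pos),
        height=float(height),
        method=PeakMethod.PARABOLIC,
        axis_kind=spectrum.axis_kind,
    )


def classify_shift(
    reference: PeakInfo, observed: PeakInfo, tolerance: float
) -> ShiftCall:
    """Classify the displacement of an observed peak against a reference.

    ``delta = observed.position - reference.position``; displacements
    with absolute value within ``tolerance`` (axis units) are "none".
    Both peaks must live on the same axis kind.
    """
    if reference.axis_kind is not observed.axis_kind:
        raise ValueError("cannot compare peaks on different axis kinds")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    delta = observed.position - reference.position
    if abs(delta) <= tolerance:
        direction = ShiftDirection.NONE
    elif delta < 0:
        direction = ShiftDirection.DOWNSHIFT
    else:
        direction = ShiftDirection.UPSHIFT
    return ShiftCall(direction=direction, delta=float(delta), axis_kind=reference.axis_kind)


class EvaluationMode(str, enum.Enum):
    """Where F is read for each quenched spectrum."""

    REFERENCE_PEAK = "reference_peak"  # fixed at the unquenched lambda_max
    PER_SPECTRUM_PEAK = "per_spectrum_peak"  # each spectrum's own lambda_max


def quench_ratios(
    series: TitrationSeries,
    at: EvaluationMode | str = EvaluationMode.REFERENCE_PEAK,
    window: int = 5,
) -> pd.DataFrame:
    """Tabulate Stern-Volmer quench ratios for a titration series.

    F0 is the unquenched spectrum's peak intensity.  In the default
    ``reference_peak`` mode F is read at the unquenched lambda_max for
    every spectrum (the standard Stern-Volmer convention); in
    ``per_spectrum_peak`` mode F is each spectrum's own peak height.

    Returns a DataFrame with columns ``quencher_conc_M``, ``F0_over_F``,
    ``F0_minus_F_over_F`` and ``enhancement`` (True where F > F0; such
    rows are excluded from downstream fits).  The zero-quencher row is
    kept for bookkeeping with ratios (1, 0).
    """
    at = EvaluationMode(at)
    ref_peak = find_peak(series.reference, window=window)
    if at is EvaluationMode.PER_SPECTRUM_PEAK:
        f0 = ref_peak.height
    else:
        # evaluate F0 by the same rule as F so the q=0 ratio is exactly 1
        ref_smooth = _moving_average(series.reference.signal, window)
        f0 = float(np.interp(ref_peak.position, series.reference.axis, ref_smooth))
    rows = []
    for spec, q in zip(series.spectra, series.quencher_conc):
        if at is EvaluationMode.PER_SPECTRUM_PEAK:
            f = find_peak(spec, window=window).height
        else:
            smooth = _moving_average(spec.signal, window)
            f = float(np.interp(ref_peak.position, spec.axis, smooth))
        if f <= 0:
            raise ValueError("non-positive intensity at the evaluation wavelength")
        rows.append(
            {
                "quencher_conc_M": float(q),
                "F0_over_F": f0 / f,
                "F0_minus_F_over_F": (f0 - f) / f,
                "enhancement": bool(f > f0 and q > 0),
            }
        )
    table = pd.DataFrame(rows)
    # the reference row is exact by construction
    zero = table["quencher_conc_M"] == 0.0
    table.loc[zero, ["F0_over_F", "F0_minus_F_over_F"]] = [1.0, 0.0]
    return table


def molar_ellipticity(record: CDRecord) -> Spectrum:
    """Convert a CD trace in degrees to molar ellipticity.

    [theta](lambda) = theta(lambda) / (R * C * l * 10), giving
    deg cm^2 dmol^-1 with C in mol/L and l in cm.  Metadata propagates.
    """
    denom = record.residue_count * record.protein_conc * record.path_length * 10.0
    return replace(record.spectrum, signal=record.spectrum.signal / denom)


def write_spectra_csv(path, series_list: list[TitrationSeries]) -> None:
    """Write titration series to long-format CSV (inverse of read)."""
    rows = []
    for series in series_list:
        for spec, q in zip(series.spectra, series.quencher_conc):
            for x, y in zip(spec.axis, spec.signal):
                rows.append(
                    (
                        spec.sample_id,
                        spec.temperature,
                        float(q),
                        spec.axis_kind.value,
                        float(x),
                        float(y),
                    )
                )
    frame = pd.DataFrame(rows, columns=SPECTRA_CSV_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.12g")


def read_spectra_csv(path) -> list[TitrationSeries]:
    """Read long-format titration CSV into TitrationSeries, grouped by
    (sample_id, temperature).  Errors name the offending CSV row."""
    frame = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in SPECTRA_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    frame["sample_id"] = frame["sample_id"].fillna("")
    for col in ("temperature_K", "quencher_conc_M", "axis_value", "signal"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[numeric.isna() & frame[col].notna() | frame[col].isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"non-numeric cell in column {col!r} at row {bad[0] + 2}")
        frame[col] = numeric
    dup = frame.duplicated(
        subset=["sample_id", "temperature_K", "quencher_conc_M", "axis_value"]
    )
    if dup.any():
        raise ValueError(
            f"duplicate (series, conc, axis_value) at row {int(frame.index[dup][0]) + 2}"
        )

    out: list[TitrationSeries] = []
    for (sample_id, temp), group in frame.groupby(["sample_id", "temperature_K"], sort=True):
        spectra = []
        concs = []
        for q, sub in group.groupby("quencher_conc_M", sort=True):
            sub = sub.sort_values("axis_value")
            kinds = sub["axis_kind"].unique()
            if len(kinds) != 1:
                raise ValueError(f"mixed axis_kind within one spectrum ({sample_id})")
            spectra.append(
                Spectrum(
                    axis_kind=AxisKind(kinds[0]),
                    axis=sub["axis_value"].to_numpy(),
                    signal=sub["signal"].to_numpy(),
                    temperature=float(temp),
                    sample_id=str(sample_id),
                )
            )
            concs.append(float(q))
        if 0.0 not in concs:
            raise ValueError(f"no F0 reference in series ({sample_id}, {temp} K)")
        out.append(TitrationSeries(spectra=tuple(spectra), quencher_conc=np.array(concs)))
    return out
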