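"""IM-MS feature data: interchange format, extracted ion mobility spectra
(EIM), mobility-gated mass spectra, smoothing and apex detection.

Feature data is a flat table of (m/z, mobility, intensity) triples with a
``#key=value`` metadata preamble.  The mobility axis is either inverse
reduced mobility 1/K0 in V·s/cm² (trapped ion mobility, TIMS) or drift
time in ms (traveling wave ion mobility, TWIMS).  Vendor raw files are
deliberately out of scope; conversion to this table happens upstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import find_peaks, peak_widths, savgol_filter

from .peptides import IsotopeEnvelope

__all__ = [
    "Platform",
    "MobilityAxis",
    "IMMSDataset",
    "MobilitySpectrum",
    "MobilityPeak",
    "FeatureTableError",
    "read_feature_table",
    "write_feature_table",
    "extract_eim",
    "extract_ms_at_mobility",
    "smooth",
    "detect_peaks",
    "default_bin_width",
    "default_mobility_tol",
]

PLATFORMS = ("TIMS", "TWIMS")
AXES = ("inverse_reduced_mobility", "drift_time")
Platform = str
MobilityAxis = str

#: Default mobility histogram bin per axis: finer than the narrowest peak
#: separation of interest (e.g. 1.126 vs 1.203 V·s/cm² on TIMS).
_DEFAULT_BIN = {"inverse_reduced_mobility": 0.001, "drift_time": 0.05}

#: Default apex-coincidence tolerance per axis.
_DEFAULT_TOL = {"inverse_reduced_mobility": 0.01, "drift_time": 0.2}

#: m/z half-window used when selecting individual isotopologue peaks.
ENVELOPE_MZ_TOL = 0.05


def default_bin_width(axis: MobilityAxis) -> float:
    return _DEFAULT_BIN[axis]


def default_mobility_tol(axis: MobilityAxis) -> float:
    return _DEFAULT_TOL[axis]


class FeatureTableError(ValueError):
    """Malformed feature table; message carries the offending line number."""


@dataclass
class IMMSDataset:
    """A collection of IM-MS features with platform metadata.

    ``quad_window`` records a quadrupole selection (center, half-width) in
    Th applied between the mobility cell and the collision cell; features
    outside the window can then only be post-selection fragments.
    """

    mz: np.ndarray
    mobility: np.ndarray
    intensity: np.ndarray
    platform: Platform = "TIMS"
    mobility_axis: MobilityAxis = "inverse_reduced_mobility"
    quad_window: Optional[Tuple[float, float]] = None
    metadata: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.mobility = np.asarray(self.mobility, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.mz) == len(self.mobility) == len(self.intensity)):
            raise ValueError("mz, mobility and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.mobility_axis not in AXES:
            raise ValueError(f"unknown mobility axis {self.mobility_axis!r}")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def select(self, mask: np.ndarray) -> "IMMSDataset":
        return replace(
            self,
            mz=self.mz[mask],
            mobility=self.mobility[mask],
            intensity=self.intensity[mask],
            metadata=dict(self.metadata),
        )


@dataclass
class MobilitySpectrum:
    """Intensity versus mobility on a regular grid, with provenance."""

    axis: np.ndarray
    intensity: np.ndarray
    provenance: str = ""
    empty_selection: bool = False

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.axis) != len(self.intensity):
            raise ValueError("axis and intensity must have equal length")
        if len(self.axis) > 1 and np.any(np.diff(self.axis) <= 0):
            raise ValueError("mobility axis must be strictly increasing")

    @property
    def bin_width(self) -> float:
        return float(self.axis[1] - self.axis[0]) if len(self.axis) > 1 else 0.0


@dataclass(frozen=True)
class MobilityPeak:
    """A detected mobility peak: parabolic-refined apex, height and FWHM."""

    apex: float
    height: float
    fwhm: float

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("peak height must be positive")


# ---------------------------------------------------------------------------
# feature-table I/O

_META_KEYS = ("platform", "mobility_axis", "quad_center", "quad_halfwidth")


def write_feature_table(dataset: IMMSDataset, path) -> None:
    """Write a dataset as TSV with a ``#key=value`` preamble.

    Floats are written with ``repr`` so a write/read round trip is
    bit-exact.
    """
    with open(path, "w") as fh:
        fh.write(f"#platform={dataset.platform}\n")
        fh.write(f"#mobility_axis={dataset.mobility_axis}\n")
        if dataset.quad_window is not None:
            fh.write(f"#quad_center={dataset.quad_window[0]!r}\n")
            fh.write(f"#quad_halfwidth={dataset.quad_window[1]!r}\n")
        for key, value in sorted(dataset.metadata.items()):
            fh.write(f"#{key}={value}\n")
        fh.write("mz\tmobility\tintensity\n")
        for mz, mob, inten in zip(dataset.mz, dataset.mobility, dataset.intensity):
            fh.write(f"{float(mz)!r}\t{float(mob)!r}\t{float(inten)!r}\n")


def read_feature_table(path) -> IMMSDataset:
    """Read a feature table written by :func:`write_feature_table`.

    Errors name the offending line; unknown ``#key=value`` metadata is
    preserved verbatim.
    """
    meta: Dict[str, str] = {}
    rows: List[Tuple[float, float, float]] = []
    header: Optional[List[str]] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise FeatureTableError(
                        f"line {lineno}: metadata line without '=': {line!r}"
                    )
                key, value = line[1:].split("=", 1)
                meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = [c.strip() for c in line.split("\t")]
                for required in ("mz", "mobility", "intensity"):
                    if required not in header:
                        raise FeatureTableError(
                            f"line {lineno}: missing required column {required!r}"
                        )
                continue
            cells = line.split("\t")
            if len(cells) != len(header):
                raise FeatureTableError(
                    f"line {lineno}: expected {len(header)} cells, got {len(cells)}"
                )
            try:
                row = {h: float(c) for h, c in zip(header, cells)}
            except ValueError as exc:
                raise FeatureTableError(f"line {lineno}: non-numeric cell ({exc})")
            rows.append((row["mz"], row["mobility"], row["intensity"]))
    if header is None:
        raise FeatureTableError("file has no header line")

    platform = meta.pop("platform", "TIMS")
    axis = meta.pop("mobility_axis", "inverse_reduced_mobility")
    if axis not in AXES:
        raise FeatureTableError(f"unknown mobility_axis value {axis!r}")
    if platform not in PLATFORMS:
        raise FeatureTableError(f"unknown platform value {platform!r}")
    quad = None
    if "quad_center" in meta or "quad_halfwidth" in meta:
        try:
            quad = (float(meta.pop("quad_center")), float(meta.pop("quad_halfwidth")))
        except KeyError:
            raise FeatureTableError(
                "quad_center and quad_halfwidth must be given together"
            )
    arr = np.array(rows, dtype=float) if rows else np.empty((0, 3))
    return IMMSDataset(
        mz=arr[:, 0],
        mobility=arr[:, 1],
        intensity=arr[:, 2],
        platform=platform,
        mobility_axis=axis,
        quad_window=quad,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# extraction

Selection = Union[Tuple[float, float], IsotopeEnvelope]


def _selection_mask(dataset: IMMSDataset, selection: Selection) -> np.ndarray:
    if isinstance(selection, IsotopeEnvelope):
        mask = np.zeros(len(dataset), dtype=bool)
        for mz in selection.mzs:
            mask |= np.abs(dataset.mz - mz) <= ENVELOPE_MZ_TOL
        return mask
    center, halfwidth = selection
    return np.abs(dataset.mz - center) <= halfwidth


def _selection_label(selection: Selection) -> str:
    if isinstance(selection, IsotopeEnvelope):
        return (
            f"envelope z={selection.charge} "
            f"[{selection.mzs[0]:.4f}..{selection.mzs[-1]:.4f}]"
        )
    return f"mz {selection[0]:.4f} +/- {selection[1]:.4f}"


def extract_eim(
    dataset: IMMSDataset,
    selection: Selection,
    bin_width: Optional[float] = None,
) -> MobilitySpectrum:
    """Extracted ion mobility spectrum of the features in an m/z selection.

    The selection is either ``(center, half-width)`` in Th or an
    :class:`IsotopeEnvelope` (features within +/-0.05 Th of any envelope
    peak).  Selected intensities are summed onto a regular mobility grid
    spanning the dataset's mobility range.
    """
    if bin_width is None:
        bin_width = default_bin_width(dataset.mobility_axis)
    if len(dataset) == 0:
        return MobilitySpectrum(
            axis=np.array([0.0]), intensity=np.array([0.0]),
            provenance=_selection_label(selection), empty_selection=True,
        )
    lo = math.floor(dataset.mobility.min() / bin_width) * bin_width
    hi = dataset.mobility.max()
    nbins = max(1, int(math.ceil((hi - lo) / bin_width)) + 1)
    axis = lo + (np.arange(nbins) + 0.5) * bin_width

    mask = _selection_mask(dataset, selection)
    spec = np.zeros(nbins)
    if not mask.any():
        warnings.warn(
            f"selection {_selection_label(selection)} matches no features",
            stacklevel=2,
        )
        return MobilitySpectrum(
            axis=axis, intensity=spec,
            provenance=_selection_label(selection), empty_selection=True,
        )
    idx = np.clip(((dataset.mobility[mask] - lo) / bin_width).astype(int), 0, nbins - 1)
    np.add.at(spec, idx, dataset.intensity[mask])
    return MobilitySpectrum(
        axis=axis, intensity=spec, provenance=_selection_label(selection)
    )


def extract_ms_at_mobility(
    dataset: IMMSDataset,
    mobility_window: Tuple[float, float],
) -> List[Tuple[float, float]]:
    """Mass spectrum of the features inside a (low, high) mobility window.

    Returns (m/z, summed intensity) pairs sorted by m/z, ready for
    isotope-spacing charge reading.
    """
    lo, hi = mobility_window
    if hi < lo:
        lo, hi = hi, lo
    mask = (dataset.mobility >= lo) & (dataset.mobility <= hi)
    if not mask.any():
        return []
    agg: Dict[float, float] = {}
    for mz, inten in zip(dataset.mz[mask], dataset.intensity[mask]):
        agg[mz] = agg.get(mz, 0.0) + inten
    return sorted(agg.items())


def smooth(
    spectrum: MobilitySpectrum, window_length: int = 11, polyorder: int = 3
) -> MobilitySpectrum:
    """Savitzky-Golay smoothing of a mobility spectrum (length preserved)."""
    if window_length % 2 == 0 or window_length <= polyorder:
        raise ValueError("window_length must be odd and greater than polyorder")
    if window_length > len(spectrum.intensity):
        raise ValueError(
            f"window_length {window_length} exceeds spectrum length "
            f"{len(spectrum.intensity)}"
        )
    return MobilitySpectrum(
        axis=spectrum.axis.copy(),
        intensity=savgol_filter(spectrum.intensity, window_length, polyorder),
        provenance=spectrum.provenance + " [smoothed]",
        empty_selection=spectrum.empty_selection,
    )


def _parabolic_apex(axis: np.ndarray, y: np.ndarray, i: int) -> Tuple[float, float]:
    """Refine a local maximum by a parabola through its three samples."""
    if i == 0 or i == len(y) - 1:
        return float(axis[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # flat or degenerate
        return float(axis[i]), float(y1)
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dx = axis[1] - axis[0]
    height = y1 - 0.25 * (y0 - y2) * delta
    return float(axis[i] + delta * dx), float(height)


def detect_peaks(
    spectrum: MobilitySpectrum,
    min_height_fraction: float = 0.05,
    min_separation: Optional[float] = None,
    min_height: float = 0.0,
) -> List[MobilityPeak]:
    """Local maxima above ``min_height_fraction`` of the base peak and the
    absolute floor ``min_height``, at least ``min_separation`` axis units
    apart, apex-refined by a 3-point parabola.  Returns peaks sorted by
    apex position."""
    y = spectrum.intensity
    if len(y) == 0 or not np.any(y > 0):
        return []
    top = float(y.max())
    dx = spectrum.bin_width or 1.0
    threshold = max(min_height_fraction * top, min_height)
    distance = max(1, int(round((min_separation or dx) / dx)))
    idx, props = find_peaks(y, height=threshold, distance=distance)
    if len(idx) == 0:
        # single-bin or monotone edge spectra: fall back to the maximum
        if top < threshold:
            return []
        i = int(np.argmax(y))
        apex, height = _parabolic_apex(spectrum.axis, y, i)
        return [MobilityPeak(apex=apex, height=height, fwhm=dx)]
    widths = peak_widths(y, idx, rel_height=0.5)[0] * dx
    peaks = []
    for i, w in zip(idx, widths):
        apex, height = _parabolic_apex(spectrum.axis, y, int(i))
        peaks.append(MobilityPeak(apex=apex, height=height, fwhm=float(max(w, dx))))
    peaks.sort(key=lambda p: p.apex)
    return peaks
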