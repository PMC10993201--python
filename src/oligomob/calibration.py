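"""Mobility-axis calibration and collision cross sections (CCS).

Two platforms are supported:

* TIMS reports inverse reduced mobility 1/K0 (V·s/cm²).  The axis is
  calibrated against reference ions of known 1/K0 (e.g. Agilent ESI Tuning
  Mix) with a monotone piecewise-linear map, and converted to CCS with the
  Mason-Schamp relation.
* TWIMS reports drift times (ms).  After subtracting the mass-dependent
  transit-time (EDC) term, ln(reduced CCS) is fitted linearly against
  ln(corrected drift time) over calibrant ions of known drift-tube CCS;
  the fit inverts to a drift-time -> CCS map.

The Mason-Schamp constants (gas number density at 273.15 K and 101.325 kPa,
N2 gas mass) follow the reduced-mobility convention and are overridable;
cross-platform *relative* comparisons are unaffected by the constant bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import constants as _const

from .oligomers import OligomerIon
from .peptides import PROTON_MASS

__all__ = [
    "N2_MASS",
    "STANDARD_TEMPERATURE",
    "TimsCalibration",
    "TwimsCalibrant",
    "TwimsCalibration",
    "CcsValue",
    "PlatformComparison",
    "fit_tims_calibration",
    "mobility_to_ccs",
    "fit_twims_calibration",
    "twims_ccs",
    "compare_platforms",
    "read_calibrant_table",
]

#: Molecular mass of the N2 drift gas in Da.
N2_MASS = 28.00615

#: Reduced-mobility reference temperature in K.
STANDARD_TEMPERATURE = 273.15

_LOSCHMIDT = _const.value("Loschmidt constant (273.15 K, 101.325 kPa)")  # m^-3


@dataclass
class TimsCalibration:
    """Monotone piecewise-linear map from a raw TIMS axis to 1/K0.

    Anchored at matched calibrant ions; anchor positions map exactly onto
    their reference 1/K0, intermediate positions interpolate linearly and
    the edge segments extrapolate.
    """

    raw_anchors: np.ndarray
    inv_k0_anchors: np.ndarray
    reference_mz: np.ndarray

    def __post_init__(self):
        self.raw_anchors = np.asarray(self.raw_anchors, dtype=float)
        self.inv_k0_anchors = np.asarray(self.inv_k0_anchors, dtype=float)
        self.reference_mz = np.asarray(self.reference_mz, dtype=float)
        if len(self.raw_anchors) < 2:
            raise ValueError("need at least 2 calibrant anchors")
        if np.any(np.diff(self.raw_anchors) <= 0) or np.any(
            np.diff(self.inv_k0_anchors) <= 0
        ):
            raise ValueError("calibrant sequence must be strictly monotone")

    def apply(self, raw) -> np.ndarray:
        """Map raw axis position(s) to 1/K0, extrapolating linearly at
        the edges."""
        raw = np.asarray(raw, dtype=float)
        x, y = self.raw_anchors, self.inv_k0_anchors
        out = np.interp(raw, x, y)
        lo = raw < x[0]
        hi = raw > x[-1]
        if np.any(lo):
            slope = (y[1] - y[0]) / (x[1] - x[0])
            out = np.where(lo, y[0] + slope * (raw - x[0]), out)
        if np.any(hi):
            slope = (y[-1] - y[-2]) / (x[-1] - x[-2])
            out = np.where(hi, y[-1] + slope * (raw - x[-1]), out)
        return out if out.ndim else float(out)


def fit_tims_calibration(
    observed: Sequence[Tuple[float, float]],
    reference: Sequence[Tuple[float, float]],
    mz_tol: float = 0.5,
) -> TimsCalibration:
    """Match observed calibrant ions (raw_position, m/z) to a reference
    table (m/z, 1/K0) and build the anchor map.

    Ions are matched on m/z within ``mz_tol``; at least two matches are
    required and both axes must be strictly increasing after sorting.
    """
    ref = sorted(reference)
    matched = []
    for raw_pos, mz in observed:
        best = min(ref, key=lambda r: abs(r[0] - mz), default=None)
        if best is not None and abs(best[0] - mz) <= mz_tol:
            matched.append((raw_pos, best[1], best[0]))
    if len(matched) < 2:
        raise ValueError(
            f"only {len(matched)} calibrant ions matched within {mz_tol} Th; "
            "need at least 2"
        )
    matched.sort()
    raw = np.array([m[0] for m in matched])
    inv = np.array([m[1] for m in matched])
    mzs = np.array([m[2] for m in matched])
    return TimsCalibration(raw_anchors=raw, inv_k0_anchors=inv, reference_mz=mzs)


def _reduced_mass_kg(ion_mass: float, gas_mass: float) -> float:
    mu_da = ion_mass * gas_mass / (ion_mass + gas_mass)
    return mu_da * _const.atomic_mass


def mobility_to_ccs(
    inv_k0: float,
    z: int,
    ion_mass: float,
    gas_mass: float = N2_MASS,
    temperature: float = STANDARD_TEMPERATURE,
) -> float:
    """Mason-Schamp conversion of inverse reduced mobility to CCS in Å².

    CCS = 3 z e / (16 N0) * sqrt(2 pi / (mu kB T)) / K0, with K0 the
    reduced mobility (1/K0 given in V·s/cm²), mu the ion-gas reduced mass
    and N0 the gas number density at standard conditions.
    """
    if inv_k0 <= 0 or z < 1 or ion_mass <= 0 or gas_mass <= 0 or temperature <= 0:
        raise ValueError("all arguments must be positive")
    mu = _reduced_mass_kg(ion_mass, gas_mass)
    k0_si = 1e-4 / inv_k0  # cm^2/(V s) -> m^2/(V s)
    omega_m2 = (
        3 * z * _const.e / (16 * _LOSCHMIDT)
        * math.sqrt(2 * math.pi / (mu * _const.k * temperature))
        / k0_si
    )
    return omega_m2 * 1e20


@dataclass(frozen=True)
class TwimsCalibrant:
    """One TWIMS calibrant ion with literature drift-tube CCS (N2, Å²)."""

    mz: float
    z: int
    ccs_ref: float
    drift_time: float
    name: str = ""


@dataclass
class TwimsCalibration:
    """Log-log power-law calibration ln(CCS') = a ln(dt') + b.

    dt' = dt - edc * sqrt(m/z) / 1000 removes the mass-dependent post-drift
    transit time (EDC delay coefficient convention of Synapt instruments);
    CCS' = CCS * sqrt(mu) / z removes charge and reduced-mass scaling.
    """

    slope: float
    intercept: float
    edc_coefficient: float
    fit_r_squared: float
    gas_mass: float = N2_MASS
    calibrants: Tuple[TwimsCalibrant, ...] = ()

    def __post_init__(self):
        if not (0.0 <= self.fit_r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")


def _corrected_drift(dt: float, mz: float, edc: float) -> float:
    return dt - edc * math.sqrt(mz) / 1000.0


def fit_twims_calibration(
    calibrants: Sequence[TwimsCalibrant],
    edc_coefficient: float,
    gas_mass: float = N2_MASS,
) -> TwimsCalibration:
    """Least-squares log-log fit of reduced CCS against corrected drift
    time over >= 3 calibrant ions."""
    if len(calibrants) < 3:
        raise ValueError(f"need at least 3 calibrants, got {len(calibrants)}")
    x, y = [], []
    for cal in calibrants:
        dtp = _corrected_drift(cal.drift_time, cal.mz, edc_coefficient)
        if dtp <= 0:
            label = cal.name or f"m/z {cal.mz:.1f} ({cal.z}+)"
            raise ValueError(
                f"calibrant {label}: corrected drift time {dtp:.4f} ms is not "
                "positive; check the EDC coefficient"
            )
        ion_mass = cal.z * (cal.mz - PROTON_MASS)
        mu = ion_mass * gas_mass / (ion_mass + gas_mass)
        ccs_red = cal.ccs_ref * math.sqrt(mu) / cal.z
        x.append(math.log(dtp))
        y.append(math.log(ccs_red))
    x = np.asarray(x)
    y = np.asarray(y)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return TwimsCalibration(
        slope=float(slope),
        intercept=float(intercept),
        edc_coefficient=edc_coefficient,
        fit_r_squared=max(0.0, min(1.0, r2)),
        gas_mass=gas_mass,
        calibrants=tuple(calibrants),
    )


def twims_ccs(
    dt: float,
    cal: TwimsCalibration,
    z: int,
    ion_mass: float,
    gas_mass: Optional[float] = None,
) -> float:
    """CCS (Å²) of an ion from its TWIMS drift time, inverting the
    calibration: CCS = exp(a ln dt' + b) * z / sqrt(mu)."""
    gas = cal.gas_mass if gas_mass is None else gas_mass
    mz = (ion_mass + z * PROTON_MASS) / z
    dtp = _corrected_drift(dt, mz, cal.edc_coefficient)
    if dtp <= 0:
        raise ValueError(
            f"corrected drift time {dtp:.4f} ms is not positive for m/z {mz:.2f}"
        )
    mu = ion_mass * gas / (ion_mass + gas)
    return math.exp(cal.slope * math.log(dtp) + cal.intercept) * z / math.sqrt(mu)


@dataclass(frozen=True)
class CcsValue:
    """A calibrated CCS for one oligomer ion on one platform."""

    species: OligomerIon
    ccs: float
    platform: str
    sd: float = 0.0

    def __post_init__(self):
        if self.ccs <= 0:
            raise ValueError("ccs must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class PlatformComparison:
    """Cross-platform CCS agreement statistics over matched (n, z) species.

    Relative differences are symmetric: 100 |a - b| / mean(a, b).  The
    linear fit regresses platform-b CCS on platform-a CCS.
    """

    species: List[Tuple[int, int]]
    ccs_a: np.ndarray
    ccs_b: np.ndarray
    relative_differences: np.ndarray
    mean_relative_difference: float
    max_relative_difference: float
    fit_slope: float
    fit_intercept: float
    r_squared: float
    n_a_larger: int
    n_b_larger: int

    @property
    def n_matched(self) -> int:
        return len(self.species)

    def to_dict(self) -> Dict:
        return {
            "n_matched": self.n_matched,
            "mean_relative_difference_pct": self.mean_relative_difference,
            "max_relative_difference_pct": self.max_relative_difference,
            "fit_slope": self.fit_slope,
            "fit_intercept": self.fit_intercept,
            "r_squared": self.r_squared,
            "n_a_larger": self.n_a_larger,
            "n_b_larger": self.n_b_larger,
            "species": [list(s) for s in self.species],
            "relative_differences_pct": list(map(float, self.relative_differences)),
        }


def compare_platforms(
    a: Sequence[CcsValue], b: Sequence[CcsValue]
) -> Optional[PlatformComparison]:
    """Compare CCS lists from two platforms, matching species on exact
    (n, z).  Returns None when the species sets do not overlap."""
    index_b = {(v.species.n, v.species.z): v for v in b}
    matched = [
        ((v.species.n, v.species.z), v, index_b[(v.species.n, v.species.z)])
        for v in a
        if (v.species.n, v.species.z) in index_b
    ]
    if not matched:
        return None
    matched.sort(key=lambda m: m[0])
    keys = [m[0] for m in matched]
    ccs_a = np.array([m[1].ccs for m in matched])
    ccs_b = np.array([m[2].ccs for m in matched])
    rel = 100.0 * np.abs(ccs_a - ccs_b) / ((ccs_a + ccs_b) / 2.0)
    if len(matched) >= 2 and np.ptp(ccs_a) > 0:
        slope, intercept = np.polyfit(ccs_a, ccs_b, 1)
        pred = slope * ccs_a + intercept
        ss_res = float(np.sum((ccs_b - pred) ** 2))
        ss_tot = float(np.sum((ccs_b - ccs_b.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    else:
        slope, intercept, r2 = float("nan"), float("nan"), 1.0
    return PlatformComparison(
        species=keys,
        ccs_a=ccs_a,
        ccs_b=ccs_b,
        relative_differences=rel,
        mean_relative_difference=float(rel.mean()),
        max_relative_difference=float(rel.max()),
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        r_squared=float(r2),
        n_a_larger=int(np.sum(ccs_a > ccs_b)),
        n_b_larger=int(np.sum(ccs_b > ccs_a)),
    )


def read_calibrant_table(path) -> List[TwimsCalibrant]:
    """Read a TWIMS calibrant TSV with columns mz, z, ccs_ref, drift_time
    and an optional name column; '#' lines are comments."""
    out = []
    with open(path) as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                for req in ("mz", "z", "ccs_ref", "drift_time"):
                    if req not in header:
                        raise ValueError(f"line {lineno}: missing column {req!r}")
                continue
            row = dict(zip(header, cells))
            out.append(
                TwimsCalibrant(
                    mz=float(row["mz"]),
                    z=int(row["z"]),
                    ccs_ref=float(row["ccs_ref"]),
                    drift_time=float(row["drift_time"]),
                    name=row.get("name", ""),
                )
            )
    return out
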