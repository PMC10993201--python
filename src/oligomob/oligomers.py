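"""Candidate oligomer enumeration, isobaric families and (n, z) inference.

Oligomers ``n^z+`` with the same n:z ratio are isobaric — their m/z values
differ only through the shared proton term and collapse onto (nearly) the
same channel, e.g. the dimer 2^1+ and the octamer 8^4+ both sit at m/z 1580
for the Ac-PHF6-NH2 monomer.  Such a family is written ``[kn]^kz+`` and is
keyed here by the gcd-reduced (n, z) pair.  Within one m/z channel the
members are distinguished by their isotopologue spacing (1.00336/z Th) and
by ion mobility.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, List, Optional, Sequence, Tuple

import numpy as np

from .peptides import (
    NEUTRON_SPACING,
    PROTON_MASS,
    ElementalComposition,
    isotope_envelope,
    oligomer_mz,
)

if TYPE_CHECKING:  # pragma: no cover
    from .mobility import IMMSDataset

__all__ = [
    "OligomerIon",
    "NZInference",
    "DetectionGrid",
    "GridEntry",
    "enumerate_species",
    "isobaric_family",
    "infer_n_z",
    "screen_oligomers",
]


@dataclass(frozen=True, order=True)
class OligomerIon:
    """An (n, z) oligomer ion with its theoretical m/z."""

    n: int
    z: int
    mz: float

    def __post_init__(self):
        if self.n < 1 or self.z < 1:
            raise ValueError(f"require n >= 1, z >= 1; got ({self.n}, {self.z})")

    @classmethod
    def from_monomer_mass(cls, M: float, n: int, z: int) -> "OligomerIon":
        return cls(n=n, z=z, mz=oligomer_mz(M, n, z))

    @property
    def family_key(self) -> Tuple[int, int]:
        """gcd-reduced n:z ratio; shared by all isobaric family members."""
        g = math.gcd(self.n, self.z)
        return (self.n // g, self.z // g)

    @property
    def label(self) -> str:
        return f"{self.n}^{self.z}+"


def enumerate_species(
    M: float,
    mz_range: Tuple[float, float] = (50.0, 3000.0),
    n_max: int = 25,
    z_max: int = 8,
) -> List[OligomerIon]:
    """All oligomer ions (n <= n_max, z <= z_max) with m/z inside the range,
    sorted by m/z then (n, z)."""
    lo, hi = mz_range
    out = [
        OligomerIon(n, z, mz)
        for n in range(1, n_max + 1)
        for z in range(1, z_max + 1)
        if lo <= (mz := oligomer_mz(M, n, z)) <= hi
    ]
    out.sort(key=lambda s: (s.mz, s.n, s.z))
    return out


def isobaric_family(
    target_mz: float,
    tol: float,
    M: float,
    n_max: int = 25,
    z_max: int = 8,
) -> List[OligomerIon]:
    """Oligomer ions within ``tol`` Th of ``target_mz``, sorted by n.

    With a tolerance below the inter-family spacing all returned members
    share one gcd-reduced family key.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    members = [
        s
        for s in enumerate_species(M, (target_mz - tol, target_mz + tol), n_max, z_max)
        if abs(s.mz - target_mz) <= tol
    ]
    members.sort(key=lambda s: (s.n, s.z))
    return members


@dataclass(frozen=True)
class NZInference:
    """Result of (n, z) inference from observed m/z and isotope spacing.

    ``assigned`` is False when no candidate back-computes to the observed
    m/z within tolerance; ``ion`` then holds the best (rejected) candidate
    and ``ppm_error`` its mass error.
    """

    assigned: bool
    ion: OligomerIon
    ppm_error: float


def infer_n_z(
    observed_mz: float,
    isotope_spacing: float,
    M: float,
    tol_ppm: float = 50.0,
) -> NZInference:
    """Infer (n, z) of an observed species from its m/z and the spacing of
    adjacent isotopologue peaks.

    The charge is read from the spacing (z = round(1.00336 / spacing)), the
    oligomer order from the deprotonated mass (n = round(z (mz - mH) / M)).
    The candidate is accepted only if its theoretical m/z matches the
    observation within ``tol_ppm``.
    """
    if isotope_spacing <= 0:
        raise ValueError("isotope_spacing must be positive")
    z = max(1, int(round(NEUTRON_SPACING / isotope_spacing)))
    n = max(1, int(round(z * (observed_mz - PROTON_MASS) / M)))
    candidate = OligomerIon.from_monomer_mass(M, n, z)
    ppm = (observed_mz - candidate.mz) / candidate.mz * 1e6
    return NZInference(assigned=abs(ppm) <= tol_ppm, ion=candidate, ppm_error=ppm)


@dataclass(frozen=True)
class GridEntry:
    n: int
    z: int
    snr: float
    detected: bool


@dataclass
class DetectionGrid:
    """Per-(n, z) maximal signal-to-noise with a detection flag.

    ``detected`` uses a strict inequality S/N > threshold, so a species
    sitting exactly at the threshold is not counted.
    """

    entries: List[GridEntry] = field(default_factory=list)
    snr_threshold: float = 3.0

    def detected_species(self) -> List[Tuple[int, int]]:
        return [(e.n, e.z) for e in self.entries if e.detected]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#snr_threshold={self.snr_threshold!r}\n")
            fh.write("n\tz\tsnr\tdetected\n")
            for e in self.entries:
                fh.write(f"{e.n}\t{e.z}\t{e.snr!r}\t{int(e.detected)}\n")

    @classmethod
    def from_tsv(cls, path) -> "DetectionGrid":
        threshold = 3.0
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#snr_threshold="):
                    threshold = float(line.split("=", 1)[1])
                    continue
                if line.startswith("n\t"):
                    continue
                n, z, snr, det = line.split("\t")
                entries.append(GridEntry(int(n), int(z), float(snr), bool(int(det))))
        return cls(entries=entries, snr_threshold=threshold)


def _mass_spectrum(dataset: "IMMSDataset", bin_width: float):
    """Collapse features over mobility onto a binned mass spectrum."""
    mz = dataset.mz
    lo = math.floor(mz.min() / bin_width) * bin_width
    nbins = int(math.ceil((mz.max() - lo) / bin_width)) + 1
    idx = np.clip(((mz - lo) / bin_width).astype(int), 0, nbins - 1)
    spec = np.zeros(nbins)
    np.add.at(spec, idx, dataset.intensity)
    centers = lo + (np.arange(nbins) + 0.5) * bin_width
    return centers, spec


def screen_oligomers(
    dataset: "IMMSDataset",
    M: float,
    snr_threshold: float = 3.0,
    comp: Optional[ElementalComposition] = None,
    n_max: int = 25,
    z_max: int = 8,
    mz_tol: float = 0.05,
    bin_width: float = 0.02,
) -> DetectionGrid:
    """Screen a dataset for detectable oligomers at an S/N threshold.

    The dataset is collapsed over mobility onto a binned mass spectrum.
    For every candidate (n, z) in the data's m/z range the signal is the
    highest bin within ``mz_tol`` of an expected isotopologue position
    (the full envelope when a composition is supplied, otherwise the first
    five comb positions).  Noise is estimated robustly from signal-free
    bins as ``median + 1.4826 * MAD`` of the positive background, and
    S/N = signal / noise.  Detection uses the strict inequality
    S/N > threshold.
    """
    if len(dataset.mz) == 0:
        return DetectionGrid(entries=[], snr_threshold=snr_threshold)
    if np.all(dataset.intensity == 0):
        raise ValueError("dataset carries no intensity; cannot screen")

    centers, spec = _mass_spectrum(dataset, bin_width)
    candidates = enumerate_species(
        M, (float(dataset.mz.min()) - 1, float(dataset.mz.max()) + 1), n_max, z_max
    )

    # expected isotopologue positions per candidate
    positions = {}
    for s in candidates:
        if comp is not None:
            env = isotope_envelope(comp, n=s.n, z=s.z, min_abundance=5e-3)
            positions[(s.n, s.z)] = np.array(env.mzs)
        else:
            positions[(s.n, s.z)] = s.mz + NEUTRON_SPACING / s.z * np.arange(5)

    # mask bins near any expected peak -> the remainder is background
    signal_mask = np.zeros_like(spec, dtype=bool)
    for pos in positions.values():
        for p in pos:
            signal_mask |= np.abs(centers - p) <= (mz_tol + bin_width)
    background = spec[~signal_mask]
    bg_pos = background[background > 0]
    if bg_pos.size:
        med = float(np.median(bg_pos))
        mad = float(np.median(np.abs(bg_pos - med)))
        noise = med + 1.4826 * mad
    else:
        noise = 0.0
    if noise <= 0:
        warnings.warn("no background signal found; S/N is unbounded", stacklevel=2)

    entries = []
    for s in candidates:
        pos = positions[(s.n, s.z)]
        sel = np.zeros_like(spec, dtype=bool)
        for p in pos:
            sel |= np.abs(centers - p) <= mz_tol
        signal = float(spec[sel].max()) if sel.any() else 0.0
        snr = signal / noise if noise > 0 else (math.inf if signal > 0 else 0.0)
        entries.append(GridEntry(s.n, s.z, snr, snr > snr_threshold))
    entries.sort(key=lambda e: (e.n, e.z))
    return DetectionGrid(entries=entries, snr_threshold=snr_threshold)
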