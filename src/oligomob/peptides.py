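"""Elemental composition, mass and isotope-envelope arithmetic for capped
peptides and their noncovalent n-mers.

The species of interest are oligomers ``n^z+`` = [nM + zH]^z+, where ``M``
is the monoisotopic mass of one peptide monomer.  Monomers may carry an
N-terminal acetyl cap (``Ac-``) and/or a C-terminal amide cap (``-NH2``),
which change the elemental composition by +C2H2O and -OH +NH2 respectively.
Oligomerisation is purely noncovalent: an n-mer is exactly n monomers, with
no water loss.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Tuple

from pyteomics import mass as _pmass

__all__ = [
    "NCap",
    "CCap",
    "PeptideSpec",
    "ElementalComposition",
    "IsotopeEnvelope",
    "PROTON_MASS",
    "NEUTRON_SPACING",
    "parse_peptide",
    "composition_of",
    "monoisotopic_mass",
    "average_mass",
    "oligomer_mass",
    "oligomer_mz",
    "isotope_envelope",
    "mz_label",
]

#: Mass of a proton in Da, used for [nM + zH]^z+ arithmetic.
PROTON_MASS = 1.007276

#: Nominal spacing of adjacent isotopologue peaks at z = 1, in Th.  For
#: peptides the envelope is dominated by 13C substitution, so the spacing is
#: taken as the 13C-12C mass difference.
NEUTRON_SPACING = 1.0033548378

_CANONICAL_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# Per-element isotope tables (mass, abundance), taken from the NIST/IUPAC
# compilation shipped with pyteomics.  Restricted to the elements occurring
# in canonical peptides.
_ELEMENTS = ("C", "H", "N", "O", "S")


def _isotopes(element: str) -> List[Tuple[float, float]]:
    table = _pmass.nist_mass[element]
    iso = [(m, ab) for key, (m, ab) in table.items() if key != 0 and ab > 0]
    iso.sort()
    return iso


_ISOTOPE_TABLE: Dict[str, List[Tuple[float, float]]] = {
    el: _isotopes(el) for el in _ELEMENTS
}


class NCap(str, Enum):
    """N-terminal state: free amine or acetylated."""

    FREE = "free"
    ACETYL = "acetyl"


class CCap(str, Enum):
    """C-terminal state: free acid or amidated."""

    FREE_ACID = "free_acid"
    AMIDE = "amide"


class ElementalComposition(dict):
    """Element -> count mapping with element-wise addition and scaling.

    Thin dict subclass; counts must remain non-negative integers.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for el, cnt in self.items():
            if cnt < 0:
                raise ValueError(f"negative count for element {el!r}: {cnt}")

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self)
        for el, cnt in other.items():
            out[el] = out.get(el, 0) + cnt
        return ElementalComposition({el: c for el, c in out.items() if c})

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 1:
            raise ValueError("multiplier must be a positive integer")
        return ElementalComposition({el: c * k for el, c in self.items()})

    __rmul__ = __mul__

    def total_atoms(self) -> int:
        return sum(self.values())

    def formula(self) -> str:
        """Hill-ordered formula string, e.g. ``C38H63N9O9``."""
        order = ["C", "H"] + sorted(el for el in self if el not in ("C", "H"))
        return "".join(
            f"{el}{self[el]}" if self.get(el, 0) != 1 else el
            for el in order
            if self.get(el, 0)
        )


@dataclass(frozen=True)
class PeptideSpec:
    """A capped peptide defined by one-letter sequence and terminal caps."""

    sequence: str
    n_cap: NCap = NCap.FREE
    c_cap: CCap = CCap.FREE_ACID
    name: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = [c for c in self.sequence if c not in _CANONICAL_RESIDUES]
        if bad:
            raise ValueError(
                f"unknown residue letter {bad[0]!r} in sequence {self.sequence!r}"
            )

    def __str__(self) -> str:
        pre = "Ac-" if self.n_cap is NCap.ACETYL else ""
        post = "-NH2" if self.c_cap is CCap.AMIDE else ""
        return f"{pre}{self.sequence}{post}"


_PEPTIDE_RE = re.compile(r"^(Ac-)?([A-Za-z]+?)(-NH2)?$")


def parse_peptide(text: str, name: str = "") -> PeptideSpec:
    """Parse an ``Ac-VQIVYK-NH2``-style peptide string.

    Prefix ``Ac-`` marks N-terminal acetylation, suffix ``-NH2`` C-terminal
    amidation; the remainder must be one-letter residue codes.
    """
    m = _PEPTIDE_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse peptide string {text!r}")
    pre, seq, post = m.groups()
    return PeptideSpec(
        sequence=seq.upper(),
        n_cap=NCap.ACETYL if pre else NCap.FREE,
        c_cap=CCap.AMIDE if post else CCap.FREE_ACID,
        name=name or text.strip(),
    )


def composition_of(spec: PeptideSpec) -> ElementalComposition:
    """Elemental composition of a capped peptide monomer.

    Residue compositions are summed, one water is added for the termini,
    then cap adjustments are applied (acetyl: +C2H2O; amide: -OH +NH2).
    """
    total = _pmass.Composition()
    for aa in spec.sequence:
        total += _pmass.std_aa_comp[aa]
    total += _pmass.Composition(formula="H2O")
    if spec.n_cap is NCap.ACETYL:
        total += _pmass.Composition(formula="C2H2O")
    if spec.c_cap is CCap.AMIDE:
        total["O"] -= 1
        total["N"] += 1
        total["H"] += 1
    return ElementalComposition({el: int(c) for el, c in total.items() if c})


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass in Da (lightest isotope of every element)."""
    return sum(_ISOTOPE_TABLE[el][0][0] * cnt for el, cnt in comp.items())


def average_mass(comp: ElementalComposition) -> float:
    """Abundance-weighted average mass in Da."""
    out = 0.0
    for el, cnt in comp.items():
        out += cnt * sum(m * ab for m, ab in _ISOTOPE_TABLE[el])
    return out


def oligomer_mass(M: float, n: int) -> float:
    """Neutral mass of a noncovalent n-mer: exactly ``n * M``."""
    if n < 1:
        raise ValueError(f"oligomer order n must be >= 1, got {n}")
    return n * M


def oligomer_mz(M: float, n: int, z: int) -> float:
    """m/z of the protonated oligomer [nM + zH]^z+."""
    if n < 1 or z < 1:
        raise ValueError(f"require n >= 1 and z >= 1, got n={n}, z={z}")
    return (n * M + z * PROTON_MASS) / z


def mz_label(mz: float) -> str:
    """Display label for an m/z value: nearest integer above 1000, one
    decimal below (the labelling convention used for oligomer channels,
    e.g. 1580 vs 790.5)."""
    if mz > 1000:
        return str(int(round(mz)))
    return f"{mz:.1f}"


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Centroided isotopologue envelope of an ion at charge z.

    Peaks are (m/z, relative abundance) with abundances normalised to unit
    sum; adjacent peaks are spaced by one nominal neutron, i.e. about
    1.00336/z Th.
    """

    peaks: Tuple[Tuple[float, float], ...]
    charge: int

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        mzs = [p[0] for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("envelope m/z values must be strictly increasing")
        s = sum(p[1] for p in self.peaks)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"envelope abundances must sum to 1, got {s}")

    @property
    def mzs(self) -> Tuple[float, ...]:
        return tuple(p[0] for p in self.peaks)

    @property
    def abundances(self) -> Tuple[float, ...]:
        return tuple(p[1] for p in self.peaks)

    @property
    def base_peak_mz(self) -> float:
        """m/z of the most abundant isotopologue."""
        return max(self.peaks, key=lambda p: p[1])[0]

    @property
    def spacing(self) -> float:
        return NEUTRON_SPACING / self.charge


def _element_distribution(element: str, count: int, prune: float) -> Dict[int, float]:
    """Abundance distribution over neutron offsets for `count` atoms of one
    element, by binary-exponentiation convolution with pruning."""
    iso = _ISOTOPE_TABLE[element]
    base_a = iso[0][0]
    one = {}
    for m, ab in iso:
        one[int(round(m - base_a))] = one.get(int(round(m - base_a)), 0.0) + ab

    def conv(a: Dict[int, float], b: Dict[int, float]) -> Dict[int, float]:
        out: Dict[int, float] = {}
        for ka, va in a.items():
            for kb, vb in b.items():
                out[ka + kb] = out.get(ka + kb, 0.0) + va * vb
        if prune > 0:
            top = max(out.values())
            out = {k: v for k, v in out.items() if v >= top * prune}
        return out

    result = {0: 1.0}
    power = dict(one)
    k = count
    while k:
        if k & 1:
            result = conv(result, power)
        k >>= 1
        if k:
            power = conv(power, power)
    return result


def isotope_envelope(
    comp: ElementalComposition,
    n: int = 1,
    z: int = 1,
    min_abundance: float = 1e-4,
    prune: float = 1e-10,
) -> IsotopeEnvelope:
    """Isotopologue envelope of the n-mer of ``comp`` at charge z.

    Computed by per-element convolution of isotope distributions, aggregated
    by total neutron count.  Peak k is placed at
    ``(mono_mass + k * 1.0033548 + z * m_proton) / z``; i.e. the small mass
    defects between isotopic substitutions (13C vs 15N vs 2H) are collapsed
    onto the carbon comb, an approximation good to < 1 mTh per neutron for
    peptide compositions.  The envelope is truncated at ``min_abundance``
    (relative to unit total) and renormalised.
    """
    if not comp or comp.total_atoms() == 0:
        raise ValueError("cannot build an isotope envelope of an empty composition")
    if n < 1 or z < 1:
        raise ValueError("n and z must be >= 1")
    if not (0 < min_abundance < 1):
        raise ValueError("min_abundance must lie strictly between 0 and 1")

    full = comp * n if n > 1 else comp
    dist = {0: 1.0}
    for el, cnt in sorted(full.items()):
        edist = _element_distribution(el, cnt, prune)
        new: Dict[int, float] = {}
        for ka, va in dist.items():
            for kb, vb in edist.items():
                new[ka + kb] = new.get(ka + kb, 0.0) + va * vb
        top = max(new.values())
        dist = {k: v for k, v in new.items() if v >= top * prune}

    total = sum(dist.values())
    dist = {k: v / total for k, v in dist.items()}
    keep = {k: v for k, v in dist.items() if v >= min_abundance}
    if not keep:  # degenerate threshold: keep the base peak
        kbest = max(dist, key=dist.get)
        keep = {kbest: dist[kbest]}
    norm = sum(keep.values())
    mono = monoisotopic_mass(full)
    peaks = tuple(
        ((mono + k * NEUTRON_SPACING + z * PROTON_MASS) / z, v / norm)
        for k, v in sorted(keep.items())
    )
    return IsotopeEnvelope(peaks=peaks, charge=z)
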