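"""Synthetic IM-MS datasets with known ground truth.

The generator emulates the signal model of a mobility-quadrupole-ToF
instrument for noncovalent peptide oligomers:

* every species n^z+ contributes its isotopologue envelope crossed with a
  Gaussian mobility profile on a regular grid;
* a configurable fraction of each species dissociates at the
  mobility-cell/multipole interface by *neutral monomer loss*, producing a
  smaller ion at the precursor's mobility, before any mass selection;
* if a quadrupole window is set, only ions whose species m/z falls inside
  it survive; a configurable fraction of the survivors then dissociates in
  the collision cell into charged sub-oligomers, again keeping the
  precursor's mobility, with intensity split between charged products in
  proportion to their charge;
* finally a uniform baseline of scattered noise features is added and peak
  samples are jittered multiplicatively.

Every feature carries a provenance label (intact / interface fragment /
collision-cell fragment / noise), so recovery by the analysis modules can
be scored exactly.  All randomness flows from one seed.

The canonical fixtures written by :func:`make_fixture_suite` plant the
mobility apexes printed for the Ac-PHF6-NH2 m/z 1580 family (1.959, 1.606,
1.416, 1.299 V·s/cm² and the fragment-assigned 1.203 and 1.126); values
that are not printed anywhere (intact monomer, the 13^5+ interface
precursor, TWIMS drift times, abundances) are synthetic choices made for
test robustness and labelled as such.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .mobility import IMMSDataset, write_feature_table
from .oligomers import OligomerIon
from .peptides import (
    PeptideSpec,
    composition_of,
    isotope_envelope,
    monoisotopic_mass,
    oligomer_mz,
    parse_peptide,
)

__all__ = [
    "SpeciesSpec",
    "SimulationConfig",
    "FeatureProvenance",
    "GroundTruth",
    "simulate_dataset",
    "make_fixture_suite",
    "AC_PHF6_NH2",
]

#: The hexapeptide VQIVYK (PHF6) with acetyl/amide caps — the default
#: aggregating monomer for fixtures.
AC_PHF6_NH2 = parse_peptide("Ac-VQIVYK-NH2", name="Ac-PHF6-NH2")


@dataclass(frozen=True)
class SpeciesSpec:
    """One planted oligomer: (n, z), its mobility apex and total abundance."""

    n: int
    z: int
    mobility: float
    abundance: float

    def __post_init__(self):
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")


@dataclass
class SimulationConfig:
    """Full description of one simulated acquisition.

    ``interface_losses`` maps a species (n, z) to [(monomers_lost,
    fraction), ...]; ``collision_pathways`` maps a quad-surviving species
    (n, z) to [((k, c), fraction), ...] where (k, c) is the split-off
    product and (n-k, z-c) its complement.  Fractions are of the species'
    (remaining) total intensity and must sum to <= 1 per species.
    """

    peptide: PeptideSpec
    species: List[SpeciesSpec]
    mobility_sigma: float = 0.008
    interface_losses: Dict[Tuple[int, int], List[Tuple[int, float]]] = field(
        default_factory=dict
    )
    collision_pathways: Dict[
        Tuple[int, int], List[Tuple[Tuple[int, int], float]]
    ] = field(default_factory=dict)
    quad_window: Optional[Tuple[float, float]] = None
    noise_baseline: float = 0.0
    noise_multiplicative_sd: float = 0.0
    n_noise_features: int = 0
    seed: int = 0
    platform: str = "TIMS"
    mobility_axis: str = "inverse_reduced_mobility"
    mobility_range: Tuple[float, float] = (1.0, 2.3)
    mz_range: Tuple[float, float] = (50.0, 3000.0)
    mobility_bin: float = 0.001
    envelope_min_abundance: float = 1e-3

    def __post_init__(self):
        if self.mobility_sigma <= 0:
            raise ValueError("mobility_sigma must be positive")
        for table in (self.interface_losses, self.collision_pathways):
            for key, rows in table.items():
                total = sum(frac for _, frac in rows)
                if not (0.0 <= total <= 1.0):
                    raise ValueError(
                        f"fragmentation fractions for {key} sum to {total}"
                    )

    # -- structured-text round trip -------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "peptide": str(self.peptide),
            "species": [
                {"n": s.n, "z": s.z, "mobility": s.mobility, "abundance": s.abundance}
                for s in self.species
            ],
            "mobility_sigma": self.mobility_sigma,
            "interface_losses": {
                f"{n},{z}": [list(r) for r in rows]
                for (n, z), rows in self.interface_losses.items()
            },
            "collision_pathways": {
                f"{n},{z}": [[list(prod), frac] for prod, frac in rows]
                for (n, z), rows in self.collision_pathways.items()
            },
            "quad_window": list(self.quad_window) if self.quad_window else None,
            "noise_baseline": self.noise_baseline,
            "noise_multiplicative_sd": self.noise_multiplicative_sd,
            "n_noise_features": self.n_noise_features,
            "seed": self.seed,
            "platform": self.platform,
            "mobility_axis": self.mobility_axis,
            "mobility_range": list(self.mobility_range),
            "mz_range": list(self.mz_range),
            "mobility_bin": self.mobility_bin,
            "envelope_min_abundance": self.envelope_min_abundance,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationConfig":
        doc = yaml.safe_load(text)

        def key(s: str) -> Tuple[int, int]:
            a, b = s.split(",")
            return (int(a), int(b))

        return cls(
            peptide=parse_peptide(doc["peptide"]),
            species=[SpeciesSpec(**row) for row in doc["species"]],
            mobility_sigma=doc.get("mobility_sigma", 0.008),
            interface_losses={
                key(k): [tuple(r) for r in rows]
                for k, rows in (doc.get("interface_losses") or {}).items()
            },
            collision_pathways={
                key(k): [(tuple(prod), frac) for prod, frac in rows]
                for k, rows in (doc.get("collision_pathways") or {}).items()
            },
            quad_window=tuple(doc["quad_window"]) if doc.get("quad_window") else None,
            noise_baseline=doc.get("noise_baseline", 0.0),
            noise_multiplicative_sd=doc.get("noise_multiplicative_sd", 0.0),
            n_noise_features=doc.get("n_noise_features", 0),
            seed=doc.get("seed", 0),
            platform=doc.get("platform", "TIMS"),
            mobility_axis=doc.get("mobility_axis", "inverse_reduced_mobility"),
            mobility_range=tuple(doc.get("mobility_range", (1.0, 2.3))),
            mz_range=tuple(doc.get("mz_range", (50.0, 3000.0))),
            mobility_bin=doc.get("mobility_bin", 0.001),
            envelope_min_abundance=doc.get("envelope_min_abundance", 1e-3),
        )


@dataclass(frozen=True)
class FeatureProvenance:
    """Origin of one simulated feature.

    ``kind`` is one of intact / interface_fragment / collision_cell_fragment
    / noise.  ``species`` is the ion the feature's m/z belongs to,
    ``precursor`` the immediate dissociating parent (if any) and ``origin``
    the outermost intact ancestor.
    """

    kind: str
    species: Optional[Tuple[int, int]] = None
    precursor: Optional[Tuple[int, int]] = None
    origin: Optional[Tuple[int, int]] = None

    def as_text(self) -> str:
        def fmt(t):
            return f"{t[0]}:{t[1]}" if t else "-"

        return f"{self.kind}\t{fmt(self.species)}\t{fmt(self.precursor)}\t{fmt(self.origin)}"


@dataclass
class GroundTruth:
    """Per-feature provenance, parallel to the dataset's feature arrays."""

    provenance: List[FeatureProvenance]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tspecies\tprecursor\torigin\n")
            for p in self.provenance:
                fh.write(p.as_text() + "\n")

    def kinds(self) -> List[str]:
        return [p.kind for p in self.provenance]


@dataclass
class _Component:
    """An ion population at one mobility, before rasterisation."""

    n: int
    z: int
    mobility: float
    intensity: float
    provenance: FeatureProvenance


def _apply_interface(
    components: List[_Component],
    losses: Dict[Tuple[int, int], List[Tuple[int, float]]],
) -> List[_Component]:
    out: List[_Component] = []
    for comp in components:
        rows = losses.get((comp.n, comp.z), [])
        moved = 0.0
        for lost, frac in rows:
            if lost < 1 or comp.n - lost < 1 or frac <= 0:
                continue
            out.append(
                _Component(
                    n=comp.n - lost,
                    z=comp.z,
                    mobility=comp.mobility,
                    intensity=comp.intensity * frac,
                    provenance=FeatureProvenance(
                        kind="interface_fragment",
                        species=(comp.n - lost, comp.z),
                        precursor=(comp.n, comp.z),
                        origin=(comp.n, comp.z),
                    ),
                )
            )
            moved += frac
        out.append(replace(comp, intensity=comp.intensity * (1.0 - moved)))
    return out


def _apply_collision(
    components: List[_Component],
    pathways: Dict[Tuple[int, int], List[Tuple[Tuple[int, int], float]]],
) -> List[_Component]:
    out: List[_Component] = []
    for comp in components:
        rows = pathways.get((comp.n, comp.z), [])
        moved = 0.0
        for (k, c), frac in rows:
            nk, zc = comp.n - k, comp.z - c
            if k < 1 or nk < 1 or c < 0 or zc < 0 or frac <= 0:
                continue
            charged = [(k, c)] * (c >= 1) + [(nk, zc)] * (zc >= 1)
            ztot = sum(z for _, z in charged)
            if ztot == 0:
                continue
            origin = comp.provenance.origin or (comp.n, comp.z)
            for nf, zf in charged:
                out.append(
                    _Component(
                        n=nf,
                        z=zf,
                        mobility=comp.mobility,
                        intensity=comp.intensity * frac * zf / ztot,
                        provenance=FeatureProvenance(
                            kind="collision_cell_fragment",
                            species=(nf, zf),
                            precursor=(comp.n, comp.z),
                            origin=origin,
                        ),
                    )
                )
            moved += frac
        out.append(replace(comp, intensity=comp.intensity * (1.0 - moved)))
    return out


def simulate_dataset(config: SimulationConfig) -> Tuple[IMMSDataset, GroundTruth]:
    """Run the instrument model and rasterise it to a feature table.

    Fragmentation redistributes intensity but never creates it; the summed
    feature intensity before noise equals the summed species abundances
    that survive the quadrupole.  Identical configs produce identical
    datasets (the seed drives all randomness).
    """
    rng = np.random.default_rng(config.seed)
    comp_elem = composition_of(config.peptide)
    M = monoisotopic_mass(comp_elem)

    components = [
        _Component(
            n=s.n,
            z=s.z,
            mobility=s.mobility,
            intensity=s.abundance,
            provenance=FeatureProvenance(
                kind="intact", species=(s.n, s.z), origin=(s.n, s.z)
            ),
        )
        for s in config.species
    ]
    components = _apply_interface(components, config.interface_losses)

    if config.quad_window is not None:
        center, half = config.quad_window
        components = [
            c
            for c in components
            if abs(oligomer_mz(M, c.n, c.z) - center) <= half
        ]
        components = _apply_collision(components, config.collision_pathways)

    lo_mob, hi_mob = config.mobility_range
    grid = np.arange(lo_mob, hi_mob + config.mobility_bin / 2, config.mobility_bin)

    mzs: List[float] = []
    mobs: List[float] = []
    intens: List[float] = []
    prov: List[FeatureProvenance] = []
    env_cache: Dict[Tuple[int, int], object] = {}

    for comp in components:
        if comp.intensity <= 0:
            continue
        mz0 = oligomer_mz(M, comp.n, comp.z)
        if not (config.mz_range[0] <= mz0 <= config.mz_range[1]):
            continue
        key = (comp.n, comp.z)
        if key not in env_cache:
            env_cache[key] = isotope_envelope(
                comp_elem,
                n=comp.n,
                z=comp.z,
                min_abundance=config.envelope_min_abundance,
            )
        env = env_cache[key]
        sel = np.abs(grid - comp.mobility) <= 4 * config.mobility_sigma
        if not sel.any():
            continue
        g = np.exp(-0.5 * ((grid[sel] - comp.mobility) / config.mobility_sigma) ** 2)
        g /= g.sum()
        for mz, ab in env.peaks:
            if not (config.mz_range[0] <= mz <= config.mz_range[1]):
                continue
            for mob, w in zip(grid[sel], g):
                mzs.append(mz)
                mobs.append(float(mob))
                intens.append(comp.intensity * ab * w)
                prov.append(comp.provenance)

    intensity = np.array(intens, dtype=float)
    if config.noise_multiplicative_sd > 0 and intensity.size:
        jitter = 1.0 + config.noise_multiplicative_sd * rng.standard_normal(
            intensity.size
        )
        intensity = intensity * np.clip(jitter, 0.0, None)

    if config.noise_baseline > 0 and config.n_noise_features > 0:
        nz = config.n_noise_features
        noise_mz = rng.uniform(config.mz_range[0], config.mz_range[1], nz)
        noise_mob = rng.uniform(lo_mob, hi_mob, nz)
        noise_int = config.noise_baseline * rng.uniform(0.5, 1.5, nz)
        mzs.extend(noise_mz.tolist())
        mobs.extend(noise_mob.tolist())
        intensity = np.concatenate([intensity, noise_int])
        prov.extend([FeatureProvenance(kind="noise")] * nz)

    dataset = IMMSDataset(
        mz=np.array(mzs, dtype=float),
        mobility=np.array(mobs, dtype=float),
        intensity=intensity,
        platform=config.platform,
        mobility_axis=config.mobility_axis,
        quad_window=config.quad_window,
        metadata={"seed": str(config.seed), "peptide": str(config.peptide)},
    )
    return dataset, GroundTruth(provenance=prov)


# ---------------------------------------------------------------------------
# canonical fixtures


def _mz1580_species() -> List[SpeciesSpec]:
    """The m/z 1580 isobaric family with the printed TIMS apexes, plus an
    intact monomer at 2.200 and a 13^5+ interface precursor at 1.320
    (both synthetic positions)."""
    return [
        SpeciesSpec(1, 1, 2.200, 4000.0),
        SpeciesSpec(2, 1, 1.959, 5000.0),
        SpeciesSpec(4, 2, 1.606, 3500.0),
        SpeciesSpec(6, 3, 1.416, 2500.0),
        SpeciesSpec(8, 4, 1.299, 1700.0),
        SpeciesSpec(10, 5, 1.203, 1000.0),
        SpeciesSpec(12, 6, 1.126, 600.0),
        SpeciesSpec(13, 5, 1.320, 500.0),
    ]


def _mz1580_collision() -> Dict[Tuple[int, int], List[Tuple[Tuple[int, int], float]]]:
    return {
        (2, 1): [((1, 1), 0.10)],
        (4, 2): [((1, 1), 0.12)],
        (6, 3): [((1, 1), 0.12)],
        (8, 4): [((1, 1), 0.12)],
        (10, 5): [((1, 1), 0.12), ((2, 2), 0.08)],
        (12, 6): [((1, 1), 0.12)],
    }


def intact_mz1580_config(seed: int = 0) -> SimulationConfig:
    """Intact reference acquisition: no quadrupole selection."""
    return SimulationConfig(
        peptide=AC_PHF6_NH2,
        species=_mz1580_species(),
        quad_window=None,
        noise_baseline=0.01,
        noise_multiplicative_sd=0.01,
        n_noise_features=400,
        seed=seed,
    )


def quad_mz1580_config(seed: int = 0) -> SimulationConfig:
    """Quadrupole-selected m/z 1580 acquisition with both fragmentation
    loci active: collision-cell splits per family member and a 13^5+
    interface chain (loses 3 monomers into the 10^5+ channel)."""
    M = monoisotopic_mass(composition_of(AC_PHF6_NH2))
    return SimulationConfig(
        peptide=AC_PHF6_NH2,
        species=_mz1580_species(),
        interface_losses={(13, 5): [(3, 0.30)]},
        collision_pathways=_mz1580_collision(),
        quad_window=(oligomer_mz(M, 2, 1), 5.0),
        noise_baseline=0.01,
        noise_multiplicative_sd=0.01,
        n_noise_features=400,
        seed=seed,
    )


def twims_mz2369_config(seed: int = 0) -> SimulationConfig:
    """TWIMS acquisition of the m/z 2369 trimer family [3n]^nz+ on a drift
    time axis (drift times synthetic, decreasing with charge)."""
    return SimulationConfig(
        peptide=AC_PHF6_NH2,
        species=[
            SpeciesSpec(3, 1, 9.20, 3000.0),
            SpeciesSpec(6, 2, 7.60, 2000.0),
            SpeciesSpec(9, 3, 6.80, 1200.0),
            SpeciesSpec(12, 4, 6.30, 700.0),
            SpeciesSpec(15, 5, 5.90, 400.0),
        ],
        mobility_sigma=0.08,
        quad_window=None,
        noise_baseline=0.01,
        noise_multiplicative_sd=0.01,
        n_noise_features=300,
        seed=seed,
        platform="TWIMS",
        mobility_axis="drift_time",
        mobility_range=(4.0, 11.0),
        mobility_bin=0.05,
    )


#: Agilent ESI Tuning Mix reference ions used for the TIMS 1/K0 axis.
TIMS_REFERENCE_TABLE: Tuple[Tuple[float, float], ...] = (
    (322.0, 0.732),
    (622.0, 0.985),
    (922.0, 1.190),
    (1222.0, 1.382),
    (1522.0, 1.556),
    (1822.0, 1.729),
    (2122.0, 1.884),
    (2422.0, 2.03),
)

#: Parameters of the synthetic TWIMS calibrant set (power-law ground truth).
TWIMS_SYNTH_SLOPE = 0.52
TWIMS_SYNTH_INTERCEPT = 7.10
TWIMS_SYNTH_EDC = 1.35


def _write_tims_calibrants(prefix: str) -> List[str]:
    ref_path = f"{prefix}.tsv"
    obs_path = f"{prefix}_observed.tsv"
    with open(ref_path, "w") as fh:
        fh.write("#Agilent ESI Tuning Mix reference inverse reduced mobilities\n")
        fh.write("mz\tinv_k0\n")
        for mz, ik in TIMS_REFERENCE_TABLE:
            fh.write(f"{mz!r}\t{ik!r}\n")
    with open(obs_path, "w") as fh:
        fh.write("#synthetic raw-axis positions: raw = 100 + 400*inv_k0 + 5*inv_k0^2\n")
        fh.write("raw_position\tmz\n")
        for mz, ik in TIMS_REFERENCE_TABLE:
            raw = 100.0 + 400.0 * ik + 5.0 * ik**2
            fh.write(f"{raw!r}\t{mz!r}\n")
    return [ref_path, obs_path]


def _write_twims_calibrants(path: str) -> List[str]:
    """Synthetic TWIMS calibrant table generated from a known power law;
    reference CCS values are invented for testing, not literature values."""
    from .peptides import PROTON_MASS

    gas = 28.00615
    rows = []
    for i, (mz, z, ccs) in enumerate(
        [
            (322.0, 1, 153.0),
            (622.0, 1, 202.0),
            (922.0, 1, 243.0),
            (1222.0, 1, 282.0),
            (1522.0, 1, 317.0),
            (785.0, 2, 530.0),
            (1047.0, 2, 610.0),
        ]
    ):
        ion_mass = z * (mz - PROTON_MASS)
        mu = ion_mass * gas / (ion_mass + gas)
        ccs_red = ccs * math.sqrt(mu) / z
        dtp = math.exp((math.log(ccs_red) - TWIMS_SYNTH_INTERCEPT) / TWIMS_SYNTH_SLOPE)
        dt = dtp + TWIMS_SYNTH_EDC * math.sqrt(mz) / 1000.0
        rows.append((mz, z, ccs, dt, f"synthetic_calibrant_{i}"))
    with open(path, "w") as fh:
        fh.write(
            "#synthetic calibrants from ln(ccs') = "
            f"{TWIMS_SYNTH_SLOPE}*ln(dt') + {TWIMS_SYNTH_INTERCEPT}, "
            f"edc = {TWIMS_SYNTH_EDC}\n"
        )
        fh.write("mz\tz\tccs_ref\tdrift_time\tname\n")
        for mz, z, ccs, dt, name in rows:
            fh.write(f"{mz!r}\t{z}\t{ccs!r}\t{dt!r}\t{name}\n")
    return [path]


def make_fixture_suite(output_dir, seed: int = 0) -> Dict[str, List[str]]:
    """Write the canonical fixture set used by tests and docs.

    Returns a mapping fixture name -> written file paths.  Running twice
    with the same seed produces byte-identical files.
    """
    import os

    os.makedirs(output_dir, exist_ok=True)
    out: Dict[str, List[str]] = {}
    for name, cfg in (
        ("intact_mz1580", intact_mz1580_config(seed)),
        ("quad_mz1580", quad_mz1580_config(seed)),
        ("twims_mz2369", twims_mz2369_config(seed)),
    ):
        dataset, truth = simulate_dataset(cfg)
        data_path = os.path.join(output_dir, f"{name}.tsv")
        truth_path = os.path.join(output_dir, f"{name}.truth.tsv")
        config_path = os.path.join(output_dir, f"{name}.config.yaml")
        write_feature_table(dataset, data_path)
        truth.write_tsv(truth_path)
        with open(config_path, "w") as fh:
            fh.write(cfg.to_yaml())
        out[name] = [data_path, truth_path, config_path]
    out["calibrants_tims"] = _write_tims_calibrants(
        os.path.join(output_dir, "calibrants_tims")
    )
    out["calibrants_twims"] = _write_twims_calibrants(
        os.path.join(output_dir, "calibrants_twims.tsv")
    )
    return out
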