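"""Mobility-coincidence assignment of oligomer precursors from their
fragment channels.

Weakly bound peptide oligomers dissociate inside the spectrometer at two
loci.  Fragments formed *after* the mobility cell keep the mobility that
was recorded for their precursor:

* at the mobility-cell/multipole interface (before the quadrupole) an
  oligomer loses neutral monomers, so an ion can enter the selected m/z
  channel while carrying the mobility signature of a larger precursor;
* in the collision cell (after the quadrupole) a mass-selected precursor
  splits into charged sub-oligomers whose m/z moves out of the selection
  window but whose mobility still marks the precursor.

The assignment exploits the second locus: when several predicted fragment
channels of a candidate precursor n^z+ all show an extracted-ion-mobility
apex at the same position, that coincidence pins the precursor's mobility
— e.g. the 1^1+, 8^3+ and 9^4+ channels of a quadrupole-selected m/z 1580
family all peaking at 1/K0 = 1.203 V·s/cm² assign the 10^5+ oligomer.
Residual apexes are then explained as intact species, collision-cell
fragments of other family members, or interface-fragmentation chains from
larger precursors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .mobility import (
    IMMSDataset,
    default_mobility_tol,
    detect_peaks,
    extract_eim,
)
from .oligomers import OligomerIon
from .peptides import ElementalComposition, isotope_envelope, oligomer_mz

__all__ = [
    "FragmentationPathway",
    "ChannelEvidence",
    "ResidualPeak",
    "AssignmentResult",
    "FamilyMonotonicityWarning",
    "enumerate_fragmentations",
    "fragment_channels",
    "interface_fragment_sources",
    "assign_by_coincidence",
]

LOCI = ("tims_multipole_interface", "collision_cell")


class FamilyMonotonicityWarning(UserWarning):
    """Assigned mobilities within one isobaric family should decrease
    strictly with oligomer order (larger n at same m/z means higher charge,
    hence lower 1/K0); raised when an assignment violates this."""


@dataclass(frozen=True)
class FragmentationPathway:
    """A precursor (n, z) split into products; z_i = 0 marks a neutral.

    Monomer count and charge are conserved exactly across the split.
    """

    precursor: OligomerIon
    products: Tuple[Tuple[int, int], ...]
    locus: str = "collision_cell"

    def __post_init__(self):
        if self.locus not in LOCI:
            raise ValueError(f"unknown fragmentation locus {self.locus!r}")
        if any(n < 1 or z < 0 for n, z in self.products):
            raise ValueError("every product must have n >= 1 and z >= 0")
        if sum(n for n, _ in self.products) != self.precursor.n:
            raise ValueError("pathway does not conserve monomer count")
        if sum(z for _, z in self.products) != self.precursor.z:
            raise ValueError("pathway does not conserve charge")

    @property
    def charged_products(self) -> Tuple[Tuple[int, int], ...]:
        return tuple((n, z) for n, z in self.products if z >= 1)


def enumerate_fragmentations(
    precursor: OligomerIon,
    max_losses: Optional[int] = None,
    locus: str = "collision_cell",
) -> List[FragmentationPathway]:
    """All binary dissociations (k, c) + (n-k, z-c) of a precursor,
    deduplicated as unordered product pairs.

    ``max_losses`` restricts the smaller product to at most that many
    monomers (the interface locus is dominated by small neutral losses).
    A monomer precursor has no dissociation pathways.
    """
    n, z = precursor.n, precursor.z
    if n < 2:
        return []
    seen: Set[Tuple[Tuple[int, int], ...]] = set()
    out: List[FragmentationPathway] = []
    for k in range(1, n):
        if max_losses is not None and min(k, n - k) > max_losses:
            continue
        for c in range(0, z + 1):
            pair = tuple(sorted(((k, c), (n - k, z - c))))
            if pair in seen:
                continue
            seen.add(pair)
            out.append(FragmentationPathway(precursor=precursor, products=pair, locus=locus))
    return out


def fragment_channels(
    precursor: OligomerIon, M: float
) -> List[Tuple[Tuple[int, int], float]]:
    """Charged dissociation products of a precursor with their m/z.

    Neutral products are invisible to the mass analyser and excluded.
    Each distinct (n, z) product appears once, sorted by m/z.
    """
    channels: Dict[Tuple[int, int], float] = {}
    for pathway in enumerate_fragmentations(precursor):
        for nf, zf in pathway.charged_products:
            channels.setdefault((nf, zf), oligomer_mz(M, nf, zf))
    return sorted(channels.items(), key=lambda item: item[1])


def interface_fragment_sources(
    target: OligomerIon,
    M: float,
    n_max: int = 25,
    z_max: int = 8,
    max_monomer_loss: int = 3,
) -> List[OligomerIon]:
    """Precursors that reach ``target``'s channel by losing neutral
    monomers at the mobility-cell/multipole interface.

    These carry the same charge but more monomers, hence a larger CCS and
    a higher 1/K0 signature than the target itself.
    """
    if target.z > z_max:
        return []
    upper = min(n_max, target.n + max(0, max_monomer_loss))
    return [
        OligomerIon.from_monomer_mass(M, n, target.z)
        for n in range(target.n + 1, upper + 1)
    ]


# ---------------------------------------------------------------------------
# coincidence assignment


@dataclass(frozen=True)
class ChannelEvidence:
    """One fragment-channel apex supporting an assignment."""

    channel_mz: float
    interpretations: Tuple[Tuple[int, int], ...]
    apex: float
    height: float


@dataclass(frozen=True)
class ResidualPeak:
    """A channel apex not used as coincidence evidence, with its
    classification."""

    channel_mz: float
    interpretations: Tuple[Tuple[int, int], ...]
    apex: float
    height: float
    label: str  # intact | collision_cell_fragment | interface_fragment | unexplained
    attributed_to: Optional[Tuple[int, int]] = None
    candidates: Tuple[Tuple[int, int], ...] = ()


@dataclass
class AssignmentResult:
    """Assigned mobility of one family member with supporting evidence.

    ``mobility`` is None when the coincidence criterion was not met.
    ``residuals`` classifies the extra apexes seen in this precursor's
    predicted channels.
    """

    species: OligomerIon
    mobility: Optional[float]
    evidence: Tuple[ChannelEvidence, ...] = ()
    ambiguous: bool = False
    residuals: Tuple[ResidualPeak, ...] = ()

    @property
    def n_supporting(self) -> int:
        return len(self.evidence)


@dataclass
class _Channel:
    mz: float
    interpretations: Tuple[Tuple[int, int], ...]
    peaks: List  # MobilityPeak


@dataclass
class _Cluster:
    apexes: List[Tuple[float, "_Channel", float]]  # (apex, channel, height)

    @property
    def channels(self) -> List["_Channel"]:
        seen, out = set(), []
        for _, ch, _ in self.apexes:
            if ch.mz not in seen:
                seen.add(ch.mz)
                out.append(ch)
        return out

    @property
    def mobility(self) -> float:
        w = np.array([h for _, _, h in self.apexes])
        x = np.array([a for a, _, _ in self.apexes])
        return float(np.average(x, weights=w)) if w.sum() > 0 else float(x.mean())


def _collect_channels(
    family: Sequence[OligomerIon],
    M: float,
    quad_window: Tuple[float, float],
) -> Tuple[Dict[float, _Channel], Dict[Tuple[int, int], Set[float]]]:
    """Union of predicted fragment channels over the family, grouped by
    m/z (isobaric fragments such as 1^1+ and 2^2+ share one channel), and
    the per-precursor map to its predicted channel keys.

    Channels falling inside the quadrupole window collide with the family
    itself and are excluded from evidence.
    """
    center, halfwidth = quad_window
    channels: Dict[float, Dict] = {}
    predicted: Dict[Tuple[int, int], Set[float]] = {}
    for member in family:
        keyset: Set[float] = set()
        if member.n >= 2:
            for (nf, zf), mz in fragment_channels(member, M):
                if abs(mz - center) <= halfwidth:
                    continue  # indistinguishable from the selected family
                key = round(mz, 2)
                entry = channels.setdefault(key, {"mz": mz, "interp": set()})
                entry["interp"].add((nf, zf))
                keyset.add(key)
        predicted[(member.n, member.z)] = keyset
    built = {
        key: _Channel(
            mz=entry["mz"],
            interpretations=tuple(sorted(entry["interp"])),
            peaks=[],
        )
        for key, entry in channels.items()
    }
    return built, predicted


def _channel_selection(channel: _Channel, comp: Optional[ElementalComposition]):
    """m/z selection for a channel EIM: the union isotope envelope of its
    interpretations when a composition is available, else a fixed window."""
    if comp is None:
        return (channel.mz, 0.5)
    envelopes = [
        isotope_envelope(comp, n=nf, z=zf, min_abundance=1e-3)
        for nf, zf in channel.interpretations
    ]
    return envelopes


def _extract_channel_eim(
    dataset: IMMSDataset,
    channel: _Channel,
    comp: Optional[ElementalComposition],
    bin_width: Optional[float],
):
    selection = _channel_selection(channel, comp)
    if isinstance(selection, list):
        spec = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for env in selection:
                part = extract_eim(dataset, env, bin_width=bin_width)
                if spec is None:
                    spec = part
                elif len(part.intensity) == len(spec.intensity):
                    spec.intensity = np.maximum(spec.intensity, part.intensity)
        return spec
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_eim(dataset, selection, bin_width=bin_width)


def _pick_peaks(spec, min_height_fraction: float, tol: float, noise_snr_min: float):
    """Peak-pick a channel EIM against its own noise floor.

    The floor is the 25th percentile of the positive bins: for a channel
    holding only scattered baseline it sits at the baseline level, so the
    S/N gate removes the spikes; for a channel with real peaks it sits on
    the far Gaussian flanks, far below even weak shoulders.  This keeps
    low shoulders (a published assignment rests on one) while rejecting
    noise-only channels.
    """
    positive = spec.intensity[spec.intensity > 0]
    floor = float(np.percentile(positive, 25)) if positive.size >= 8 else 0.0
    return detect_peaks(
        spec,
        min_height_fraction=min_height_fraction,
        min_separation=tol,
        min_height=noise_snr_min * floor,
    )


def _single_linkage_clusters(
    records: List[Tuple[float, _Channel, float]], tol: float
) -> List[_Cluster]:
    if not records:
        return []
    records = sorted(records, key=lambda r: r[0])
    clusters, current = [], [records[0]]
    for rec in records[1:]:
        if rec[0] - current[-1][0] <= tol:
            current.append(rec)
        else:
            clusters.append(_Cluster(apexes=current))
            current = [rec]
    clusters.append(_Cluster(apexes=current))
    return clusters


def _is_candidate(
    cluster: _Cluster,
    member: OligomerIon,
    predicted: Dict[Tuple[int, int], Set[float]],
    min_channels: int,
) -> bool:
    keys = predicted[(member.n, member.z)]
    chans = cluster.channels
    if len(chans) < min_channels:
        return False
    return all(round(ch.mz, 2) in keys for ch in chans)


def _parsimony_cost(cluster: _Cluster, member: OligomerIon) -> int:
    """Total monomers lost under the cheapest interpretation of each
    cluster channel as a fragment of ``member`` (small splits are the
    dominant dissociation mode)."""
    cost = 0
    for ch in cluster.channels:
        best = None
        for nf, _zf in ch.interpretations:
            if nf < member.n:
                loss = min(nf, member.n - nf)
                best = loss if best is None else min(best, loss)
        cost += best if best is not None else member.n
    return cost


def _intact_mobility_estimates(
    intact_reference: Optional[IMMSDataset],
    ions: Sequence[OligomerIon],
    comp: Optional[ElementalComposition],
    bin_width: Optional[float],
    min_height_fraction: float,
    tol: float,
    noise_snr_min: float,
) -> Dict[Tuple[int, int], float]:
    """Strongest envelope-EIM apex per ion in the reference run (no
    quadrupole).  Family members share a channel m/z, but their
    charge-specific isotopologue combs separate all but the shared
    monoisotopic position."""
    if intact_reference is None or comp is None:
        return {}
    out: Dict[Tuple[int, int], float] = {}
    for member in ions:
        env = isotope_envelope(comp, n=member.n, z=member.z, min_abundance=1e-3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spec = extract_eim(intact_reference, env, bin_width=bin_width)
        if spec.empty_selection:
            continue
        peaks = _pick_peaks(spec, min_height_fraction, tol, noise_snr_min)
        if peaks:
            out[(member.n, member.z)] = max(peaks, key=lambda p: p.height).apex
    return out


def assign_by_coincidence(
    quad_dataset: IMMSDataset,
    M: float,
    family: Sequence[OligomerIon],
    intact_reference: Optional[IMMSDataset] = None,
    tol_mobility: Optional[float] = None,
    min_channels: int = 2,
    comp: Optional[ElementalComposition] = None,
    bin_width: Optional[float] = None,
    min_height_fraction: float = 0.01,
    noise_snr_min: float = 5.0,
    n_max: int = 25,
    max_monomer_loss: int = 3,
) -> List[AssignmentResult]:
    """Assign precursor mobilities in a quadrupole-selected dataset from
    the coincidence of fragment-channel EIM apexes.

    For every family member the predicted charged fragment channels are
    extracted and peak-picked; apexes are single-linkage clustered across
    channels within ``tol_mobility``.  A cluster whose channels are all
    predicted fragments of one precursor, with at least ``min_channels``
    distinct channels, assigns that mobility to the precursor.  Contested
    clusters are resolved by iterative sole-contender elimination, then
    minimum-monomer-loss parsimony, then support count; unresolved ties
    are reported on all contenders with an ambiguity flag.  Remaining
    apexes are classified as intact species (via ``intact_reference``),
    collision-cell fragments of other members, interface-fragmentation
    chains from larger precursors, or left unexplained.

    A :class:`FamilyMonotonicityWarning` is emitted when assigned
    mobilities do not decrease strictly with oligomer order.
    """
    if quad_dataset.quad_window is None:
        raise ValueError("quad_dataset must carry a quadrupole selection window")
    family = sorted(family, key=lambda s: (s.n, s.z))
    if not family:
        raise ValueError("family must contain at least one oligomer ion")
    if tol_mobility is None:
        tol_mobility = default_mobility_tol(quad_dataset.mobility_axis)

    channels, predicted = _collect_channels(family, M, quad_dataset.quad_window)

    records: List[Tuple[float, _Channel, float]] = []
    for channel in channels.values():
        spec = _extract_channel_eim(quad_dataset, channel, comp, bin_width)
        if spec is None or spec.empty_selection:
            continue
        channel.peaks = _pick_peaks(
            spec, min_height_fraction, tol_mobility, noise_snr_min
        )
        for peak in channel.peaks:
            records.append((peak.apex, channel, peak.height))

    clusters = _single_linkage_clusters(records, tol_mobility)

    # --- resolution: sole-contender cascade, then parsimony/support ---
    assigned: Dict[Tuple[int, int], Tuple[_Cluster, bool]] = {}
    live_clusters = [
        c for c in clusters if any(_is_candidate(c, m, predicted, min_channels) for m in family)
    ]
    while True:
        unassigned = [m for m in family if (m.n, m.z) not in assigned]
        open_clusters = [c for c in live_clusters if c not in
                         [cl for cl, _ in assigned.values()]]
        if not open_clusters or not unassigned:
            break
        contenders = {
            id(c): [m for m in unassigned if _is_candidate(c, m, predicted, min_channels)]
            for c in open_clusters
        }
        open_clusters = [c for c in open_clusters if contenders[id(c)]]
        if not open_clusters:
            break
        progress = False
        # members that are the sole contender of >= 1 open cluster
        for member in unassigned:
            sole = [
                c for c in open_clusters
                if contenders[id(c)] == [member]
            ]
            if sole:
                best = max(sole, key=lambda c: (len(c.channels), sum(h for _, _, h in c.apexes)))
                assigned[(member.n, member.z)] = (best, False)
                progress = True
                break
        if progress:
            continue
        # contested resolution on the strongest cluster
        target = max(open_clusters, key=lambda c: (len(c.channels), sum(h for _, _, h in c.apexes)))
        cands = contenders[id(target)]
        costs = {(m.n, m.z): _parsimony_cost(target, m) for m in cands}
        best_cost = min(costs.values())
        finalists = [m for m in cands if costs[(m.n, m.z)] == best_cost]
        if len(finalists) > 1:
            support = {
                (m.n, m.z): sum(
                    1 for ch in target.channels if round(ch.mz, 2) in predicted[(m.n, m.z)]
                )
                for m in finalists
            }
            top = max(support.values())
            finalists = [m for m in finalists if support[(m.n, m.z)] == top]
        ambiguous = len(finalists) > 1
        for m in finalists:
            assigned[(m.n, m.z)] = (target, ambiguous)

    # --- residual classification ---
    assigned_cluster_ids = {id(cl) for cl, _ in assigned.values()}
    known_mobility: Dict[Tuple[int, int], float] = {
        key: cl.mobility for key, (cl, _) in assigned.items()
    }
    source_pool: Dict[Tuple[int, int], OligomerIon] = {}
    for member in family:
        for src_ion in interface_fragment_sources(
            member, M, n_max=n_max, max_monomer_loss=max_monomer_loss
        ):
            source_pool.setdefault((src_ion.n, src_ion.z), src_ion)
    pool = list(family) + [
        ion for key, ion in sorted(source_pool.items())
        if key not in {(m.n, m.z) for m in family}
    ]
    intact_estimates = _intact_mobility_estimates(
        intact_reference, pool, comp, bin_width, min_height_fraction,
        tol_mobility, noise_snr_min,
    )
    for key, mob in intact_estimates.items():
        known_mobility.setdefault(key, mob)

    # apexes of intact (non-family) species in each channel, from the
    # reference run without quadrupole selection
    intact_channel_apexes: Dict[float, List[float]] = {}
    if intact_reference is not None:
        for key, channel in channels.items():
            spec = _extract_channel_eim(intact_reference, channel, comp, bin_width)
            if spec is None or spec.empty_selection:
                continue
            intact_channel_apexes[key] = [
                p.apex
                for p in _pick_peaks(spec, min_height_fraction, tol_mobility,
                                     noise_snr_min)
            ]

    residuals: List[ResidualPeak] = []
    for cluster in clusters:
        if id(cluster) in assigned_cluster_ids:
            continue
        for apex, channel, height in cluster.apexes:
            key = round(channel.mz, 2)
            label, attributed, candidates = "unexplained", None, ()
            # (1) intact species of this channel's own m/z
            if any(
                abs(apex - a) <= tol_mobility
                for a in intact_channel_apexes.get(key, ())
            ):
                label = "intact"
            else:
                # (2) collision-cell fragment of a family member at a known mobility
                hits = [
                    mk
                    for mk, mob in known_mobility.items()
                    if key in predicted.get(mk, set()) and abs(apex - mob) <= tol_mobility
                ]
                if hits:
                    label = "collision_cell_fragment"
                    attributed = min(hits)
                else:
                    # (3) interface chain: larger precursor -> in-window species
                    # -> this channel; its apex sits above the assigned mobility
                    chain_sources: List[Tuple[int, int]] = []
                    for member in family:
                        mk = (member.n, member.z)
                        if key not in predicted.get(mk, set()):
                            continue
                        base = known_mobility.get(mk)
                        if base is None or apex <= base + tol_mobility:
                            continue
                        for src in interface_fragment_sources(
                            member, M, n_max=n_max, max_monomer_loss=max_monomer_loss
                        ):
                            chain_sources.append((src.n, src.z))
                    if chain_sources:
                        candidates = tuple(sorted(set(chain_sources)))
                        named = [
                            c
                            for c in candidates
                            if c in intact_estimates
                            and abs(apex - intact_estimates[c]) <= tol_mobility
                        ]
                        if named:
                            label = "interface_fragment"
                            attributed = named[0]
                        elif intact_reference is None:
                            # cannot verify the chain without a reference
                            # run; report the candidates as-is
                            label = "interface_fragment"
                        else:
                            candidates = ()
            residuals.append(
                ResidualPeak(
                    channel_mz=channel.mz,
                    interpretations=channel.interpretations,
                    apex=apex,
                    height=height,
                    label=label,
                    attributed_to=attributed,
                    candidates=candidates,
                )
            )

    # --- build results ordered by n ---
    results: List[AssignmentResult] = []
    for member in family:
        key = (member.n, member.z)
        if key in assigned:
            cluster, ambiguous = assigned[key]
            evidence = tuple(
                ChannelEvidence(
                    channel_mz=ch.mz,
                    interpretations=ch.interpretations,
                    apex=apex,
                    height=height,
                )
                for apex, ch, height in cluster.apexes
            )
            results.append(
                AssignmentResult(
                    species=member,
                    mobility=cluster.mobility,
                    evidence=evidence,
                    ambiguous=ambiguous,
                    residuals=tuple(
                        r for r in residuals if round(r.channel_mz, 2) in predicted[key]
                    ),
                )
            )
        else:
            results.append(
                AssignmentResult(
                    species=member,
                    mobility=None,
                    residuals=tuple(
                        r for r in residuals if round(r.channel_mz, 2) in predicted[key]
                    ),
                )
            )

    seq = [(r.species.n, r.mobility) for r in results if r.mobility is not None]
    if any(b[1] >= a[1] for a, b in zip(seq, seq[1:])):
        warnings.warn(
            "assigned mobilities are not strictly decreasing with oligomer "
            f"order within the family: {seq}",
            FamilyMonotonicityWarning,
            stacklevel=2,
        )
    return results
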