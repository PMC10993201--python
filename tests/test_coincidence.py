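"""Fragmentation pathway enumeration and mobility-coincidence assignment."""

import warnings

import numpy as np
import pytest

import oligomob as om
from oligomob.coincidence import FamilyMonotonicityWarning
from oligomob.mobility import IMMSDataset
from oligomob.simulate import (
    SimulationConfig,
    SpeciesSpec,
    intact_mz1580_config,
    quad_mz1580_config,
    simulate_dataset,
)


def ion(M, n, z):
    return om.OligomerIon.from_monomer_mass(M, n, z)


# ---------------------------------------------------------------------------
# pathway enumeration


def test_pathways_conserve_n_and_z_exhaustively(M):
    """Every enumerated split conserves monomer count and charge for all
    precursors up to (25, 8)."""
    for n in range(2, 26):
        for z in range(1, 9):
            for pw in om.enumerate_fragmentations(ion(M, n, z)):
                assert sum(p[0] for p in pw.products) == n
                assert sum(p[1] for p in pw.products) == z
                assert all(p[0] >= 1 for p in pw.products)


def test_pathway_count_matches_counting_oracle(M):
    """The number of deduplicated binary splits equals the count of
    unordered {(k,c),(n-k,z-c)} pairs enumerated independently."""
    for n in range(2, 9):
        for z in range(1, 5):
            oracle = {
                tuple(sorted(((k, c), (n - k, z - c))))
                for k in range(1, n)
                for c in range(0, z + 1)
            }
            assert len(om.enumerate_fragmentations(ion(M, n, z))) == len(oracle)


def test_monomer_has_no_pathways(M):
    assert om.enumerate_fragmentations(ion(M, 1, 1)) == []


def test_dimer_single_pathway(M):
    pathways = om.enumerate_fragmentations(ion(M, 2, 1))
    assert [pw.products for pw in pathways] == [((1, 0), (1, 1))]


def test_10_5_includes_published_splits(M):
    products = {pw.products for pw in om.enumerate_fragmentations(ion(M, 10, 5))}
    assert tuple(sorted(((1, 1), (9, 4)))) in products
    assert tuple(sorted(((2, 2), (8, 3)))) in products
    assert tuple(sorted(((1, 0), (9, 5)))) in products


def test_12_6_includes_monomer_loss_split(M):
    products = {pw.products for pw in om.enumerate_fragmentations(ion(M, 12, 6))}
    assert tuple(sorted(((1, 1), (11, 5)))) in products


def test_max_losses_restricts_small_product(M):
    for pw in om.enumerate_fragmentations(ion(M, 10, 5), max_losses=2):
        assert min(p[0] for p in pw.products) <= 2


# ---------------------------------------------------------------------------
# fragment channels


def test_channels_of_10_5_hit_printed_mz(M):
    channels = dict(om.fragment_channels(ion(M, 10, 5), M))
    assert channels[(1, 1)] == pytest.approx(790.48, abs=0.01)
    assert channels[(8, 3)] == pytest.approx(2106.27, abs=0.01)
    assert channels[(9, 4)] == pytest.approx(1777.33, abs=0.01)


def test_channels_of_12_6_include_11_5(M):
    channels = dict(om.fragment_channels(ion(M, 12, 6), M))
    assert channels[(11, 5)] == pytest.approx(1737.85, abs=0.01)


def test_dimer_has_single_channel(M):
    channels = om.fragment_channels(ion(M, 2, 1), M)
    assert [c for c, _ in channels] == [(1, 1)]


def test_channels_exclude_neutrals(M):
    for (nf, zf), _ in om.fragment_channels(ion(M, 10, 5), M):
        assert zf >= 1


# ---------------------------------------------------------------------------
# interface sources


def test_interface_sources_examples(M):
    sources = om.interface_fragment_sources(ion(M, 10, 5), M, max_monomer_loss=3)
    assert [(s.n, s.z) for s in sources] == [(11, 5), (12, 5), (13, 5)]
    sources = om.interface_fragment_sources(ion(M, 1, 1), M, max_monomer_loss=3)
    assert [(s.n, s.z) for s in sources] == [(2, 1), (3, 1), (4, 1)]
    assert om.interface_fragment_sources(ion(M, 10, 5), M, max_monomer_loss=0) == []


def test_interface_sources_respect_n_max(M):
    sources = om.interface_fragment_sources(
        ion(M, 24, 8), M, n_max=25, max_monomer_loss=3
    )
    assert [(s.n, s.z) for s in sources] == [(25, 8)]


# ---------------------------------------------------------------------------
# coincidence assignment on the canonical fixture


@pytest.fixture(scope="module")
def fixture_assignments(M, phf6_comp, mz1580_family):
    quad, _ = simulate_dataset(quad_mz1580_config(seed=0))
    ref, _ = simulate_dataset(intact_mz1580_config(seed=0))
    with warnings.catch_warnings():
        warnings.simplefilter("error", FamilyMonotonicityWarning)
        results = om.assign_by_coincidence(
            quad, M, mz1580_family, intact_reference=ref, comp=phf6_comp
        )
    return {(r.species.n, r.species.z): r for r in results}


def test_10_5_assigned_at_1203_with_three_channels(fixture_assignments):
    r = fixture_assignments[(10, 5)]
    assert r.mobility == pytest.approx(1.203, abs=0.01)
    assert r.n_supporting == 3
    interp = {i for e in r.evidence for i in e.interpretations}
    assert {(1, 1), (8, 3), (9, 4)} <= interp


def test_12_6_assigned_at_1126_via_11_5_channel(fixture_assignments):
    r = fixture_assignments[(12, 6)]
    assert r.mobility == pytest.approx(1.126, abs=0.01)
    interp = {i for e in r.evidence for i in e.interpretations}
    assert (11, 5) in interp


def test_intermediate_members_assigned_in_order(fixture_assignments):
    expected = {(4, 2): 1.606, (6, 3): 1.416, (8, 4): 1.299}
    for key, mob in expected.items():
        assert fixture_assignments[key].mobility == pytest.approx(mob, abs=0.01)


def test_interface_chain_attributed_to_13_5(fixture_assignments):
    """The asterisk peaks at 1.32 in the 8^3+/9^4+ channels trace back to
    the 13^5+ precursor that lost three monomers at the interface."""
    r = fixture_assignments[(10, 5)]
    interface = [p for p in r.residuals if p.label == "interface_fragment"]
    assert interface
    assert all(p.attributed_to == (13, 5) for p in interface)
    assert all(p.apex > r.mobility for p in interface)


def test_monomer_fragment_of_dimer_classified(fixture_assignments):
    """The 1^1+ channel apex at the dimer's mobility is recognised as a
    collision-cell fragment of 2^1+, not evidence for a larger species."""
    r = fixture_assignments[(2, 1)]
    assert r.mobility is None  # only one charged channel: below min_channels
    hits = [p for p in r.residuals if p.label == "collision_cell_fragment"]
    assert any(p.attributed_to == (2, 1) and abs(p.apex - 1.959) < 0.01 for p in hits)


def test_assign_requires_quad_window(M, mz1580_family, intact_reference_dataset):
    with pytest.raises(ValueError, match="quad"):
        om.assign_by_coincidence(intact_reference_dataset[0], M, mz1580_family)


def test_assign_rejects_empty_family(M, quad1580_dataset):
    with pytest.raises(ValueError, match="family"):
        om.assign_by_coincidence(quad1580_dataset[0], M, [])


# ---------------------------------------------------------------------------
# negative controls and property-style checks


def _gaussian_features(entries, sigma=0.008):
    grid = np.arange(1.0, 2.3, 0.001)
    mzs, mobs, ints = [], [], []
    for mz, center, height in entries:
        sel = np.abs(grid - center) <= 4 * sigma
        g = np.exp(-0.5 * ((grid[sel] - center) / sigma) ** 2)
        mzs.extend([mz] * int(sel.sum()))
        mobs.extend(grid[sel].tolist())
        ints.extend((height * g).tolist())
    return np.array(mzs), np.array(mobs), np.array(ints)


def test_inconsistent_channel_mobilities_yield_no_assignment(M, mz1580_family):
    """Fragment channels planted at mutually inconsistent mobilities never
    reach the two-channel coincidence requirement."""
    mzs, mobs, ints = _gaussian_features(
        [
            (om.oligomer_mz(M, 9, 4), 1.20, 50.0),
            (om.oligomer_mz(M, 8, 3), 1.45, 50.0),
            (om.oligomer_mz(M, 1, 1), 1.70, 50.0),
        ]
    )
    quad = IMMSDataset(
        mz=mzs, mobility=mobs, intensity=ints,
        quad_window=(om.oligomer_mz(M, 2, 1), 5.0),
    )
    results = om.assign_by_coincidence(quad, M, mz1580_family)
    assert all(r.mobility is None for r in results)
    labels = {p.label for r in results for p in r.residuals}
    assert labels == {"unexplained"}


def _recovery_config(seed):
    """Random decreasing family mobilities with monomer-loss collision
    pathways: every member with two charged channels must be recovered."""
    rng = np.random.default_rng(1000 + seed)
    members = [(2, 1), (4, 2), (6, 3), (8, 4), (10, 5), (12, 6)]
    mobility = 1.95 - np.concatenate([[0], np.cumsum(rng.uniform(0.05, 0.12, 5))])
    species = [
        SpeciesSpec(n, z, float(m), float(rng.uniform(500, 3000)))
        for (n, z), m in zip(members, mobility)
    ]
    pathways = {(n, z): [((1, 1), 0.15)] for (n, z) in members}
    M = om.monoisotopic_mass(om.composition_of(om.AC_PHF6_NH2))
    return SimulationConfig(
        peptide=om.AC_PHF6_NH2,
        species=species,
        collision_pathways=pathways,
        quad_window=(om.oligomer_mz(M, 2, 1), 5.0),
        noise_baseline=0.01,
        noise_multiplicative_sd=0.01,
        n_noise_features=300,
        seed=seed,
    ), {(n, z): float(m) for (n, z), m in zip(members, mobility)}


def test_planted_precursors_recovered_across_seeds(M, phf6_comp, mz1580_family):
    """At least 95% of precursors with >= 2 detectable fragment channels
    are assigned within tolerance over seeds 0-19."""
    recovered = total = 0
    for seed in range(20):
        config, truth = _recovery_config(seed)
        quad, _ = simulate_dataset(config)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = om.assign_by_coincidence(
                quad, M, mz1580_family, comp=phf6_comp
            )
        for r in results:
            key = (r.species.n, r.species.z)
            if key == (2, 1):  # single charged channel: out of scope
                continue
            total += 1
            if r.mobility is not None and abs(r.mobility - truth[key]) <= 0.01:
                recovered += 1
    assert total == 100
    assert recovered / total >= 0.95


def test_zero_fragmentation_yields_zero_assignments(M, phf6_comp, mz1580_family):
    """Without fragmentation there is no channel signal, hence no
    coincidence and no false assignment."""
    for seed in range(5):
        config, _ = _recovery_config(seed)
        config.collision_pathways = {}
        quad, _ = simulate_dataset(config)
        results = om.assign_by_coincidence(quad, M, mz1580_family, comp=phf6_comp)
        assert all(r.mobility is None for r in results)


def test_monotonicity_warning_fires_on_planted_inversion(M, phf6_comp, mz1580_family):
    """Swapping two planted mobilities produces an assignment sequence
    that violates the family ordering and must raise the warning."""
    config, _ = _recovery_config(0)
    species = list(config.species)
    i6 = next(i for i, s in enumerate(species) if (s.n, s.z) == (6, 3))
    i8 = next(i for i, s in enumerate(species) if (s.n, s.z) == (8, 4))
    species[i6], species[i8] = (
        SpeciesSpec(6, 3, species[i8].mobility, species[i6].abundance),
        SpeciesSpec(8, 4, species[i6].mobility, species[i8].abundance),
    )
    config.species = species
    quad, _ = simulate_dataset(config)
    with pytest.warns(FamilyMonotonicityWarning):
        om.assign_by_coincidence(quad, M, mz1580_family, comp=phf6_comp)
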