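"""Rotatable-dihedral selection, random conformer generation, deduplication."""

import numpy as np
import pytest
from scipy import stats

from anomerthermo.chem_core import measure_dihedral
from anomerthermo.errors import DegeneratePlanError
from anomerthermo.sampling import (
    Conformer,
    SamplingPlan,
    deduplicate_minima,
    generate_conformers,
    select_rotatable_dihedrals,
)
from anomerthermo.synthetic import toy_molecule


@pytest.mark.parametrize(
    "kind, expected",
    [("toy-furanose", 5), ("toy-deoxyfuranose", 4), ("methanol", 1), ("water", 0)],
)
def test_rotatable_dihedral_counts(kind, expected):
    """Ribofuranose-like: 4 hydroxyl + beta = 5; 2'-deoxy: 3 + beta = 4."""
    geom, _ = toy_molecule(kind)
    assert len(select_rotatable_dihedrals(geom)) == expected


def test_selector_matches_declared_sets():
    for kind in ("toy-furanose", "toy-deoxyfuranose", "methanol", "toy-phosphate"):
        geom, declared = toy_molecule(kind)
        selected = select_rotatable_dihedrals(geom)
        assert [s.indices for s in selected] == [s.indices for s in declared]


def test_unknown_rule_rejected(furanose):
    with pytest.raises(ValueError):
        select_rotatable_dihedrals(furanose[0], rule="all_torsions")


def test_generation_count_and_determinism(furanose):
    geom, dihedrals = furanose
    plan = SamplingPlan(tuple(dihedrals), 50, seed=11)
    first = generate_conformers(geom, plan)
    second = generate_conformers(geom, plan)
    assert len(first) == 50
    assert all(a.dihedrals == b.dihedrals for a, b in zip(first, second))
    assert all(np.array_equal(a.geometry.coords, b.geometry.coords) for a, b in zip(first, second))
    # achieved torsions equal the drawn ones
    for c in first[:5]:
        for spec, want in zip(dihedrals, c.dihedrals):
            assert measure_dihedral(c.geometry, spec) == pytest.approx(want, abs=1e-6)


def test_generation_does_not_mutate_input(furanose):
    geom, dihedrals = furanose
    before = geom.coords.copy()
    generate_conformers(geom, SamplingPlan(tuple(dihedrals), 5, seed=0))
    assert np.array_equal(geom.coords, before)


def test_empty_plan_rejected():
    geom, _ = toy_molecule("water")
    with pytest.raises(DegeneratePlanError):
        generate_conformers(geom, SamplingPlan((), 2, seed=0))


def test_dihedral_distribution_uniform():
    """10,000 draws of one torsion pass a 12-bin chi-square test at α=0.001."""
    geom, _ = toy_molecule("methanol")
    dihedrals = select_rotatable_dihedrals(geom)
    plan = SamplingPlan(tuple(dihedrals), 10_000, seed=2024)
    rng = np.random.default_rng(plan.seed)
    angles = rng.uniform(-180.0, 180.0, size=(plan.n_samples, 1))  # the sampling law
    sampled = np.array([c.dihedrals[0] for c in generate_conformers(geom, plan)])
    assert np.array_equal(sampled, angles[:, 0])  # generator draws exactly this law
    counts, _ = np.histogram(sampled, bins=12, range=(-180.0, 180.0))
    chi2 = ((counts - len(sampled) / 12) ** 2 / (len(sampled) / 12)).sum()
    assert chi2 < stats.chi2.ppf(1 - 0.001, df=11)


def _conf(dihedrals, energy, index=0):
    geom, _ = toy_molecule("water")
    return Conformer(geometry=geom, dihedrals=tuple(dihedrals), energy=energy, sample_index=index)


def test_dedup_identical_copies_merge():
    confs = [_conf((10.0, 20.0), 1.0, i) for i in range(7)]
    assert len(deduplicate_minima(confs)) == 1


def test_dedup_distinct_torsions_kept():
    confs = [_conf((10.0,), 1.0, 0), _conf((130.0,), 1.0, 1)]
    assert len(deduplicate_minima(confs)) == 2


def test_dedup_periodic_wrap():
    confs = [_conf((-179.0,), 1.0, 0), _conf((179.0,), 1.0, 1)]
    assert len(deduplicate_minima(confs)) == 1  # 2° apart across the ±180° seam


def test_dedup_requires_energies():
    with pytest.raises(ValueError):
        deduplicate_minima([_conf((0.0,), None)])


def _pairwise_oracle(confs, etol, dtol):
    """Brute-force single-linkage clustering by exhaustive pair scan."""
    n = len(confs)
    labels = list(range(n))

    def wrap(d):
        return abs((d + 180.0) % 360.0 - 180.0)

    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                same = abs(confs[i].energy - confs[j].energy) <= etol and all(
                    wrap(a - b) <= dtol for a, b in zip(confs[i].dihedrals, confs[j].dihedrals)
                )
                if same and labels[i] != labels[j]:
                    new = min(labels[i], labels[j])
                    labels[i] = labels[j] = new
                    changed = True
    return len(set(labels))


def test_dedup_planted_centroids(rng):
    """50 conformers jittered around 3 planted centroids collapse to 3 minima."""
    centroids = [(-60.0, 60.0), (60.0, 180.0), (180.0, -60.0)]
    energies = [0.0, 1.0, 2.0]
    confs = []
    for i in range(50):
        k = i % 3
        jitter = rng.uniform(-5.0, 5.0, size=2)
        confs.append(
            _conf(tuple(np.array(centroids[k]) + jitter), energies[k] + rng.uniform(0, 0.02), i)
        )
    unique = deduplicate_minima(confs, energy_tol=0.1, dihedral_tol=15.0)
    assert len(unique) == 3
    assert len(unique) == _pairwise_oracle(confs, 0.1, 15.0)
    # representatives are the lowest-energy members, ascending
    assert [round(c.energy) for c in unique] == [0, 1, 2]


def test_dedup_idempotent_and_merge_count(rng):
    for trial in range(5):
        confs = [
            _conf((float(rng.uniform(-180, 180)),), float(rng.uniform(0, 1.5)), i)
            for i in range(rng.integers(5, 30))
        ]
        once = deduplicate_minima(confs)
        twice = deduplicate_minima(once)
        assert [c.sample_index for c in once] == [c.sample_index for c in twice]
        assert len(once) == _pairwise_oracle(confs, 0.1, 15.0)
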