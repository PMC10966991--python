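"""Trajectory observables: Rg, windowed RMSD, contacts, oligomer clusters."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cdist

from diffmd import analysis as an
from diffmd import synthetic as syn


def test_radius_of_gyration_analytic_cases():
    assert an.radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0
    # two equal masses a distance d apart: Rg = d/2
    f = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    assert an.radius_of_gyration(f, np.ones(2)) == pytest.approx(0.5)
    # four equal masses at unit-square corners (direct formula)
    f = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]])
    com = f.mean(axis=0)
    expected = np.sqrt(np.mean(((f - com) ** 2).sum(axis=1)))
    assert an.radius_of_gyration(f, np.ones(4)) == pytest.approx(expected)
    with pytest.raises(ValueError):
        an.radius_of_gyration(f, np.zeros(4))


def _naive_windowed_rmsd(frames, reference, window):
    """Loop oracle: per-frame Kabsch RMSD then explicit window means."""
    from scipy.spatial.transform import Rotation

    raw = []
    for f in frames:
        mob = f - f.mean(axis=0)
        ref = reference - reference.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref, mob)
        raw.append(np.sqrt(((rot.apply(mob) - ref) ** 2).sum(axis=1).mean()))
    out = []
    for t in range(len(raw)):
        vals = [raw[u] for u in range(max(0, t - window),
                                      min(len(raw), t + window + 1))]
        out.append(np.mean(vals))
    return np.array(out)


def test_windowed_rmsd_zero_for_identical_and_rotated():
    rng = np.random.default_rng(0)
    ref = rng.normal(size=(12, 3))
    q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    frames = [ref.copy(), ref @ q.T + 1.0, ref.copy()]
    t = an.Trajectory(frames=frames)
    out = an.windowed_rmsd(t, ref, window=10)
    assert np.all(out < 1e-7)


def test_windowed_rmsd_matches_loop_oracle():
    rng = np.random.default_rng(1)
    ref = rng.normal(size=(8, 3))
    # alternate between two conformations
    alt = ref + rng.normal(scale=0.2, size=ref.shape)
    frames = [ref.copy() if i % 2 == 0 else alt.copy() for i in range(30)]
    t = an.Trajectory(frames=frames)
    for window in (0, 3, 10):
        ours = an.windowed_rmsd(t, ref, window=window)
        oracle = _naive_windowed_rmsd(frames, ref, window)
        assert np.allclose(ours, oracle, atol=1e-12)
    # window 0 equals the plain per-frame RMSD
    assert np.allclose(an.windowed_rmsd(t, ref, window=0),
                       _naive_windowed_rmsd(frames, ref, 0))


def test_ligand_contact_fraction_rules():
    # residue 0 near the ligand in half the frames, residue 1 always far
    lig = np.array([[0.0, 0, 0]])
    near = np.array([[0.3, 0, 0]])
    far = np.array([[10.0, 0, 0]])
    res1 = np.array([[5.0, 5, 5]])
    frames = []
    for i in range(10):
        r0 = near if i % 2 == 0 else far
        frames.append(np.concatenate([lig, r0, res1]))
    t = an.Trajectory(frames=frames)
    frac = an.ligand_contact_fraction(t, [0], [[1], [2]])
    assert frac[0] == pytest.approx(0.5)
    assert frac[1] == 0.0
    # boundary: exactly at the cutoff is NOT a contact (strict less-than)
    frames = [np.array([[0.0, 0, 0], [0.6, 0, 0]])]
    t = an.Trajectory(frames=frames)
    assert an.ligand_contact_fraction(t, [0], [[1]])[0] == 0.0
    with pytest.raises(ValueError):
        an.ligand_contact_fraction(t, [], [[1]])


def _union_find_oracle(frame, groups, cutoff):
    parent = list(range(len(groups)))

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    for a, b in itertools.combinations(range(len(groups)), 2):
        if cdist(frame[np.asarray(groups[a])],
                 frame[np.asarray(groups[b])]).min() < cutoff:
            parent[find(a)] = find(b)
    sizes = {}
    for a in range(len(groups)):
        sizes[find(a)] = sizes.get(find(a), 0) + 1
    return sorted(sizes.values(), reverse=True)


def test_oligomer_sizes_constructed_cases(registry):
    _, reg = registry
    coords, groups, _ = syn.make_dimer_fixture(5.0, 6, registry=reg)
    assert an.oligomer_sizes(coords, groups) == [1, 1, 1, 1, 1, 1]
    # chain A-B-C where only consecutive pairs touch: one trimer
    coords, groups, _ = syn.make_dimer_fixture(0.3, 3, registry=reg)
    assert an.oligomer_sizes(coords, groups) == [3]
    # two triads separated by a large gap
    coords, groups, _ = syn.make_dimer_fixture(
        0.3, 6, gaps=[0.3, 0.3, 6.0, 0.3, 0.3], registry=reg)
    assert an.oligomer_sizes(coords, groups) == [3, 3]
    with pytest.raises(ValueError):
        an.oligomer_sizes(coords, [groups[0], groups[0]])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 16), st.integers(2, 8))
def test_oligomer_sizes_match_union_find(seed, n_groups):
    rng = np.random.default_rng(seed)
    frame = rng.uniform(0, 2.0, size=(n_groups * 3, 3))
    groups = [np.arange(3) + 3 * g for g in range(n_groups)]
    ours = an.oligomer_sizes(frame, groups, cutoff=0.7)
    assert ours == _union_find_oracle(frame, groups, 0.7)
    assert sum(ours) == n_groups


def test_oligomer_minimum_image_with_box():
    # two peptides touching only across the periodic boundary
    g1 = np.array([[0.1, 0.5, 0.5]])
    g2 = np.array([[4.9, 0.5, 0.5]])
    frame = np.concatenate([g1, g2])
    assert an.oligomer_sizes(frame, [[0], [1]], cutoff=0.4) == [1, 1]
    assert an.oligomer_sizes(frame, [[0], [1]], cutoff=0.4, box=5.0) == [2]


def test_rg_series_on_simulation(registry, tripeptide):
    from diffmd import dynamics as dyn, topology as topo
    vec, _ = registry
    cfg = topo.SimulationConfig(n_steps=200, record_interval=20,
                                checkpoint_interval=100, seed=2)
    record, _ = dyn.simulate_with_checkpoints(tripeptide, vec, cfg)
    traj = an.Trajectory.from_record(record, tripeptide)
    rg = an.rg_series(traj)
    assert rg.shape == (10,)
    assert np.all((rg > 0.1) & (rg < 2.0))
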