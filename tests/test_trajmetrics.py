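"""Trajectory observables: closed forms, parameter recovery, invariances."""

import numpy as np
import pytest
from scipy.optimize import minimize

import lipoflex as lf
from lipoflex import trajmetrics as tm
from lipoflex.geometry import rotation_about
from lipoflex.structure import Atom, StructureModel, Trajectory


def _ca_model(coords, res_names=None):
    atoms = [Atom(i + 1, "CA", "C",
                  (res_names[i] if res_names else "GLY"), i + 1, "A", c)
             for i, c in enumerate(coords)]
    return StructureModel(atoms)


@pytest.fixture(scope="module")
def cube():
    pts = np.array(np.meshgrid([-1, 1], [-1, 1], [-1, 1])).T.reshape(-1, 3)
    return _ca_model(pts.astype(float))


# ------------------------------------------------------------- superposition

def test_kabsch_identity_and_exact_recovery():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(12, 3))
    R, t, r = tm.kabsch_superpose(X, X)
    assert np.allclose(R, np.eye(3))
    assert r == pytest.approx(0.0, abs=1e-12)
    Q = rotation_about([1.0, 2.0, 3.0], 0.9)
    Y = X @ Q.T + np.array([4.0, -1.0, 2.0])
    _, _, r2 = tm.kabsch_superpose(Y, X)
    assert r2 <= 1e-9
    assert np.linalg.det(tm.kabsch_superpose(Y, X)[0]) == pytest.approx(1.0)


def test_kabsch_matches_numeric_minimisation():
    """The analytic optimum equals a brute-force minimisation over rotation
    angles on a 4-point problem with a known 1 A discrepancy."""
    ref = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
    mobile = ref.copy()
    mobile[3, 2] += 1.0
    _, _, r_kabsch = tm.kabsch_superpose(mobile, ref)

    def cost(p):
        R = (rotation_about([1, 0, 0], p[0]) @ rotation_about([0, 1, 0], p[1])
             @ rotation_about([0, 0, 1], p[2]))
        moved = (mobile - mobile.mean(0)) @ R.T + ref.mean(0) + p[3:]
        return np.sqrt(((moved - ref) ** 2).sum(axis=1).mean())

    best = min(minimize(cost, x0, method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000}).fun
               for x0 in (np.zeros(6), np.array([0.3, -0.2, 0.1, 0.1, 0, 0])))
    assert r_kabsch == pytest.approx(best, abs=1e-6)


def test_kabsch_degenerate_geometry_raises():
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(ValueError, match="collinear"):
        tm.kabsch_superpose(line + 0.0, line)
    with pytest.raises(ValueError, match="3 points"):
        tm.kabsch_superpose(line[:2], line[:2])


# --------------------------------------------------------------------- RMSD

def test_rmsd_zero_for_rigid_rotations(cube):
    frames = [cube.coords]
    for k in range(1, 5):
        frames.append(cube.coords @ rotation_about([1, 1, 0], 0.3 * k).T + k)
    traj = Trajectory(cube, np.array(frames))
    assert np.abs(tm.rmsd_series(traj)).max() <= 1e-9


def test_rmsd_mean_matches_harmonic_expectation(toy):
    sigma = 0.5
    traj = lf.make_harmonic_trajectory(toy, lf.MotionSpec(sigmas=sigma,
                                                          n_frames=400, seed=2))
    series = tm.rmsd_series(traj)
    # deviation of one iid frame from the (equally noisy) reference frame:
    # variance doubles, so RMSD -> sigma*sqrt(6) for many residues
    # (superposition removes a few d.o.f., hence the 5% band)
    assert series[1:].mean() == pytest.approx(sigma * np.sqrt(6), rel=0.05)


def test_rmsd_empty_selection(cube):
    traj = Trajectory(cube, cube.coords[None])
    with pytest.raises(ValueError, match="selection"):
        tm.rmsd_series(traj, selection="CB")


# --------------------------------------------------------------------- RMSF

def test_rmsf_static_zero_and_single_frame_error(cube):
    traj = Trajectory(cube, np.repeat(cube.coords[None], 4, axis=0))
    prof = tm.rmsf_profile(traj)
    assert max(prof.rmsf.values()) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="two frames"):
        tm.rmsf_profile(Trajectory(cube, cube.coords[None]))


def test_rmsf_gaussian_recovery_and_ratio(toy):
    n_res = len(toy.residues)
    sigmas = np.full(n_res, 0.5)
    sigmas[10] = 1.0
    traj = lf.make_harmonic_trajectory(toy, lf.MotionSpec(sigmas=sigmas,
                                                          n_frames=2000, seed=4))
    prof = tm.rmsf_profile(traj, fit=False)
    vals = np.array([prof.rmsf[(c, s)] for (c, s, _) in toy.residues])
    assert vals[10] / np.median(vals) == pytest.approx(2.0, rel=0.05)
    expected = sigmas * np.sqrt(3)
    assert np.abs(vals / expected - 1).max() <= 0.05


# ----------------------------------------------------------------------- Rg

def test_gyration_closed_forms(cube):
    traj = Trajectory(cube, np.array([cube.coords, cube.coords * 2.5]))
    rg = tm.gyration_series(traj, mass_weighted=False)
    assert rg[0] == pytest.approx(np.sqrt(3))
    assert rg[1] == pytest.approx(2.5 * np.sqrt(3))   # homogeneity
    assert np.allclose(tm.gyration_series(traj), rg)  # homoatomic: weights moot
    collapsed = Trajectory(cube, np.zeros((1, len(cube), 3)))
    assert tm.gyration_series(collapsed)[0] == pytest.approx(0.0)


# --------------------------------------------------------------------- SASA

def test_sasa_series_constant_and_cross_module(small_toy):
    frames = np.repeat(small_toy.coords[None], 3, axis=0)
    traj = Trajectory(small_toy, frames)
    series = tm.sasa_series(traj, n_points=64)
    assert np.ptp(series) == pytest.approx(0.0, abs=1e-9)
    direct = lf.compute_sasa(small_toy, n_points=64).sum()
    assert series[0] == pytest.approx(direct, rel=1e-12)


def test_sasa_series_burial_monotonic():
    """A residue moved from an exposed to an enclosed position loses SASA."""
    mob = lf.make_peptide("L", "extended")
    cage = lf.make_toy_protein(lf.ToySpec(n_strands=6, n_strand_res=4,
                                          n_helix_res=1, barrel_radius=6.0))
    atoms = [Atom(a.serial, a.name, a.element, a.res_name, 200, "M", a.coords)
             for a in mob.atoms]
    combined = StructureModel(list(cage.atoms) + atoms)
    idx = np.array(combined.residue_atom_indices("M", 200))
    far = combined.coords
    far[idx] += np.array([60.0, 0.0, 0.0])     # far outside
    inside = combined.coords
    inside[idx] -= inside[idx].mean(0)          # centred in the barrel
    traj = Trajectory(combined, np.array([far, inside]))
    series = tm.sasa_series(traj, selection=idx, n_points=64)
    assert series[1] < series[0]


# ----------------------------------------------------------- helix distance

def test_helix_barrel_distance_static_and_aggregation():
    coords = np.array([[0.0, 0, 0], [5.0, 0, 0], [0, 0, 6.0], [4.0, 0, 6.0]])
    model = _ca_model(coords)
    traj = Trajectory(model, np.repeat(coords[None], 3, axis=0))
    one = tm.helix_barrel_distance(traj, [(("A", 2), ("A", 1))])
    assert np.allclose(one.d, 5.0)
    assert one.D_max == one.D_ave == 5.0
    two = tm.helix_barrel_distance(traj, [(("A", 2), ("A", 1)),
                                          (("A", 4), ("A", 3))])
    assert np.allclose(two.d, 4.5)  # mean of 5 and 4
    with pytest.raises(KeyError, match="A.*9"):
        tm.helix_barrel_distance(traj, [(("A", 9), ("A", 1))])
    with pytest.raises(ValueError, match="at least one"):
        tm.helix_barrel_distance(traj, [])


def test_breathing_recovery(toy):
    motion = lf.MotionSpec(n_frames=500, breathing_amplitude=1.65,
                           breathing_period=100, seed=9)
    res = lf.make_breathing_trajectory(toy, motion)
    hb = tm.helix_barrel_distance(res.trajectory, res.pair_spec)
    sem = hb.D_sd / np.sqrt(len(hb.d))
    assert abs(hb.D_ave - res.d0) <= 3 * sem
    step = res.amplitude * 2 * np.pi / res.period
    assert abs(hb.D_max - (res.d0 + res.amplitude)) <= step
    assert hb.D_max >= hb.D_ave


# ----------------------------------------------------------------------- PCA

def test_pca_single_mode(small_toy):
    rng = np.random.default_rng(3)
    mode = rng.normal(size=(len(small_toy), 3))
    amps = np.sin(np.linspace(0, 8 * np.pi, 80))
    frames = small_toy.coords[None] + 0.4 * amps[:, None, None] * mode[None]
    pca = tm.pca_essential(Trajectory(small_toy, frames))
    assert pca.explained_variance[0] >= 0.99
    assert pca.eigenvalues[0] >= pca.eigenvalues[1] >= 0
    assert np.abs(pca.projections.mean(axis=0)).max() <= 1e-9
    lo, hi = pca.ranges[0]
    assert lo <= 0 <= hi


def test_pca_isotropic_noise_is_featureless(cube):
    rng = np.random.default_rng(8)
    frames = cube.coords[None] + rng.normal(scale=0.3, size=(5000, len(cube), 3))
    pca = tm.pca_essential(Trajectory(cube, frames), n_components=5)
    # no collective mode: the leading component explains only its random share
    assert pca.explained_variance[0] <= 0.12
    assert pca.eigenvalues[0] / pca.eigenvalues[1] <= 1.3


def test_pca_nm_units(small_toy):
    rng = np.random.default_rng(1)
    frames = small_toy.coords[None] + rng.normal(
        scale=0.2, size=(30, len(small_toy), 3))
    a = tm.pca_essential(Trajectory(small_toy, frames), units="angstrom")
    n = tm.pca_essential(Trajectory(small_toy, frames), units="nm")
    assert n.ranges[0][1] == pytest.approx(0.1 * a.ranges[0][1], rel=1e-9)


# ------------------------------------------------------------- invariances

def test_metrics_invariant_under_global_rigid_motion(toy):
    traj = lf.make_harmonic_trajectory(toy, lf.MotionSpec(sigmas=0.3,
                                                          n_frames=40, seed=6))
    Q = rotation_about([0.2, 1.0, 0.5], 1.1)
    shift = np.array([3.0, -8.0, 2.0])
    moved = Trajectory(toy, traj.frames @ Q.T + shift)
    assert np.abs(tm.rmsd_series(moved) - tm.rmsd_series(traj)).max() <= 1e-6
    p0 = tm.rmsf_profile(traj)
    p1 = tm.rmsf_profile(moved)
    assert max(abs(p0.rmsf[k] - p1.rmsf[k]) for k in p0.rmsf) <= 1e-6
    assert np.abs(tm.gyration_series(moved) - tm.gyration_series(traj)).max() <= 1e-6
    e0 = tm.pca_essential(traj).eigenvalues
    e1 = tm.pca_essential(moved).eigenvalues
    assert np.abs(e0 - e1).max() <= 1e-6
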