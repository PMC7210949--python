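"""Accessible-interaction-space scan vs an independent brute-force oracle."""

import math

import numpy as np
import pytest

from coreceptor import ispace, synthdata
from coreceptor.io import CoarseStructure
from coreceptor.xlink import DistanceRestraint


def brute_force_counts(receptor, ligand, restraints, params):
    """Naive triple-loop census over the identical placement set.

    Independent of the vectorized scanner: plain ``math.dist`` arithmetic over
    each (rotation, grid center, bead) triple.
    """
    grid = ispace.placement_grid(receptor.coords, params["grid_spacing"], params["padding"])
    rotations = ispace.rotation_set(params["n_rotations"])
    lig_local = ligand.coords - ligand.coords.mean(axis=0)
    anchors = []
    for r in restraints:
        ri = receptor.index_of(*r.anchor_a)
        li = ligand.index_of(*r.anchor_b)
        anchors.append((tuple(receptor.coords[ri]), li, r.lower, r.upper))
    counts = {k: 0 for k in range(len(restraints) + 1)}
    for rot in rotations:
        placed = [tuple(rot @ b) for b in lig_local]
        for center in grid:
            pos = [(center[0] + b[0], center[1] + b[1], center[2] + b[2]) for b in placed]
            if any(
                math.dist(p, tuple(rc)) < params["clash_dist"]
                for p in pos
                for rc in receptor.coords
            ):
                continue
            counts[0] += 1
            nsat = sum(
                1
                for apos, li, lo, up in anchors
                if lo <= math.dist(pos[li], apos) <= up
            )
            for k in range(1, nsat + 1):
                counts[k] += 1
    return counts


def run_scan(toy):
    p = toy.scan_params
    return ispace.scan(
        toy.receptor, toy.ligand, toy.restraints,
        grid_spacing=p["grid_spacing"], padding=p["padding"],
        n_rotations=p["n_rotations"], clash_dist=p["clash_dist"],
        canonicalize=p["canonicalize"],
    )


@pytest.mark.parametrize("scenario", ["census", "two_lobe", "symmetric"])
def test_scan_matches_brute_force_oracle(scenario):
    toy = synthdata.gen_toy_structures(0, scenario)
    oracle = brute_force_counts(toy.receptor, toy.ligand, toy.restraints, toy.scan_params)
    result = run_scan(toy)
    assert result.counts == oracle
    # the generator's stored census is the same quantity
    assert result.counts == toy.census


def test_oracle_equality_with_rotations_and_multibead_ligand():
    receptor = CoarseStructure(
        beads=[("R", 1), ("R", 2), ("R", 3)],
        coords=np.array([[0.0, 0, 0], [5.0, 0, 0], [0.0, 4, 0]]),
    )
    ligand = CoarseStructure(
        beads=[("L", 1), ("L", 2)], coords=np.array([[0.0, 0, 0], [3.0, 0, 0]])
    )
    restraints = [
        DistanceRestraint(("R", 1), ("L", 2), 2.0, 9.0),
        DistanceRestraint(("R", 3), ("L", 1), 0.0, 7.0),
    ]
    params = {"grid_spacing": 3.0, "padding": 6.0, "n_rotations": 8,
              "clash_dist": 3.0, "canonicalize": False}
    oracle = brute_force_counts(receptor, ligand, restraints, params)
    result = ispace.scan(receptor, ligand, restraints, grid_spacing=3.0, padding=6.0,
                         n_rotations=8, clash_dist=3.0, canonicalize=False)
    assert result.counts == oracle


@pytest.mark.parametrize("scenario", ["census", "two_lobe", "symmetric"])
def test_counts_non_increasing_in_k(scenario):
    toy = synthdata.gen_toy_structures(0, scenario)
    result = run_scan(toy)
    values = [result.counts[k] for k in sorted(result.counts)]
    assert all(a >= b for a, b in zip(values, values[1:]))


def test_zero_restraints_clash_only_census():
    toy = synthdata.gen_toy_structures(0, "census")
    p = toy.scan_params
    result = ispace.scan(toy.receptor, toy.ligand, [], grid_spacing=p["grid_spacing"],
                         padding=p["padding"], n_rotations=1, clash_dist=p["clash_dist"],
                         canonicalize=False)
    assert result.counts == {0: toy.census[0]}


def test_unsatisfiable_restraint_gives_zero():
    toy = synthdata.gen_toy_structures(0, "census")
    p = toy.scan_params
    impossible = [DistanceRestraint(("R", 1), ("L", 1), 0.0, 1.0)]  # < clash_dist
    result = ispace.scan(toy.receptor, toy.ligand, impossible,
                         grid_spacing=p["grid_spacing"], padding=p["padding"],
                         n_rotations=1, clash_dist=p["clash_dist"], canonicalize=False)
    assert result.counts[1] == 0


class TestDropCurve:
    def test_two_lobe_sharpest_drop_at_tail(self):
        """The degron-tail restraint applied last removes one placement lobe:
        its relative drop strictly exceeds every earlier step."""
        toy = synthdata.gen_toy_structures(0, "two_lobe")
        p = toy.scan_params
        assert toy.restraints[-1].source == "TAIL"
        curve = ispace.restraint_drop_curve(
            toy.receptor, toy.ligand, toy.restraints,
            grid_spacing=p["grid_spacing"], padding=p["padding"],
            n_rotations=p["n_rotations"], clash_dist=p["clash_dist"],
            canonicalize=p["canonicalize"],
        )
        assert all(a >= b for a, b in zip(curve, curve[1:]))
        drops = [1 - b / a for a, b in zip(curve, curve[1:]) if a > 0]
        assert drops[-1] > max(drops[:-1])

    def test_empty_list_gives_clash_free_count(self):
        toy = synthdata.gen_toy_structures(0, "census")
        p = toy.scan_params
        curve = ispace.restraint_drop_curve(
            toy.receptor, toy.ligand, [], grid_spacing=p["grid_spacing"],
            padding=p["padding"], n_rotations=1, clash_dist=p["clash_dist"],
            canonicalize=False,
        )
        assert curve == [toy.census[0]]

    def test_duplicated_restraint_changes_nothing(self):
        toy = synthdata.gen_toy_structures(0, "census")
        p = toy.scan_params
        kwargs = dict(grid_spacing=p["grid_spacing"], padding=p["padding"],
                      n_rotations=1, clash_dist=p["clash_dist"], canonicalize=False)
        base = ispace.restraint_drop_curve(toy.receptor, toy.ligand, toy.restraints, **kwargs)
        doubled = ispace.restraint_drop_curve(
            toy.receptor, toy.ligand, toy.restraints + [toy.restraints[-1]], **kwargs
        )
        assert doubled[:-1] == base
        assert doubled[-1] == base[-1]


class TestPropensity:
    def test_symmetric_scenario_all_unit_propensity(self):
        toy = synthdata.gen_toy_structures(0, "symmetric")
        p = toy.scan_params
        result = ispace.propensity(
            toy.receptor, toy.ligand, toy.restraints,
            grid_spacing=p["grid_spacing"], padding=p["padding"],
            n_rotations=p["n_rotations"], clash_dist=p["clash_dist"],
            contact_dist=p["contact_dist"], canonicalize=False,
        )
        for value in result.propensity.values():
            assert value == pytest.approx(1.0)
        assert result.active == []  # strict > 1.0

    def test_mean_propensity_of_contacted_residues_is_one(self):
        toy = synthdata.gen_toy_structures(0, "two_lobe")
        p = toy.scan_params
        result = ispace.propensity(
            toy.receptor, toy.ligand, toy.restraints,
            grid_spacing=p["grid_spacing"], padding=p["padding"],
            n_rotations=p["n_rotations"], clash_dist=p["clash_dist"],
            contact_dist=6.0, canonicalize=False,
        )
        contacted = [v for v in result.propensity.values() if v > 0]
        assert np.mean(contacted) == pytest.approx(1.0)

    def test_planted_patch_contains_active_set(self):
        """With a tight restraint pinning placements near one anchor, active
        residues must lie in that planted neighbourhood."""
        toy = synthdata.gen_toy_structures(0, "two_lobe")
        p = toy.scan_params
        result = ispace.propensity(
            toy.receptor, toy.ligand, toy.restraints,
            grid_spacing=p["grid_spacing"], padding=p["padding"],
            n_rotations=p["n_rotations"], clash_dist=p["clash_dist"],
            contact_dist=6.0, canonicalize=False,
        )
        # consistent placements sit within 9 A of the anchor bead (R,18) at
        # (8,0,0); the planted patch is every receptor bead within 9 A of it:
        # the anchor itself plus the four central wall beads at (0,+-2,+-2)
        # (distance sqrt(64+4+4) ~ 8.5 A)
        patch = {("R", 18), ("R", 6), ("R", 7), ("R", 10), ("R", 11)}
        assert set(result.active) <= patch
        assert ("R", 18) in result.active

    def test_no_consistent_placement_raises(self):
        toy = synthdata.gen_toy_structures(0, "census")
        p = toy.scan_params
        impossible = [DistanceRestraint(("R", 1), ("L", 1), 0.0, 1.0)]
        with pytest.raises(ValueError, match="relax"):
            ispace.propensity(
                toy.receptor, toy.ligand, impossible,
                grid_spacing=p["grid_spacing"], padding=p["padding"],
                n_rotations=1, clash_dist=p["clash_dist"], canonicalize=False,
            )


class TestInvariances:
    def _bodies(self):
        receptor = CoarseStructure(
            beads=[("R", 1), ("R", 2), ("R", 3)],
            coords=np.array([[0.0, 0, 0], [7.0, 0, 0], [0.0, 3, 1.0]]),
        )
        ligand = CoarseStructure(beads=[("L", 1)], coords=np.array([[0.0, 0, 0]]))
        restraints = [DistanceRestraint(("R", 2), ("L", 1), 0.0, 8.0)]
        return receptor, ligand, restraints

    def test_rigid_motion_invariance(self):
        """Translating/rotating the whole system leaves counts unchanged when
        the grid is re-anchored to the receptor frame."""
        from scipy.spatial.transform import Rotation

        receptor, ligand, restraints = self._bodies()
        kwargs = dict(grid_spacing=2.0, padding=6.0, n_rotations=1,
                      clash_dist=3.0, canonicalize=True)
        base = ispace.scan(receptor, ligand, restraints, **kwargs)
        rot = Rotation.from_euler("zyx", [31.0, -17.0, 54.0], degrees=True).as_matrix()
        shift = np.array([11.0, -6.0, 3.5])
        moved = CoarseStructure(
            beads=list(receptor.beads), coords=receptor.coords @ rot.T + shift
        )
        moved_result = ispace.scan(moved, ligand, restraints, **kwargs)
        assert moved_result.counts == base.counts

    def test_grid_halving_scales_clash_free_count(self):
        """Halving the spacing multiplies the clash-free census by ~8 on a
        convex toy (volume consistency within 20%)."""
        receptor = CoarseStructure(beads=[("R", 1)], coords=np.array([[0.0, 0, 0]]))
        ligand = CoarseStructure(beads=[("L", 1)], coords=np.array([[0.0, 0, 0]]))
        coarse = ispace.scan(receptor, ligand, [], grid_spacing=2.0, padding=20.0,
                             n_rotations=1, clash_dist=3.0, canonicalize=False)
        fine = ispace.scan(receptor, ligand, [], grid_spacing=1.0, padding=20.0,
                           n_rotations=1, clash_dist=3.0, canonicalize=False)
        ratio = fine.counts[0] / coarse.counts[0]
        assert abs(ratio - 8.0) / 8.0 < 0.20


class TestRotationSet:
    def test_identity_for_single_rotation(self):
        mats = ispace.rotation_set(1)
        assert np.allclose(mats[0], np.eye(3))

    def test_valid_rotation_matrices(self):
        mats = ispace.rotation_set(64)
        assert mats.shape == (64, 3, 3)
        for m in mats:
            assert np.allclose(m @ m.T, np.eye(3), atol=1e-10)
            assert np.linalg.det(m) == pytest.approx(1.0)

    def test_deterministic(self):
        assert np.array_equal(ispace.rotation_set(100), ispace.rotation_set(100))
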