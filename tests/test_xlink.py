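"""Crosslink tables, replicate filtering, clustering, restraints."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coreceptor import synthdata
from coreceptor.hydro import load_fold_bands
from coreceptor.io import CoarseStructure
from coreceptor.xlink import (
    CrossLink,
    DistanceRestraint,
    build_network,
    classify_links,
    cluster_residues,
    export_circular_map,
    load_xl_table,
    read_tbl,
    replicate_filter,
    tail_restraint,
    write_tbl,
    xl_to_restraints,
)


@pytest.fixture()
def xl_csv(tmp_path):
    df, truth = synthdata.gen_xl_table(seed=5)
    path = tmp_path / "xl.csv"
    df.to_csv(path, index=False)
    return path, truth


class TestLoadTable:
    def test_offset_correction(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "protein1,residue1,protein2,residue2,replicate,score\n"
            "TIR1,100,IAA7,10,rep1,90\n"
        )
        links = load_xl_table(path, offsets={"IAA7": 5})
        assert links[0].residue_b == 5
        assert links[0].residue_a == 100  # no offset declared for TIR1

    def test_zero_offset_identity(self, xl_csv):
        path, _ = xl_csv
        a = load_xl_table(path)
        b = load_xl_table(path, offsets={})
        assert [l.pair for l in a] == [l.pair for l in b]

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("protein1,residue1\nTIR1,5\n")
        with pytest.raises(ValueError, match="protein2"):
            load_xl_table(path)

    def test_duplicate_rows_collapse_in_network(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "protein1,residue1,protein2,residue2,replicate,score\n"
            "TIR1,100,IAA7,10,rep1,90\n"
            "TIR1,100,IAA7,10,rep1,95\n"
            "IAA7,10,TIR1,100,rep1,80\n"  # swapped endpoints, same pair
        )
        net = build_network(load_xl_table(path))
        assert len(net.support) == 1
        assert net.support[next(iter(net.support))] == {"rep1"}

    def test_nonpositive_corrected_residue_dropped_with_warning(self, tmp_path):
        path = tmp_path / "o.csv"
        path.write_text(
            "protein1,residue1,protein2,residue2,replicate,score\n"
            "TIR1,100,IAA7,3,rep1,90\n"
        )
        with pytest.warns(UserWarning, match="dropped"):
            links = load_xl_table(path, offsets={"IAA7": 5})
        assert links == []


class TestReplicateFilter:
    def _net(self, support, n_replicates=3):
        links = []
        for (ra, rb), reps in support.items():
            for rep in reps:
                links.append(
                    CrossLink(
                        protein_a="TIR1", residue_a=ra,
                        protein_b="IAA7", residue_b=rb, replicate_id=rep,
                    )
                )
        return build_network(links, n_replicates=n_replicates)

    def test_two_of_three_kept_dashed(self):
        net = self._net({(100, 10): ["rep1", "rep2"]})
        filtered, classes = replicate_filter(net, min_support=2)
        assert len(filtered.support) == 1
        assert list(classes.values()) == ["dashed"]

    def test_singleton_dropped(self):
        net = self._net({(100, 10): ["rep1"]})
        filtered, _ = replicate_filter(net, min_support=2)
        assert len(filtered.support) == 0

    def test_unanimous_solid(self):
        net = self._net({(100, 10): ["rep1", "rep2", "rep3", "rep4"]}, n_replicates=4)
        _, classes = replicate_filter(net, min_support=3)
        assert list(classes.values()) == ["solid"]

    def test_idempotent_and_monotone(self, xl_csv):
        path, _ = xl_csv
        net = build_network(load_xl_table(path))
        f2, _ = replicate_filter(net, 2)
        f2_again, _ = replicate_filter(f2, 2)
        assert f2.support == f2_again.support
        f3, _ = replicate_filter(net, 3)
        assert set(f3.support) <= set(f2.support)

    def test_planted_set_recovered_exactly(self, xl_csv):
        path, truth = xl_csv
        net = build_network(load_xl_table(path), n_replicates=truth["n_replicates"])
        filtered, _ = replicate_filter(net, truth["min_support"])
        recovered = {(p[0][1], p[1][1]) for p in filtered.pairs}
        # pairs are ((IAA7,res),(TIR1,res)) after unordered normalization
        planted = {tuple(p) for p in truth["planted"]}
        recovered_rl = {(b, a) for a, b in recovered}
        assert recovered_rl == planted or recovered == planted

    def test_min_support_above_replicates_rejected(self):
        net = self._net({(100, 10): ["rep1"]})
        with pytest.raises(ValueError):
            replicate_filter(net, min_support=5)


class TestClassifyAndExport:
    def test_partition(self):
        links = [
            CrossLink("TIR1", 10, "TIR1", 50, "rep1"),
            CrossLink("TIR1", 10, "IAA7", 5, "rep1"),
        ]
        net = build_network(links)
        intra, inter = classify_links(net)
        assert len(intra) == 1 and len(inter) == 1
        assert len(intra) + len(inter) == len(net.support)

    def test_circular_map_schema(self, xl_csv):
        path, truth = xl_csv
        net = build_network(load_xl_table(path), n_replicates=truth["n_replicates"])
        filtered, classes = replicate_filter(net, 2)
        table = export_circular_map(filtered, classes)
        assert len(table) == len(filtered.support)
        assert set(table["class"]) <= {"intra", "inter"}
        assert set(table["support_class"]) <= {"solid", "dashed"}


class TestClusterResidues:
    def test_two_spans(self):
        spans = cluster_residues([150, 160, 200, 490, 500], max_gap=50)
        assert [(s.start, s.end) for s in spans] == [(150, 200), (490, 500)]

    def test_singleton(self):
        spans = cluster_residues([42], max_gap=30)
        assert [(s.start, s.end) for s in spans] == [(42, 42)]

    def test_large_gap_single_span(self):
        spans = cluster_residues([1, 100, 200], max_gap=500)
        assert len(spans) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_residues([])

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=1, max_value=600), min_size=1, max_size=60),
        st.integers(min_value=0, max_value=100),
    )
    def test_spans_disjoint_and_cover_positions(self, positions, max_gap):
        spans = cluster_residues(positions, max_gap=max_gap)
        covered = [m for s in spans for m in s.members]
        assert sorted(covered) == sorted(set(positions))
        for a, b in zip(spans, spans[1:]):
            assert a.end < b.start

    def test_planted_cluster_windows_recovered(self):
        """Residues drawn from two receptor windows come back as two spans
        inside those windows."""
        _, truth = synthdata.gen_xl_table(seed=12, n_true_inter=12)
        positions = sorted({p[0] for p in truth["planted"]})
        spans = cluster_residues(positions, max_gap=30)
        windows = [tuple(w) for w in truth["receptor_windows"]]
        # windows are separated by far more than max_gap: every span falls
        # inside exactly one window and both windows are represented
        for span in spans:
            assert any(lo <= span.start <= span.end <= hi for lo, hi in windows)
        for lo, hi in windows:
            assert any(lo <= span.start <= hi for span in spans)


class TestRestraints:
    def _structures(self):
        receptor = CoarseStructure(
            beads=[("A", 100), ("A", 101)],
            coords=np.array([[0.0, 0, 0], [25.0, 0, 0]]),
        )
        ligand = CoarseStructure(beads=[("B", 5)], coords=np.array([[40.0, 0, 0]]))
        return receptor, ligand

    def test_satisfied_and_violated_flags(self):
        receptor, ligand = self._structures()
        links = [
            CrossLink("TIR1", 101, "IAA7", 5, "rep1"),  # 15 A apart -> satisfied
            CrossLink("TIR1", 100, "IAA7", 5, "rep1"),  # 40 A apart -> violated
        ]
        net = build_network(links)
        report = xl_to_restraints(
            net,
            {"TIR1": receptor, "IAA7": ligand},
            {"TIR1": "A", "IAA7": "B"},
            max_ca_ca=30.0,
        )
        assert len(report.restraints) == 2
        flags = sorted(report.satisfied.values())
        assert flags == [False, True]

    def test_unresolvable_endpoints_listed_not_fatal(self):
        receptor, ligand = self._structures()
        links = [CrossLink("TIR1", 999, "IAA7", 5, "rep1")]
        net = build_network(links)
        with pytest.warns(UserWarning, match="no resolvable"):
            report = xl_to_restraints(
                net, {"TIR1": receptor, "IAA7": ligand}, {"TIR1": "A", "IAA7": "B"}
            )
        assert report.restraints == []
        assert len(report.unresolvable) == 1

    def test_restraint_count_conservation(self, xl_csv):
        path, truth = xl_csv
        net = build_network(load_xl_table(path), n_replicates=truth["n_replicates"])
        filtered, _ = replicate_filter(net, truth["min_support"])
        # structures resolving every endpoint
        rec_res = sorted({p[1] for pair in filtered.pairs for p in pair if p[0] == "TIR1"})
        lig_res = sorted({p[1] for pair in filtered.pairs for p in pair if p[0] == "IAA7"})
        receptor = CoarseStructure(
            beads=[("A", r) for r in rec_res],
            coords=np.array([[float(i), 0, 0] for i in range(len(rec_res))]),
        )
        ligand = CoarseStructure(
            beads=[("B", r) for r in lig_res],
            coords=np.array([[float(i), 50, 0] for i in range(len(lig_res))]),
        )
        report = xl_to_restraints(
            filtered, {"TIR1": receptor, "IAA7": ligand}, {"TIR1": "A", "IAA7": "B"}
        )
        _, inter = classify_links(filtered)
        assert len(report.restraints) == len(inter)


class TestTailRestraint:
    def test_bounds_ordered_and_monotone(self):
        bands = load_fold_bands()
        uppers, lowers = [], []
        for n in (10, 20, 36, 49, 60):
            r = tail_restraint(n, ("A", 1), ("B", 1), bands)
            assert r.lower < r.upper
            assert r.source == "TAIL"
            uppers.append(r.upper)
            lowers.append(r.lower)
        assert all(np.diff(uppers) > 0)
        assert all(np.diff(lowers) > 0)

    def test_longer_tail_has_larger_upper_bound(self):
        # 49-aa tail (IAA12-like) vs 36-aa tail (IAA7-like)
        bands = load_fold_bands()
        short = tail_restraint(36, ("A", 1), ("B", 1), bands)
        long = tail_restraint(49, ("A", 1), ("B", 1), bands)
        assert long.upper > short.upper

    def test_zero_tail_rejected(self):
        with pytest.raises(ValueError):
            tail_restraint(0, ("A", 1), ("B", 1), load_fold_bands())


class TestTblFormat:
    def test_line_dialect(self, tmp_path):
        r = DistanceRestraint(anchor_a=("A", 100), anchor_b=("B", 5), lower=0.0, upper=30.0)
        path = tmp_path / "r.tbl"
        write_tbl([r], path)
        line = path.read_text().strip()
        assert line == (
            "assign (segid A and resid 100 and name CA) "
            "(segid B and resid 5 and name CA) 30.0 30.0 0.0"
        )

    def test_round_trip(self, tmp_path):
        restraints = [
            DistanceRestraint(("A", 10), ("B", 2), 5.0, 22.5),
            DistanceRestraint(("A", 3), ("B", 9), 0.0, 30.0),
        ]
        path = tmp_path / "rt.tbl"
        write_tbl(restraints, path, header_params={"max_ca_ca": 30.0})
        back = read_tbl(path)
        assert len(back) == 2
        got = {(r.anchor_a, r.anchor_b, r.lower, r.upper) for r in back}
        want = {(r.anchor_a, r.anchor_b, r.lower, r.upper) for r in restraints}
        assert got == want

    def test_byte_stable(self, tmp_path):
        restraints = [
            DistanceRestraint(("A", 10), ("B", 2), 5.0, 22.5),
            DistanceRestraint(("A", 3), ("B", 9), 0.0, 30.0),
        ]
        p1, p2 = tmp_path / "a.tbl", tmp_path / "b.tbl"
        write_tbl(restraints, p1)
        write_tbl(list(reversed(restraints)), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_tbl([], tmp_path / "e.tbl")
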