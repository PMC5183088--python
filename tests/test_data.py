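"""Data model, lattice construction, CSV and BUGS-dump readers/writers."""

import numpy as np
import pytest

import occudyn as od
from occudyn.data import _adjacency_from_bugs, read_bugs_dump


class TestBuildAdjacency:
    def test_2x2_grid_every_quadrat_has_two_neighbours(self):
        lat = od.build_adjacency(2, 2)
        assert (lat.neighbor_count == 2).all()

    def test_1x2_grid_each_quadrat_has_one_neighbour(self):
        lat = od.build_adjacency(1, 2)
        assert (lat.neighbor_count == 1).all()

    def test_20x10_grid_degree_distribution_and_edge_count(self):
        # rook lattice: corners 2, edges 3, interior 4 neighbours;
        # directed entries = 2 * (horizontal + vertical undirected edges)
        lat = od.build_adjacency(20, 10)
        deg = lat.neighbor_count
        counts = {d: int((deg == d).sum()) for d in (2, 3, 4)}
        assert counts == {2: 4, 3: 2 * 18 + 2 * 8, 4: 18 * 8}
        assert lat.adjacency.nnz == 2 * (19 * 10 + 20 * 9)
        assert lat.is_connected()

    def test_neighbor_count_equals_adjacency_row_sums(self):
        lat = od.build_adjacency(3, 4)
        rows = np.asarray(lat.adjacency.sum(axis=1)).ravel()
        np.testing.assert_array_equal(lat.neighbor_count, rows)

    def test_queen_rule_adds_diagonal_neighbours(self):
        lat = od.build_adjacency(3, 3, rule="queen")
        assert lat.neighbor_count[4] == 8  # centre cell

    def test_gap_ids_outside_grid_raise(self):
        with pytest.raises(ValueError, match="gap_ids"):
            od.build_adjacency(2, 2, gap_ids={"q99"})

    def test_single_quadrat_rejected(self):
        with pytest.raises(ValueError):
            od.build_adjacency(1, 1)


class TestCsvRoundTrip:
    def test_round_trip_matrices_and_lattice(self, small_dataset, tmp_path):
        survey, lattice, _ = small_dataset
        sp, qp = tmp_path / "survey.csv", tmp_path / "quadrats.csv"
        od.write_survey_csv(survey, lattice, sp, qp)
        survey2, lattice2 = od.read_survey_csv(sp, qp)
        # species never detected are absent from a presences-only file
        seen = survey.detections_per_species() > 0
        np.testing.assert_array_equal(survey2.y1, survey.y1[seen])
        np.testing.assert_array_equal(survey2.y2, survey.y2[seen])
        assert lattice2.quadrat_ids == lattice.quadrat_ids
        np.testing.assert_array_equal(lattice2.gap, lattice.gap)
        assert (lattice2.adjacency != lattice.adjacency).nnz == 0

    def test_omitting_absence_rows_gives_same_matrices(self, small_dataset, tmp_path):
        survey, lattice, _ = small_dataset
        full_s, full_q = tmp_path / "full.csv", tmp_path / "q1.csv"
        thin_s, thin_q = tmp_path / "thin.csv", tmp_path / "q2.csv"
        od.write_survey_csv(survey, lattice, full_s, full_q, presences_only=False)
        od.write_survey_csv(survey, lattice, thin_s, thin_q, presences_only=True)
        sv_full, _ = od.read_survey_csv(full_s, full_q)
        sv_thin, _ = od.read_survey_csv(thin_s, thin_q)
        seen = [s in sv_thin.species_ids for s in sv_full.species_ids]
        np.testing.assert_array_equal(sv_full.y1[seen], sv_thin.y1)
        np.testing.assert_array_equal(sv_full.y2[seen], sv_thin.y2)

    @pytest.mark.parametrize(
        "mutation, message",
        [
            ("duplicate", "duplicate"),
            ("presence2", "presence"),
            ("three_years", "two census years"),
        ],
    )
    def test_malformed_survey_rows_raise(self, tmp_path, mutation, message):
        qp = tmp_path / "q.csv"
        qp.write_text("quadrat,row,col,gap\nq1,0,0,0\nq2,0,1,1\n")
        rows = ["species,quadrat,year,presence", "a,q1,1992,1", "a,q2,2014,0"]
        if mutation == "duplicate":
            rows.append("a,q1,1992,0")
        elif mutation == "presence2":
            rows.append("b,q1,1992,2")
        else:
            rows.append("a,q1,2020,1")
        sp = tmp_path / "s.csv"
        sp.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValueError, match=message):
            od.read_survey_csv(sp, qp)


class TestBugsDump:
    def test_two_quadrat_path_graph(self, tmp_path):
        path = tmp_path / "dump.R"
        path.write_text(
            "y1 <- structure(c(1, 0), .Dim = c(1, 2))\n"
            "y2 <- structure(c(0, 1), .Dim = c(1, 2))\n"
            "plot <- structure(c(0, 0, 5, 10, 0, 1), .Dim = c(2, 3))\n"
            "adj <- c(2, 1)\n"
            "weights <- c(1, 1)\n"
            "num <- c(1, 1)\n"
        )
        survey, lattice = read_bugs_dump(path)
        np.testing.assert_array_equal(survey.y1, [[1, 0]])
        np.testing.assert_array_equal(lattice.adjacency.toarray(), [[0, 1], [1, 0]])
        np.testing.assert_array_equal(lattice.gap, [0, 1])
        np.testing.assert_array_equal(lattice.extra["slope"], [5, 10])

    def test_round_trip_on_study_sized_lattice(self, default_dataset, tmp_path):
        survey, lattice, _ = default_dataset
        path = tmp_path / "dump.R"
        od.write_bugs_dump(survey, lattice, path)
        survey2, lattice2 = read_bugs_dump(path)
        np.testing.assert_array_equal(survey2.y1, survey.y1)
        np.testing.assert_array_equal(survey2.y2, survey.y2)
        assert (lattice2.adjacency != lattice.adjacency).nnz == 0
        np.testing.assert_array_equal(lattice2.gap, lattice.gap)

    def test_reconstructed_adjacency_matches_direct_construction(self):
        lat = od.build_adjacency(5, 4)
        lil = lat.adjacency.tolil()
        num = np.array([len(r) for r in lil.rows])
        adj = np.array([k + 1 for r in lil.rows for k in sorted(r)])
        A = _adjacency_from_bugs(adj, num, lat.n_quadrats)
        assert (A != lat.adjacency).nnz == 0

    def test_adjacency_index_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="outside"):
            _adjacency_from_bugs(np.array([0, 1]), np.array([1, 1]), 2)
        with pytest.raises(ValueError, match="outside"):
            _adjacency_from_bugs(np.array([3, 1]), np.array([1, 1]), 2)

    def test_num_adj_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="num"):
            _adjacency_from_bugs(np.array([2, 1, 1]), np.array([1, 1]), 2)

    def test_asymmetric_adjacency_raises(self):
        with pytest.raises(ValueError, match="asymmetric"):
            _adjacency_from_bugs(np.array([2]), np.array([1, 0]), 2)


class TestFilterSpecies:
    def _survey(self, y1, y2):
        S, J = np.asarray(y1).shape
        return od.PresenceAbsenceSurvey(
            [f"s{i}" for i in range(S)], [f"q{j}" for j in range(J)], y1, y2
        )

    def test_six_records_retained_five_dropped(self):
        y1 = np.zeros((2, 6), dtype=int)
        y2 = np.zeros((2, 6), dtype=int)
        y1[0, :3] = 1
        y2[0, :3] = 1  # 6 records: strictly more than 5 -> kept
        y1[1, :5] = 1  # exactly 5 -> dropped
        out = od.filter_species(self._survey(y1, y2), min_records=5)
        assert out.species_ids == ["s0"]

    def test_retained_set_matches_brute_force_recount(self, default_dataset):
        survey, _, _ = default_dataset
        out = od.filter_species(survey, min_records=5)
        expected = [
            s
            for i, s in enumerate(survey.species_ids)
            if sum(int(v) for v in survey.y1[i]) + sum(int(v) for v in survey.y2[i]) > 5
        ]
        assert out.species_ids == expected
        assert out.quadrat_ids == survey.quadrat_ids

    def test_zero_threshold_removes_exactly_never_detected(self, default_dataset):
        survey, _, _ = default_dataset
        out = od.filter_species(survey, min_records=0)
        never = (survey.detections_per_species() == 0).sum()
        assert out.n_species == survey.n_species - never

    def test_quadrat_union_rule(self):
        y1 = np.array([[1, 1, 1, 0, 0, 0]])
        y2 = np.array([[1, 1, 1, 0, 0, 0]])  # 6 records but only 3 quadrats
        sv = self._survey(y1, y2)
        assert od.filter_species(sv, 5, count="records").n_species == 1
        with pytest.raises(ValueError, match="min_records"):
            od.filter_species(sv, 5, count="quadrats")

    def test_empty_result_raises_with_advice(self):
        sv = self._survey(np.zeros((1, 4), int), np.zeros((1, 4), int))
        with pytest.raises(ValueError, match="threshold"):
            od.filter_species(sv, min_records=5)
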