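"""Event parsing, layer construction, pooling, and Pajek round trips."""

import numpy as np
import pytest

from antweb.errors import EmptyLayerError, SchemaError, ValidationError
from antweb.network_model import (
    MULTILAYER,
    LayerMatrix,
    build_layer,
    build_multilayer,
    export_pajek,
    read_events,
    read_pajek,
    write_events,
)

from conftest import make_event, make_layer

CSV_HEADER = "site_id,plot_id,season,plant_sp,ant_sp,resource,workers\n"


class TestReadEvents:
    def test_well_formed_rows_parse_identically(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(
            CSV_HEADER
            + "S1,p1,Jan,P1,A1,EFN,2\n"
            + "S1,p2,Apr,P2,A1,visit,0\n"
            + "S2,p1,Jul,P1,A2,trophobiont,5\n"
        )
        events = read_events(p)
        assert len(events) == 3
        assert events[0].plant_sp == "P1" and events[0].workers == 2
        assert events[2].resource == "trophobiont"

    def test_unknown_resource_label_rejected(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(CSV_HEADER + "S1,p1,Jan,P1,A1,nectar,1\n")
        with pytest.raises(SchemaError, match="nectar"):
            read_events(p)

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(CSV_HEADER)
        assert read_events(p) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text("site_id,plant_sp,ant_sp,resource\nS1,P1,A1,EFN\n")
        with pytest.raises(SchemaError, match="missing columns"):
            read_events(p)

    def test_negative_workers_names_offending_row(self, tmp_path):
        p = tmp_path / "ev.csv"
        p.write_text(CSV_HEADER + "S1,p1,Jan,P1,A1,EFN,1\nS1,p1,Jan,P2,A1,EFN,-3\n")
        with pytest.raises(ValidationError, match=":3"):
            read_events(p)

    def test_write_read_round_trip(self, tmp_path):
        events = [make_event(plant=f"P{i}", workers=i) for i in range(1, 4)]
        p = tmp_path / "out.csv"
        write_events(events, p)
        assert read_events(p) == events


class TestBuildLayer:
    def test_direct_count_example(self):
        events = [
            make_event("P1", "A1"),
            make_event("P1", "A1"),
            make_event("P2", "A2"),
        ]
        layer = build_layer(events, "EFN")
        assert layer.plants == ("P1", "P2") and layer.ants == ("A1", "A2")
        assert layer.A.tolist() == [[2, 0], [0, 1]]

    def test_empty_filter_signals_not_0x0(self):
        events = [make_event("P1", "A1"), make_event("P2", "A2")]
        with pytest.raises(EmptyLayerError):
            build_layer(events, "flower")

    def test_counts_match_exhaustive_tally(self, rng):
        plants = ["Pa", "Pb", "Pc"]
        ants = ["Ax", "Ay", "Az"]
        events = [
            make_event(plants[rng.integers(3)], ants[rng.integers(3)])
            for _ in range(10)
        ]
        layer = build_layer(events, "EFN")
        for i, p in enumerate(layer.plants):
            for j, a in enumerate(layer.ants):
                tally = sum(1 for e in events if e.plant_sp == p and e.ant_sp == a)
                assert layer.A[i, j] == tally

    def test_order_invariance(self, rng):
        events = [
            make_event(f"P{rng.integers(4)}", f"A{rng.integers(3)}") for _ in range(25)
        ]
        shuffled = list(events)
        rng.shuffle(shuffled)
        assert build_layer(events, "EFN") == build_layer(shuffled, "EFN")

    def test_site_filter(self):
        events = [make_event("P1", "A1", site="S1"), make_event("P2", "A2", site="S2")]
        layer = build_layer(events, "EFN", sites=["S2"])
        assert layer.plants == ("P2",)

    def test_no_zero_margins_survive(self, rng):
        events = [
            make_event(f"P{rng.integers(6)}", f"A{rng.integers(5)}") for _ in range(12)
        ]
        layer = build_layer(events, "EFN")
        assert np.all(layer.row_margins > 0) and np.all(layer.col_margins > 0)


class TestBuildMultilayer:
    def test_pooled_total_is_event_count(self):
        events = [
            make_event("P1", "A1"),
            make_event("P1", "A1"),
            make_event("P2", "A2"),
        ]
        net = build_multilayer(events)
        assert net.pooled.F == 3

    def test_pooled_cell_is_sum_of_layer_cells(self):
        events = [
            make_event("P1", "A1", "EFN"),
            make_event("P1", "A1", "visit"),
            make_event("P1", "A1", "visit"),
        ]
        net = build_multilayer(events)
        i = net.pooled.plants.index("P1")
        j = net.pooled.ants.index("A1")
        efn = net.layers["EFN"].A[0, 0]
        visit = net.layers["visit"].A[0, 0]
        assert net.pooled.A[i, j] == efn + visit == 3

    def test_layer_totals_conserve_events(self, rng):
        resources = ["EFN", "flower", "visit", "trophobiont"]
        events = [
            make_event(f"P{rng.integers(5)}", f"A{rng.integers(4)}",
                       resources[rng.integers(4)])
            for _ in range(60)
        ]
        net = build_multilayer(events)
        total = sum(m.F for m in net.layers.values() if m is not None)
        assert total == len(events) == net.pooled.F

    def test_every_layer_species_in_pooled(self, rng):
        events = [
            make_event(f"P{rng.integers(5)}", f"A{rng.integers(4)}",
                       ["EFN", "fruit"][rng.integers(2)])
            for _ in range(20)
        ]
        net = build_multilayer(events)
        for m in net.layers.values():
            if m is None:
                continue
            assert set(m.plants) <= set(net.pooled.plants)
            assert set(m.ants) <= set(net.pooled.ants)


class TestPajek:
    def test_vertex_and_arc_counts(self, tiny_layer, tmp_path):
        path = tmp_path / "net.net"
        export_pajek(tiny_layer, path)
        text = path.read_text()
        assert "*Vertices 4 2" in text
        lines = text.strip().splitlines()
        edges = lines[lines.index("*Edges") + 1 :]
        weights = sorted(int(e.split()[2]) for e in edges)
        assert weights == [1, 2]

    def test_round_trip(self, tmp_path, rng):
        A = rng.integers(0, 4, size=(5, 5))
        A[A.sum(axis=1) == 0, 0] = 1
        A[0, A.sum(axis=0) == 0] = 1
        layer = make_layer(A)
        path = tmp_path / "m.net"
        export_pajek(layer, path)
        back = read_pajek(path, resource="EFN")
        assert back == layer

    def test_edge_count_equals_positive_cells(self, tmp_path, rng):
        A = rng.integers(0, 3, size=(5, 5)) + np.eye(5, dtype=int)
        layer = make_layer(A)
        path = tmp_path / "m.net"
        export_pajek(layer, path)
        lines = path.read_text().strip().splitlines()
        n_edges = len(lines) - lines.index("*Edges") - 1
        assert n_edges == int(np.count_nonzero(A))


class TestTsv:
    def test_round_trip(self, tmp_path, rng):
        A = rng.integers(1, 5, size=(3, 4))
        layer = make_layer(A)
        p = tmp_path / "m.tsv"
        layer.to_tsv(p)
        assert LayerMatrix.from_tsv(p, resource="EFN") == layer
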