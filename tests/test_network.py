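"""Capability-table IO, filtering, taxon mapping, summaries."""

import numpy as np
import pandas as pd
import pytest

from gutflow import (
    CrossFeedingNetwork,
    ExclusionList,
    filter_network,
    load_interactions,
    map_taxa,
    network_summary,
    write_interactions,
)
from gutflow.network import FormatError, normalize_name


@pytest.fixture
def toy_table(tmp_path):
    """5 rows, 2 species, 3 metabolites, one exact duplicate row."""
    df = pd.DataFrame(
        [
            ("Escherichia coli", "glucose", "consumption"),
            ("Escherichia coli", "acetate", "production"),
            ("Escherichia coli", "glucose", "consumption"),  # duplicate
            ("Bacteroides fragilis", "xylose", "consumption"),
            ("Bacteroides fragilis", "acetate", "production"),
        ],
        columns=["species", "metabolite", "direction"],
    )
    p = tmp_path / "toy.tsv"
    df.to_csv(p, sep="\t", index=False)
    return p


class TestLoad:
    def test_toy_table_dedup(self, toy_table, caplog):
        net = load_interactions(toy_table)
        assert net.n_species == 2
        assert net.n_metabolites == 3
        assert len(net.consumption_edges) + len(net.production_edges) == 4

    def test_empty_table(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("species,metabolite,direction\n")
        net = load_interactions(p)
        assert (net.n_species, net.n_metabolites) == (0, 0)

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("species,metabolite\na,b\n")
        with pytest.raises(FormatError, match="direction"):
            load_interactions(p)

    def test_unknown_direction_token_lists_rows(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("species,metabolite,direction\na,b,eats\n")
        with pytest.raises(FormatError, match="eats"):
            load_interactions(p)

    def test_custom_tokens_and_columns(self, tmp_path):
        p = tmp_path / "alt.csv"
        p.write_text("taxon,compound,dir\na,b,in\na,c,out\n")
        net = load_interactions(
            p,
            columns={"species": "taxon", "metabolite": "compound", "direction": "dir"},
            direction_tokens={"in": "consumption", "out": "production"},
        )
        assert ("a", "b") in net.consumption_edges
        assert ("a", "c") in net.production_edges

    def test_xlsx_round_trip(self, tmp_path, toy_table):
        net = load_interactions(toy_table)
        xlsx = tmp_path / "cap.xlsx"
        rows = [(s, m, "consumption") for s, m in sorted(net.consumption_edges)]
        rows += [(s, m, "production") for s, m in sorted(net.production_edges)]
        pd.DataFrame(rows, columns=["species", "metabolite", "direction"]).to_excel(
            xlsx, index=False
        )
        net2 = load_interactions(xlsx)
        assert net2.consumption_edges == net.consumption_edges
        assert net2.production_edges == net.production_edges

    def test_write_load_round_trip(self, tmp_path, toy_table):
        net = load_interactions(toy_table)
        out = tmp_path / "rt.tsv"
        write_interactions(net, out)
        net2 = load_interactions(out)
        assert net2.consumption_edges == net.consumption_edges
        assert net2.production_edges == net.production_edges


class TestFilter:
    def test_excluding_ion_removes_its_edges(self):
        net = CrossFeedingNetwork(
            ["a", "b", "c"],
            ["Na+", "glc"],
            [("a", "Na+"), ("b", "Na+"), ("a", "glc")],
            [("c", "Na+")],
        )
        out, report = filter_network(net, ExclusionList(metabolite_ids={"Na+"}))
        assert "Na+" not in out.metabolites
        assert report.n_edges_removed == 3
        assert len(out.consumption_edges) == 1

    def test_empty_exclusion_is_identity(self, toy_table):
        net = load_interactions(toy_table)
        out, _ = filter_network(net, ExclusionList())
        assert out == net

    def test_idempotent(self, toy_table):
        net = load_interactions(toy_table)
        excl = ExclusionList(metabolite_ids={"acetate"})
        once, _ = filter_network(net, excl)
        twice, _ = filter_network(once, excl)
        assert once == twice

    def test_absent_id_is_noop(self, toy_table):
        net = load_interactions(toy_table)
        out, report = filter_network(net, ExclusionList(species_ids={"nobody"}))
        assert out == net
        assert report.absent_ids == ["nobody"]

    def test_drop_isolated(self):
        net = CrossFeedingNetwork(
            ["a", "b"], ["x", "y"], [("a", "x"), ("b", "y")], []
        )
        out, report = filter_network(
            net, ExclusionList(species_ids={"b"}), drop_isolated=True
        )
        assert out.species == ["a"]
        assert out.metabolites == ["x"]
        assert report.n_isolated_metabolites_removed == 1

    def test_reference_shape_counts(self, tmp_path):
        """Raw 570 species / 244 metabolites filter down to the curated
        567 / 235 / 4,248 shape."""
        from gutflow.synthetic import generate_reference_tables

        paths = generate_reference_tables(tmp_path, seed=0)
        net = load_interactions(paths["capability_table"])
        assert net.n_species == 570
        assert net.n_metabolites == 244
        excl = ExclusionList.from_files(paths["ion_list"], paths["host_list"])
        out, _ = filter_network(net, excl, drop_isolated=True)
        assert out.n_species == 567
        assert out.n_metabolites == 235
        assert len(out.consumption_edges) + len(out.production_edges) == 4248


class TestMapTaxa:
    @pytest.fixture
    def net(self):
        return CrossFeedingNetwork(
            species=["Bacteroides uniformis", "Bacteroides ovatus", "Prevotella copri"],
            metabolites=["glc", "xyl", "ace"],
            consumption_edges=[
                ("Bacteroides uniformis", "glc"),
                ("Bacteroides ovatus", "glc"),
                ("Prevotella copri", "xyl"),
            ],
            production_edges=[
                ("Bacteroides uniformis", "ace"),
                ("Bacteroides ovatus", "ace"),
            ],
        )

    def test_exact_match_with_name_normalization(self, net):
        rep = map_taxa(["Bacteroides_uniformis", "PREVOTELLA  COPRI"], net)
        assert rep.records[0].stage == "exact"
        assert rep.records[0].mapped_id == "Bacteroides uniformis"
        assert rep.records[1].mapped_id == "Prevotella copri"

    def test_genus_fallback_identical_capabilities(self, net):
        rep = map_taxa(["Bacteroides stercoris"], net)
        assert rep.records[0].stage == "genus"
        # inherits the congeners' shared set: consumes glc, produces ace
        assert ("Bacteroides stercoris", "glc") in rep.added_edges_c
        assert ("Bacteroides stercoris", "ace") in rep.added_edges_p

    def test_genus_with_differing_capabilities_unmapped(self):
        net = CrossFeedingNetwork(
            ["Clostridium a", "Clostridium b"],
            ["x", "y"],
            [("Clostridium a", "x"), ("Clostridium b", "y")],
            [],
        )
        rep = map_taxa(["Clostridium novum"], net)
        assert rep.records[0].stage == "unmapped"

    def test_core_capability_rule_for_flagged_genus(self):
        net = CrossFeedingNetwork(
            ["Clostridium a", "Clostridium b"],
            ["x", "y"],
            [("Clostridium a", "x"), ("Clostridium b", "x"), ("Clostridium b", "y")],
            [],
        )
        rep = map_taxa(
            ["Clostridium novum"], net, core_capability_genera=["Clostridium"]
        )
        assert rep.records[0].stage == "genus-core"
        assert rep.added_edges_c == [("Clostridium novum", "x")]  # intersection only

    def test_coverage_fraction(self, net):
        rep = map_taxa(["Bacteroides uniformis", "Unknownus alienus"], net)
        cov = rep.coverage({"Bacteroides uniformis": 0.6, "Unknownus alienus": 0.4})
        assert cov == pytest.approx(0.6)
        assert 0.0 <= cov <= 1.0

    def test_no_fallback_flag(self, net):
        rep = map_taxa(["Bacteroides stercoris"], net, genus_fallback=False)
        assert rep.records[0].stage == "unmapped"


class TestSummary:
    def test_empty(self):
        net = CrossFeedingNetwork([], [], [], [])
        s = network_summary(net)
        assert s["n_species"] == 0 and s["n_interactions"] == 0

    def test_toy_counts(self, toy_table):
        net = load_interactions(toy_table)
        s = network_summary(net)
        assert s["n_consumption_edges"] == 2
        assert s["n_production_edges"] == 2
        assert sorted(s["species_in_degree"]) == [1, 1]


def test_normalize_name_variants():
    assert normalize_name(" Faecalibacterium_prausnitzii ") == "faecalibacterium prausnitzii"
    assert normalize_name("A   b") == normalize_name("a_b")
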