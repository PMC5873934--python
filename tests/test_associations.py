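"""Association loading, true-path propagation and ortholog transfer."""

import io

import pytest

from stressprio.associations import (
    AssociationError, DIRECT, TRANSITIVE, OrthologMap, genes_for_terms,
    propagate, read_associations, transfer_transitive,
)
from stressprio.ontology import build_term_set


def tsv(*rows):
    header = "gene_id\tspecies\tterm_id\tontology_key"
    return io.StringIO("\n".join([header, *rows, ""]))


class TestReadAssociations:
    def test_exact_duplicates_collapsed(self):
        t = read_associations(tsv(
            "g1\tsorghum\tGO:0009414\tGO",
            "g1\tsorghum\tGO:0009414\tGO",
            "g2\tsorghum\tGO:0009414\tGO",
        ))
        assert len(t) == 2

    def test_empty_file_with_header(self):
        assert len(read_associations(tsv())) == 0

    def test_gro_row_queryable_by_term(self, registry):
        t = read_associations(tsv("Sb03g003110\tsorghum\tGRO:0007150\tGRO"))
        t = propagate(t, registry)
        ts = build_term_set(registry["GRO"], ["GRO:0007150"], "late-booting")
        hits = genes_for_terms(t, ts, "sorghum")
        assert list(hits.index) == ["Sb03g003110"]

    def test_prefix_mismatch_rejected_with_majority_error(self):
        # a single bad row is dropped, a majority-bad file raises
        t = read_associations(tsv(
            "g1\tsorghum\tGO:0009414\tGO",
            "g2\tsorghum\tEO:0007404\tGO",
            "g3\tsorghum\tGO:0009414\tGO",
        ))
        assert set(t.gene_id) == {"g1", "g3"}
        with pytest.raises(AssociationError):
            read_associations(tsv(
                "g1\tsorghum\tEO:0007404\tGO",
                "g2\tsorghum\tTO:0000495\tGO",
                "g3\tsorghum\tGO:0009414\tGO",
            ))


class TestPropagate:
    def test_chain_closure(self, registry):
        t = propagate(
            read_associations(tsv("g1\tsorghum\tGO:0009269\tGO")), registry
        )
        assert set(t.term_id) == {"GO:0009269", "GO:0009414", "GO:0006950"}

    def test_root_annotation_fixed_point(self, registry):
        t = propagate(
            read_associations(tsv("g1\tsorghum\tGO:0006950\tGO")), registry
        )
        assert set(t.term_id) == {"GO:0006950"}

    def test_siblings_share_parent(self, registry):
        t = propagate(read_associations(tsv(
            "g1\tsorghum\tGO:0009414\tGO",
            "g2\tsorghum\tGO:0009819\tGO",
        )), registry)
        parent_genes = set(t[t.term_id == "GO:0006950"].gene_id)
        assert parent_genes == {"g1", "g2"}

    def test_idempotence(self, registry, assoc_table):
        once = propagate(assoc_table, registry)
        twice = propagate(once, registry)
        assert once.equals(twice)

    def test_unknown_terms_dropped(self, registry):
        t = propagate(
            read_associations(tsv("g1\tsorghum\tGO:0099999\tGO")), registry
        )
        assert len(t) == 0


class TestGenesForTerms:
    def test_no_annotated_gene_yields_empty(self, registry, assoc_table):
        prop = propagate(assoc_table, registry)
        ts = build_term_set(registry["GO"], ["GO:0009819"], "recovery")
        assert genes_for_terms(prop, ts, "maize").empty

    def test_descendant_annotation_included_via_closure(self, registry):
        prop = propagate(
            read_associations(tsv("g1\tsorghum\tGO:0009269\tGO")), registry
        )
        ts = build_term_set(registry["GO"], ["GO:0009414"], "drought")
        assert list(genes_for_terms(prop, ts, "sorghum").index) == ["g1"]

    def test_empty_term_set_rejected(self, registry, assoc_table):
        from stressprio.ontology import TermSet
        empty = TermSet(ontology_key="GO", seed_ids=[], member_ids=set())
        with pytest.raises(AssociationError):
            genes_for_terms(assoc_table, empty, "sorghum")


class TestTransferTransitive:
    @pytest.fixture()
    def eo_term_set(self, registry):
        return build_term_set(registry["EO"], ["EO:0007404"], "drought env")

    def test_gene_without_ortholog_unchanged(self, registry, eo_term_set):
        t = propagate(
            read_associations(tsv("Os_r1\trice\tEO:0007404\tEO")), registry
        )
        orthologs = OrthologMap.from_pairs(
            [("rice", "Os_other", "sorghum", "Sb_x")]
        )
        out, summary = transfer_transitive(t, orthologs, "sorghum", eo_term_set)
        assert len(out) == len(t)
        assert summary["n_transitive"] == 0

    def test_rice_annotation_transfers_with_provenance(self, registry,
                                                       eo_term_set):
        t = propagate(
            read_associations(tsv("Os_r1\trice\tEO:0007404\tEO")), registry
        )
        orthologs = OrthologMap.from_pairs([("rice", "Os_r1", "sorghum", "s1")])
        out, summary = transfer_transitive(t, orthologs, "sorghum", eo_term_set)
        added = out[(out.gene_id == "s1") & (out.term_id == "EO:0007404")]
        assert len(added) == 1
        row = added.iloc[0]
        assert row.provenance == TRANSITIVE
        assert (row.source_species, row.source_gene) == ("rice", "Os_r1")
        assert summary["n_transitive"] == 1

    def test_direct_precedence_blocks_transitive(self, registry, eo_term_set):
        t = propagate(read_associations(tsv(
            "Os_r1\trice\tEO:0007404\tEO",
            "s1\tsorghum\tEO:0007404\tEO",
        )), registry)
        orthologs = OrthologMap.from_pairs([("rice", "Os_r1", "sorghum", "s1")])
        out, _ = transfer_transitive(t, orthologs, "sorghum", eo_term_set)
        s1 = out[(out.gene_id == "s1") & (out.species == "sorghum")]
        assert set(s1.provenance) == {DIRECT}

    def test_transfer_conserves_direct_records(self, registry, assoc_table,
                                               eo_term_set):
        prop = propagate(assoc_table, registry)
        orthologs = OrthologMap.from_pairs(
            [("rice", "Os_r1", "sorghum", "Sb_new")]
        )
        out, _ = transfer_transitive(prop, orthologs, "sorghum", eo_term_set)
        n_direct_before = int((prop.provenance == DIRECT).sum())
        n_direct_after = int((out.provenance == DIRECT).sum())
        assert n_direct_after == n_direct_before
        # no record removed
        merged = prop.merge(
            out, on=["gene_id", "species", "term_id", "provenance"], how="left",
            indicator=True,
        )
        assert (merged["_merge"] == "both").all()


class TestOrthologMap:
    def test_symmetric_lookup(self):
        m = OrthologMap.from_pairs([("rice", "r1", "sorghum", "s1")])
        assert m.orthologs_of("sorghum", "s1") == [("rice", "r1")]
        assert m.orthologs_of("rice", "r1") == [("sorghum", "s1")]

    def test_many_to_many_allowed(self):
        m = OrthologMap.from_pairs([
            ("rice", "r1", "sorghum", "s1"),
            ("rice", "r1", "sorghum", "s2"),
            ("maize", "m1", "sorghum", "s1"),
        ])
        assert m.orthologs_of("rice", "r1") == [("sorghum", "s1"),
                                                ("sorghum", "s2")]
        assert m.orthologs_of("sorghum", "s1") == [("maize", "m1"),
                                                   ("rice", "r1")]

    def test_homology_type_filter(self):
        text = io.StringIO(
            "species_a\tgene_a\tspecies_b\tgene_b\thomology_type\n"
            "rice\tr1\tsorghum\ts1\tortholog_one2one\n"
            "rice\tr2\tsorghum\ts2\tortholog_many2many\n"
        )
        m = OrthologMap.read(text, homology_type="ortholog_one2one")
        assert len(m) == 1
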