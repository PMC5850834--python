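"""Scope resolution, donor selection, and functional transfer."""

import pytest

from ogmap import annotate as ann
from ogmap import ogdb
from ogmap.annotate import (
    STATUS_ANNOTATED,
    STATUS_SEED_ONLY,
    STATUS_UNMAPPED,
    ConfigurationError,
    ScopeSetting,
    TransferPolicy,
    annotate_queries,
    annotate_query,
    normalize_gene_name,
    predict_gene_name,
    read_annotations,
    resolve_scope,
    select_orthologs,
    transfer_cog,
    transfer_go,
    transfer_kegg,
    write_annotations,
)
from ogmap.ogdb import FunctionalAnnotation, OrthologousGroup
from ogmap.search import SeedOrtholog


def seed_for(db, pid):
    return SeedOrtholog("q", pid, 100.0, 1e-30, "direct")


class TestResolveScope:
    def test_fixed_scope(self, small_db):
        root = small_db.taxonomy.root
        pid = sorted(next(og for og in small_db.ogs if og.clade == root).members)[0]
        setting = ScopeSetting(mode="fixed", fixed_clade=root)
        assert resolve_scope(seed_for(small_db, pid), small_db, setting) == root

    def test_fixed_scope_must_be_a_level(self, small_db):
        pid = sorted(small_db.ogs[0].members)[0]
        bad = ScopeSetting(mode="fixed", fixed_clade=999999)
        with pytest.raises(ConfigurationError):
            resolve_scope(seed_for(small_db, pid), small_db, bad)

    def test_auto_matches_lineage_scan_oracle(self, small_db):
        setting = ScopeSetting(mode="auto")
        for pid in sorted(small_db.proteins)[:80]:
            ogs = ogdb.ogs_for_protein(small_db, pid)
            if not ogs:
                continue
            got = resolve_scope(seed_for(small_db, pid), small_db, setting)
            # oracle: deepest clade level on the species lineage hosting an OG
            lineage = small_db.taxonomy.lineage(small_db.proteins[pid].taxid)
            candidates = [
                lvl for lvl in small_db.clade_levels
                if lvl in lineage and any(og.clade == lvl for og in ogs)
            ]
            expected = max(candidates, key=lambda t: small_db.taxonomy.depth(t))
            assert got == expected


class TestSelectOrthologs:
    def test_root_scope_no_exclusions_is_identity(self, small_db):
        og = small_db.ogs[0]
        donors = {(pid, "one2one") for pid in og.members}
        policy = TransferPolicy(target_orthologs="all")
        got = select_orthologs(donors, small_db.taxonomy.root, policy, small_db)
        assert got == donors

    def test_one2one_policy_on_many2many_only(self, small_db):
        og = small_db.ogs[0]
        donors = {(pid, "many2many") for pid in og.members}
        policy = TransferPolicy(target_orthologs="one2one")
        assert select_orthologs(donors, small_db.taxonomy.root, policy, small_db) == set()

    def test_matches_set_comprehension_oracle(self, small_db, rng):
        tax = small_db.taxonomy
        og = max(small_db.ogs, key=lambda o: len(o.members))
        donors = {(pid, rel) for pid, rel in
                  zip(sorted(og.members), ["one2one", "many2many", "one2many"] * len(og.members))}
        levels = small_db.clade_levels
        leaves = tax.leaves()
        for _ in range(20):
            scope = levels[int(rng.integers(len(levels)))]
            excl = {int(t) for t in rng.choice(leaves, size=2, replace=False)}
            policy = TransferPolicy(excluded_taxa=excl)
            got = select_orthologs(donors, scope, policy, small_db)
            expected = {
                (pid, rel) for pid, rel in donors
                if scope in tax.lineage(small_db.proteins[pid].taxid)
                and not any(x in tax.lineage(small_db.proteins[pid].taxid) for x in excl)
            }
            assert got == expected


def og_with_terms(member_terms, member_kegg=None, cog="EG", names=None):
    members = set(member_terms)
    per_member = {
        pid: FunctionalAnnotation(
            go_terms=set(terms),
            kegg_pathways=set((member_kegg or {}).get(pid, set())),
            cog_category=cog,
            gene_name=(names or {}).get(pid),
        )
        for pid, terms in member_terms.items()
    }
    newick = "(" + ",".join(sorted(members)) + ");"
    return OrthologousGroup("OGt", 1, members, newick,
                            FunctionalAnnotation(cog_category=cog), per_member)


class TestTransfer:
    def test_no_donors_empty(self, diamond_dag):
        og = og_with_terms({"2.a": set()})
        assert transfer_go([], og, diamond_dag, TransferPolicy()) == set()

    def test_evidence_filter_iea(self, diamond_dag):
        og = og_with_terms({"2.a": {("GO:0000004", "IEA")}})
        donors = [("2.a", "one2one")]
        assert transfer_go(donors, og, diamond_dag, TransferPolicy(go_evidence="experimental")) == set()
        got = transfer_go(donors, og, diamond_dag, TransferPolicy(go_evidence="all"))
        assert got == {"GO:0000001", "GO:0000002", "GO:0000003", "GO:0000004"}

    def test_union_then_closure(self, diamond_dag):
        og = og_with_terms({
            "2.a": {("GO:0000002", "IDA")},
            "3.b": {("GO:0000003", "EXP"), ("GO:0000002", "IMP")},
        })
        donors = [("2.a", "one2one"), ("3.b", "one2one")]
        got = transfer_go(donors, og, diamond_dag, TransferPolicy())
        assert got == {"GO:0000001", "GO:0000002", "GO:0000003"}

    def test_kegg_union_and_cog_verbatim(self, diamond_dag):
        og = og_with_terms(
            {"2.a": set(), "3.b": set()},
            member_kegg={"2.a": {"P1"}, "3.b": {"P1", "P2"}},
            cog="EG",
        )
        donors = [("2.a", "one2one"), ("3.b", "one2one")]
        assert transfer_kegg(donors, og) == {"P1", "P2"}
        assert transfer_kegg([], og) == set()
        assert transfer_cog(og) == "EG"


class TestGeneName:
    def test_normalization(self):
        assert normalize_gene_name("trpB") == "TRPB"
        assert normalize_gene_name("TRPB2") == "TRPB"
        assert normalize_gene_name("abc_3") == "ABC"

    def test_normalized_majority(self, small_db):
        og = og_with_terms({"2.a": set(), "3.b": set(), "4.c": set()},
                           names={"2.a": "abcA", "3.b": "abcA2", "4.c": "xyzZ"})
        donors = [("2.a", "one2one"), ("3.b", "one2one"), ("4.c", "one2one")]
        assert predict_gene_name(donors, og, small_db) == "ABCA"

    def test_mixed_case_copy_number_merge(self, small_db):
        og = og_with_terms({"2.a": set(), "3.b": set()},
                           names={"2.a": "trpB", "3.b": "TRPB2"})
        donors = [("2.a", "one2one"), ("3.b", "one2one")]
        assert predict_gene_name(donors, og, small_db) == "TRPB"

    def test_no_names_returns_none(self, small_db):
        og = og_with_terms({"2.a": set()})
        assert predict_gene_name([("2.a", "one2one")], og, small_db) is None


class TestAnnotateQuery:
    def test_unmapped_for_alien_sequence(self, small_sim):
        r = annotate_query("alien", "W" * 60, small_sim.db, small_sim.dag,
                           policy=TransferPolicy(max_evalue=1e-10))
        assert r.status == STATUS_UNMAPPED and r.seed is None

    def test_self_taxon_exclusion_removes_all_same_species_sources(self, small_sim):
        db, dag = small_sim.db, small_sim.dag
        held = db.taxonomy.leaves()[1]
        queries = {pid: db.proteins[pid].sequence
                   for pid in sorted(db.proteins) if db.proteins[pid].taxid == held}
        queries = dict(list(queries.items())[:5])
        policy = TransferPolicy(excluded_taxa={held}, go_evidence="all")
        for r in annotate_queries(queries, db, dag, policy=policy):
            if r.seed is not None:
                assert db.proteins[r.seed.protein_id].taxid != held
            for pid, _ in r.orthologs_used:
                assert db.proteins[pid].taxid != held

    def test_policy_containment(self, small_sim):
        db, dag = small_sim.db, small_sim.dag
        held = db.taxonomy.leaves()[0]
        queries = {pid: db.proteins[pid].sequence
                   for pid in sorted(db.proteins) if db.proteins[pid].taxid == held}
        queries = dict(list(queries.items())[:6])

        def run(**kw):
            return {r.query_id: r for r in annotate_queries(
                queries, db, dag, policy=TransferPolicy(excluded_taxa={held}, **kw))}

        res_all = run(target_orthologs="all", go_evidence="all")
        res_121 = run(target_orthologs="one2one", go_evidence="all")
        res_exp = run(target_orthologs="all", go_evidence="experimental")
        res_ne = run(target_orthologs="all", go_evidence="non_electronic")
        for q in queries:
            assert res_121[q].go_terms <= res_all[q].go_terms
            assert res_exp[q].go_terms <= res_ne[q].go_terms <= res_all[q].go_terms
        n_ann = lambda res: sum(1 for r in res.values() if r.status == STATUS_ANNOTATED)
        assert n_ann(res_121) <= n_ann(res_all)

    def test_seed_only_when_donors_filtered_out(self, small_sim):
        db, dag = small_sim.db, small_sim.dag
        # exclude every species: no donor can survive, but the query's own
        # protein is found as seed when its taxon is not excluded from search
        og = next(og for og in db.ogs if len({db.proteins[m].taxid for m in og.members}) >= 2)
        pid = sorted(og.members)[0]
        other_taxa = {t for t in db.taxonomy.leaves() if t != db.proteins[pid].taxid}
        r = annotate_query("q", db.proteins[pid].sequence, db, dag,
                           policy=TransferPolicy(excluded_taxa=other_taxa, go_evidence="all"))
        assert r.status in (STATUS_SEED_ONLY, STATUS_ANNOTATED)
        if r.status == STATUS_SEED_ONLY:
            assert r.cog_category != "" or r.og_id is None

    def test_tsv_roundtrip(self, small_sim, tmp_path):
        db, dag = small_sim.db, small_sim.dag
        pid = sorted(small_sim.db.ogs[0].members)[0]
        results = annotate_queries({"q1": db.proteins[pid].sequence, "q2": "W" * 40},
                                   db, dag, policy=TransferPolicy(go_evidence="all"))
        out = tmp_path / "ann.tsv"
        write_annotations(results, out)
        rows = read_annotations(out)
        assert [r["query"] for r in rows] == ["q1", "q2"]
        by_q = {r["query"]: r for r in rows}
        r1 = next(r for r in results if r.query_id == "q1")
        assert by_q["q1"]["go_terms"] == r1.go_terms
        assert by_q["q1"]["status"] == r1.status
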