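"""Cluster extraction, discrepancy detection/repair, flat file, statistics."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from ontoxref.fixtures import FixtureSpec, generate_fixture
from ontoxref.model import TermRef
from ontoxref.xref import (
    ConfigurationError,
    DiscrepancyKind,
    Matching,
    contribution_stats,
    detect_multilevel_refs,
    detect_obsolete_refs,
    extract_matchings,
    read_xref_tsv,
    repair_matchings,
    validate_atomicity,
    write_xref_tsv,
)

from conftest import CKD_MEMBERS, make_ontology


class TestMatchingTriple:
    def test_similarity_degree_is_binary(self):
        a, b = TermRef("MONDO", "MONDO_1"), TermRef("DOID", "DOID_1")
        assert Matching(a, b, 1).s == 1
        with pytest.raises(ValueError):
            Matching(a, b, 2)
        with pytest.raises(ValueError):
            Matching(a, b, 0.5)

    def test_matching_pairs_distinct_ontologies(self):
        a = TermRef("MONDO", "MONDO_1")
        with pytest.raises(ValueError):
            Matching(a, TermRef("MONDO", "MONDO_2"), 1)


class TestExtractMatchings:
    def test_ckd_record_defines_six_matching_pairs(self, ckd_mondo):
        build = extract_matchings({"MONDO": ckd_mondo})
        ckd = next(
            c for c in build.clusters
            if c.preferred == TermRef("MONDO", "MONDO_0005300")
        )
        assert ckd.members == CKD_MEMBERS
        assert len(ckd.atomic_mappings()) == 6
        assert all(m.s == 1 for m in build.matchings)
        assert sum(m.t_id == ckd.preferred for m in build.matchings) == 6

    def test_no_xrefs_means_singleton_clusters(self):
        ontology = make_ontology("MONDO", {"a": ("x",), "b": ("y",)})
        build = extract_matchings({"MONDO": ontology})
        assert len(build.clusters) == 2
        assert all(not c.members for c in build.clusters)
        assert build.matchings == []

    def test_hub_bridge_joins_via_shared_umls_cui(self):
        # NCIT knows only its UMLS CUI; MONDO references the same CUI:
        # the NCIT term must join the MONDO cluster through the hub.
        mondo = make_ontology("MONDO", {"MONDO_1": ("ckd", (), ["UMLS:C1"])})
        umls = make_ontology("UMLS", {"C1": ("ckd",)})
        ncit = make_ontology("NCIT", {"NCIT_C9": ("ckd", (), ["UMLS:C1"])})
        build = extract_matchings({"MONDO": mondo, "UMLS": umls, "NCIT": ncit})
        (cluster,) = [c for c in build.clusters if c.preferred.ontology == "MONDO"]
        assert cluster.members == {"UMLS": "C1", "NCIT": "NCIT_C9"}
        assert cluster.provenance["NCIT"] == "hub-bridged"
        assert len(build.clusters) == 1

    def test_reverse_evidence_only_when_enabled(self):
        mondo = make_ontology("MONDO", {"MONDO_1": ("ckd",)})
        doid = make_ontology("DOID", {"DOID_7": ("ckd", (), ["MONDO:MONDO_1"])})
        direct = extract_matchings({"MONDO": mondo, "DOID": doid}, evidence="direct")
        assert all(not c.members for c in direct.clusters)
        both = extract_matchings({"MONDO": mondo, "DOID": doid})
        (cluster,) = [c for c in both.clusters if c.preferred.ontology == "MONDO"]
        assert cluster.members == {"DOID": "DOID_7"}
        assert cluster.provenance["DOID"] == "reverse"

    def test_non_preferred_terms_seed_fallback_clusters(self):
        mondo = make_ontology("MONDO", {"MONDO_1": ("a",)})
        mesh = make_ontology("MESH", {"D1": ("b", (), ["OMIM:111111"])})
        omim = make_ontology("OMIM", {"111111": ("b",)})
        build = extract_matchings({"MONDO": mondo, "MESH": mesh, "OMIM": omim})
        preferred = {c.preferred.ontology for c in build.clusters}
        assert preferred == {"MONDO", "MESH"}
        mesh_cluster = next(c for c in build.clusters if c.preferred.ontology == "MESH")
        assert mesh_cluster.members == {"OMIM": "111111"}

    def test_unknown_preference_namespace_is_a_configuration_error(self, ckd_mondo):
        with pytest.raises(ConfigurationError):
            extract_matchings({"MONDO": ckd_mondo}, preference_order=["NOPE"])

    def test_cyclic_hierarchy_refused_without_force(self):
        from ontoxref.xref import CyclicHierarchyError

        cyclic = make_ontology("MONDO", {"a": ("", {"b"}), "b": ("", {"a"})})
        with pytest.raises(CyclicHierarchyError):
            extract_matchings({"MONDO": cyclic})
        assert extract_matchings({"MONDO": cyclic}, force=True).clusters

    def test_invariant_under_input_permutation(self):
        fixture = generate_fixture(
            FixtureSpec(master_tree_size=40, n_ontologies=5, retention=0.7, seed=11)
        )
        forward = extract_matchings(dict(fixture.ontologies))
        reversed_order = extract_matchings(
            dict(reversed(list(fixture.ontologies.items())))
        )
        assert forward.clusters == reversed_order.clusters
        assert forward.matchings == reversed_order.matchings


class TestDiscrepancies:
    def _obsolete_pair(self):
        mondo = make_ontology("MONDO", {"MONDO_1": ("ckd", (), ["DOID:9"])})
        doid = make_ontology("DOID", {
            "DOID_9": ("old ckd", (), (), True, "DOID_10"),
            "DOID_10": ("ckd",),
        })
        return {"MONDO": mondo, "DOID": doid}

    def test_obsolete_target_with_replacement_plans_follow(self):
        found = detect_obsolete_refs(self._obsolete_pair())
        assert [d.kind for d in found] == [DiscrepancyKind.OBSOLETE_TARGET]
        assert found[0].repair == "follow-replaced-by:DOID_10"
        assert found[0].targets == (TermRef("DOID", "DOID_9"),)

    def test_obsolete_target_without_replacement_plans_drop(self):
        ontologies = self._obsolete_pair()
        ontologies["DOID"].terms["DOID_9"].replaced_by = None
        (found,) = detect_obsolete_refs(ontologies)
        assert found.repair == "drop"
        repaired, _ = repair_matchings(ontologies, [found])
        assert not repaired["MONDO"].terms["MONDO_1"].xrefs
        # the source inputs stay untouched
        assert ontologies["MONDO"].terms["MONDO_1"].xrefs

    def test_clean_ontologies_have_no_discrepancies(self, ckd_mondo):
        assert detect_obsolete_refs({"MONDO": ckd_mondo}) == []
        assert detect_multilevel_refs({"MONDO": ckd_mondo}) == []

    def test_multilevel_group_collapses_to_referenced_ancestor(self):
        doid = make_ontology("DOID", {
            "DOID_1": ("kidney disease",),
            "DOID_2": ("ckd", {"DOID_1"}),
            "DOID_3": ("ckd stage 3", {"DOID_2"}),
            "DOID_4": ("ckd stage 4", {"DOID_2"}),
        })
        mondo = make_ontology("MONDO", {
            "MONDO_1": ("ckd", (), ["DOID:2", "DOID:3", "DOID:4"]),
        })
        (found,) = detect_multilevel_refs({"MONDO": mondo, "DOID": doid})
        assert found.kind is DiscrepancyKind.MULTILEVEL
        assert found.repair == "collapse-to-parent:DOID_2"
        assert found.targets[0] == TermRef("DOID", "DOID_2")
        repaired, _ = repair_matchings({"MONDO": mondo, "DOID": doid}, [found])
        targets = {x.target_id for x in repaired["MONDO"].terms["MONDO_1"].xrefs}
        assert targets == {"DOID_2"}

    def test_singleton_reference_is_not_multilevel(self):
        doid = make_ontology("DOID", {"DOID_1": ("x",)})
        mondo = make_ontology("MONDO", {"MONDO_1": ("x", (), ["DOID:1"])})
        assert detect_multilevel_refs({"MONDO": mondo, "DOID": doid}) == []

    def test_sibling_references_are_unrepaired(self):
        doid = make_ontology("DOID", {
            "DOID_1": ("root",),
            "DOID_2": ("a", {"DOID_1"}),
            "DOID_3": ("b", {"DOID_1"}),
        })
        mondo = make_ontology("MONDO", {"MONDO_1": ("x", (), ["DOID:2", "DOID:3"])})
        (found,) = detect_multilevel_refs({"MONDO": mondo, "DOID": doid})
        assert found.repair == "unrepaired"
        repaired, _ = repair_matchings({"MONDO": mondo, "DOID": doid}, [found])
        assert len(repaired["MONDO"].terms["MONDO_1"].xrefs) == 2  # untouched

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_planted_defects_are_detected_exactly(self, seed):
        fixture = generate_fixture(
            FixtureSpec(master_tree_size=50, n_ontologies=5, retention=0.85,
                        n_obsolete_refs=3, n_multilevel_refs=2, n_conflicts=2,
                        seed=seed)
        )
        obsolete = detect_obsolete_refs(fixture.ontologies)
        assert {(d.source, d.targets[0]) for d in obsolete} == {
            (p.source, p.obsolete_target) for p in fixture.truth.obsolete_refs
        }
        multilevel = detect_multilevel_refs(fixture.ontologies)
        repairable = {d for d in multilevel if d.repairable}
        assert {(d.source, d.targets[0]) for d in repairable} == {
            (p.source, p.parent_target) for p in fixture.truth.multilevel_refs
        }
        # planted conflicts surface as the unrepaired multilevel groups
        unrepaired = {d for d in multilevel if not d.repairable}
        assert {(d.source, tuple(t.local_id for t in d.targets)) for d in unrepaired} == {
            (p.source, p.candidates) for p in fixture.truth.conflicts
        }

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_detect_and_repair_is_idempotent(self, seed):
        fixture = generate_fixture(
            FixtureSpec(master_tree_size=40, n_ontologies=4, retention=0.8,
                        n_obsolete_refs=2, n_multilevel_refs=2, n_conflicts=1,
                        seed=seed)
        )
        discrepancies = detect_obsolete_refs(fixture.ontologies) + \
            detect_multilevel_refs(fixture.ontologies)
        once, _ = repair_matchings(fixture.ontologies, discrepancies)
        remaining = detect_obsolete_refs(once) + detect_multilevel_refs(once)
        assert all(not d.repairable for d in remaining)
        twice, _ = repair_matchings(once, remaining)
        assert {ns: o.terms for ns, o in twice.items()} == {
            ns: o.terms for ns, o in once.items()
        }


class TestAtomicity:
    def test_ckd_cluster_is_atomic(self, ckd_mondo):
        build = extract_matchings({"MONDO": ckd_mondo})
        assert validate_atomicity(build.clusters) == []

    def test_two_unrelated_doid_candidates_are_a_violation(self):
        doid = make_ontology("DOID", {"DOID_1": ("a",), "DOID_2": ("b",)})
        mondo = make_ontology("MONDO", {"MONDO_1": ("x", (), ["DOID:1", "DOID:2"])})
        build = extract_matchings({"MONDO": mondo, "DOID": doid})
        (violation,) = validate_atomicity(build.clusters)
        assert violation.namespace == "DOID"
        assert violation.candidates == ("DOID_1", "DOID_2")
        # default policy: neither candidate admitted
        cluster = next(c for c in build.clusters if c.preferred.ontology == "MONDO")
        assert "DOID" not in cluster.members

    def test_keep_first_admits_best_evidenced_candidate(self):
        doid = make_ontology("DOID", {"DOID_1": ("a",), "DOID_2": ("b",)})
        mondo = make_ontology("MONDO", {"MONDO_1": ("x", (), ["DOID:1", "DOID:2"])})
        build = extract_matchings({"MONDO": mondo, "DOID": doid}, keep_first=True)
        cluster = next(c for c in build.clusters if c.preferred.ontology == "MONDO")
        assert cluster.members["DOID"] == "DOID_1"
        assert validate_atomicity(build.clusters)  # still reported for curation

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_violation_count_matches_planted_conflicts(self, seed):
        fixture = generate_fixture(
            FixtureSpec(master_tree_size=60, n_ontologies=5, retention=0.9,
                        n_conflicts=3, seed=seed)
        )
        build = extract_matchings(fixture.ontologies)
        violations = validate_atomicity(build.clusters)
        assert len(violations) == 3
        assert {tuple(v.candidates) for v in violations} == {
            p.candidates for p in fixture.truth.conflicts
        }
        # atomicity invariant holds regardless: at most one member per namespace
        for cluster in build.clusters:
            assert len(set(cluster.members)) == len(cluster.members)


class TestXrefFlatFile:
    def test_ckd_row_has_six_member_cells(self, ckd_mondo):
        build = extract_matchings({"MONDO": ckd_mondo})
        buffer = io.StringIO()
        rows = write_xref_tsv(build.clusters, buffer)
        assert rows == 2  # CKD + the xref-less second term
        lines = buffer.getvalue().splitlines()
        header = lines[0].split("\t")
        assert header[:3] == ["preferred_id", "preferred_ontology", "label"]
        ckd_row = next(l for l in lines if l.startswith("MONDO_0005300")).split("\t")
        assert sum(1 for cell in ckd_row[3:] if cell) == 6

    def test_zero_clusters_writes_header_only(self):
        buffer = io.StringIO()
        assert write_xref_tsv([], buffer) == 0
        assert len(buffer.getvalue().splitlines()) == 1

    def test_duplicate_preferred_id_rejected_on_read(self):
        text = (
            "preferred_id\tpreferred_ontology\tlabel\tMONDO\tMESH\n"
            "D1\tMESH\tx\t\t\nD1\tMESH\ty\t\t\n"
        )
        with pytest.raises(ValueError, match="duplicate preferred_id"):
            read_xref_tsv(io.StringIO(text))

    def test_multi_value_member_cell_rejected_on_read(self):
        text = (
            "preferred_id\tpreferred_ontology\tlabel\tMONDO\tMESH\n"
            "MONDO_1\tMONDO\tx\t\tD1|D2\n"
        )
        with pytest.raises(ValueError, match="multiple values"):
            read_xref_tsv(io.StringIO(text))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_identity(self, seed):
        fixture = generate_fixture(
            FixtureSpec(master_tree_size=50, n_ontologies=6, retention=0.8, seed=seed)
        )
        build = extract_matchings(fixture.ontologies)
        buffer = io.StringIO()
        write_xref_tsv(build.clusters, buffer)
        buffer.seek(0)
        assert read_xref_tsv(buffer) == sorted(
            build.clusters, key=lambda c: (c.preferred.local_id, c.preferred.ontology)
        )


class TestContributionStats:
    def test_single_ckd_cluster_counts(self, ckd_mondo):
        build = extract_matchings({"MONDO": ckd_mondo})
        frame = contribution_stats(build.clusters)
        assert frame.loc["MONDO", "preferred_terms"] == 2
        assert frame.loc["MONDO", "terms_only"] == 1  # the xref-less term
        assert frame.loc["MESH", "references"] == 1
        assert frame.loc["MESH", "unique_references"] == 1
        assert frame.loc["ICD10", "references"] == 1
        assert frame.loc["Total", "preferred_terms"] == len(build.clusters)

    def test_empty_cluster_set_is_all_zero(self):
        frame = contribution_stats([])
        assert (frame.drop(index="Total") == 0).all().all()

    def test_shared_code_counts_references_but_one_unique(self):
        # three diseases pointing at one coarse ICD-10 code: 3 references,
        # 1 unique reference (the many-to-one pattern of coarse terminologies)
        mondo = make_ontology("MONDO", {
            "MONDO_1": ("a", (), ["ICD10:N18.9"]),
            "MONDO_2": ("b", (), ["ICD10:N18.9"]),
            "MONDO_3": ("c", (), ["ICD10:N18.9"]),
        })
        build = extract_matchings({"MONDO": mondo})
        frame = contribution_stats(build.clusters)
        assert frame.loc["ICD10", "references"] == 3
        assert frame.loc["ICD10", "unique_references"] == 1

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_reference_conservation(self, seed):
        fixture = generate_fixture(
            FixtureSpec(master_tree_size=40, n_ontologies=5, retention=0.8, seed=seed)
        )
        build = extract_matchings(fixture.ontologies)
        frame = contribution_stats(build.clusters)
        assert frame.loc["Total", "references"] == sum(
            1 + len(c.members) for c in build.clusters
        )
        assert frame.loc["Total", "preferred_terms"] == len(build.clusters)
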