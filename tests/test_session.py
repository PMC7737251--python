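"""Mapping project state machine, privileges, comments and audit log."""

import random

import pytest

from dictmap.errors import (
    ConfigError,
    NotFoundError,
    PermissionDeniedError,
    StateError,
    ValidationError,
)
from dictmap.session import MappingProject, create_project, replay_log

from conftest import fixed_clock, make_dictionary


@pytest.fixture
def project(toy_ontology, three_variable_dictionary):
    return create_project(
        "kcr", "registry mapping", toy_ontology, three_variable_dictionary,
        owner="alice", clock=fixed_clock(),
    )


class TestCreate:
    def test_defaults_private_with_empty_state(self, project):
        assert project.visibility == "private"
        assert project.mappings == {}
        assert project.log == []
        assert project.status_summary().mapped_count == 0

    def test_owner_holds_both_privileges(self, project):
        assert project.has_can_edit("alice")
        assert project.has_can_map("alice")

    def test_invalid_display_field_is_config_error(self, toy_ontology, three_variable_dictionary):
        with pytest.raises(ConfigError):
            create_project(
                "p", "", toy_ontology, three_variable_dictionary,
                owner="alice", display_fields=["NotAColumn"],
            )

    def test_invalid_search_field_is_config_error(self, toy_ontology, three_variable_dictionary):
        with pytest.raises(ConfigError):
            create_project(
                "p", "", toy_ontology, three_variable_dictionary,
                owner="alice", default_search_field="NotAColumn",
            )

    def test_public_project_admits_any_user(self, toy_ontology, three_variable_dictionary):
        public = create_project(
            "open", "", toy_ontology, three_variable_dictionary,
            owner="alice", visibility="public",
        )
        public.record_mapping("random_user", "Race 1", "A")
        assert public.status_summary().mapped_count == 1


class TestPrivileges:
    def test_owner_grants_can_map(self, project):
        project.grant_privilege("alice", "bob", "can_map")
        project.record_mapping("bob", "Race 1", "A")
        assert "Race 1" in project.mappings

    def test_can_map_holder_cannot_grant(self, project):
        project.grant_privilege("alice", "bob", "can_map")
        with pytest.raises(PermissionDeniedError):
            project.grant_privilege("bob", "carol", "can_map")

    def test_can_edit_subsumes_can_map(self, project):
        project.grant_privilege("alice", "carol", "can_edit")
        assert project.has_can_edit("carol")
        assert project.has_can_map("carol")
        project.grant_privilege("carol", "dave", "can_map")  # carol can now grant

    def test_unprivileged_user_cannot_map(self, project):
        with pytest.raises(PermissionDeniedError):
            project.record_mapping("mallory", "Race 1", "A")
        assert project.log == []


class TestMappingStateMachine:
    def test_mapping_sets_status_and_logs(self, project):
        project.record_mapping("alice", "Race 1", "A")
        summary = project.status_summary()
        assert summary.per_variable_status["Race 1"] == "M"
        assert summary.mapped_count == 1
        assert len(project.log) == 1
        assert project.log[0].action == "MAP"
        assert project.log[0].concept_id == "A"

    def test_remapping_requires_delete_first(self, project):
        project.record_mapping("alice", "Race 1", "A")
        with pytest.raises(StateError, match="delete the existing match"):
            project.record_mapping("alice", "Race 1", "B")

    def test_many_variables_may_share_one_concept(self, project):
        project.record_mapping("alice", "Race 1", "A")
        project.record_mapping("alice", "Sex", "A")
        assert {m.concept_id for m in project.mappings.values()} == {"A"}

    def test_unmap_then_remap(self, project):
        project.record_mapping("alice", "Race 1", "A")
        project.remove_mapping("alice", "Race 1")
        project.record_mapping("alice", "Race 1", "B")
        assert project.mappings["Race 1"].concept_id == "B"
        assert [e.action for e in project.log] == ["MAP", "UNMAP", "MAP"]

    def test_unmap_unmapped_variable_is_state_error(self, project):
        with pytest.raises(StateError):
            project.remove_mapping("alice", "Race 1")

    def test_unknown_variable_or_concept(self, project):
        with pytest.raises(NotFoundError):
            project.record_mapping("alice", "Nope", "A")
        with pytest.raises(NotFoundError):
            project.record_mapping("alice", "Race 1", "Z")

    def test_unmap_without_privilege_leaves_state_unchanged(self, project):
        project.record_mapping("alice", "Race 1", "A")
        with pytest.raises(PermissionDeniedError):
            project.remove_mapping("mallory", "Race 1")
        assert project.mappings["Race 1"].concept_id == "A"


class TestComments:
    def test_comment_count_increments(self, project):
        assert project.comment_count("Race 1") == 0
        project.add_comment("alice", "Race 1", "checked against registry manual")
        assert project.comment_count("Race 1") == 1

    def test_comment_order_preserved(self, project):
        for body in ("first", "second", "third"):
            project.add_comment("alice", "Race 1", body)
        assert [c.body for c in project.comments["Race 1"]] == ["first", "second", "third"]
        assert project.comment_count("Race 1") == 3

    def test_empty_body_rejected(self, project):
        with pytest.raises(ValidationError):
            project.add_comment("alice", "Race 1", "   ")

    def test_comment_on_unknown_variable(self, project):
        with pytest.raises(NotFoundError):
            project.add_comment("alice", "Nope", "body")


class TestStatusSummary:
    def test_counts_sum_to_dictionary_size(self, project):
        project.record_mapping("alice", "Race 1", "A")
        summary = project.status_summary()
        assert summary.mapped_count + summary.unmapped_count == 3
        assert summary.mapped_count == 1

    def test_fresh_project_all_unmapped(self, project):
        summary = project.status_summary()
        assert (summary.mapped_count, summary.unmapped_count) == (0, 3)


def random_operations(project, rng, users=("alice", "bob"), steps=40):
    """Random legal MAP/UNMAP/COMMENT sequence against a project."""
    project.grant_privilege("alice", "bob", "can_map")
    variable_ids = [v.variable_id for v in project.dictionary.variables]
    concept_ids = sorted(project.ontology.concepts)
    for _ in range(steps):
        user = rng.choice(users)
        vid = rng.choice(variable_ids)
        op = rng.choice(("map", "unmap", "comment"))
        if op == "map" and vid not in project.mappings:
            project.record_mapping(user, vid, rng.choice(concept_ids))
        elif op == "unmap" and vid in project.mappings:
            project.remove_mapping(user, vid)
        elif op == "comment":
            project.add_comment(user, vid, f"note {rng.random():.3f}")


class TestLogProperties:
    @pytest.mark.parametrize("seed", range(20))
    def test_replaying_the_log_reconstructs_the_mapping_state(
        self, seed, toy_ontology
    ):
        rng = random.Random(seed)
        dictionary = make_dictionary([f"V{i}" for i in range(6)])
        project = create_project(
            "replay", "", toy_ontology, dictionary, owner="alice", clock=fixed_clock()
        )
        random_operations(project, rng)
        rebuilt = replay_log(project.log, toy_ontology, dictionary)
        live = {vid: m.concept_id for vid, m in project.mappings.items()}
        assert rebuilt == live

    def test_log_is_append_only_across_operations(self, project):
        lengths = [len(project.log)]
        project.record_mapping("alice", "Race 1", "A")
        lengths.append(len(project.log))
        project.add_comment("alice", "Race 1", "ok")
        lengths.append(len(project.log))
        project.remove_mapping("alice", "Race 1")
        lengths.append(len(project.log))
        assert lengths == sorted(lengths) and lengths[-1] == 3


class TestPersistence:
    def test_project_file_round_trip(self, project, tmp_path):
        project.record_mapping("alice", "Race 1", "A")
        project.add_comment("alice", "Race 1", "checked")
        project.grant_privilege("alice", "bob", "can_map")
        path = tmp_path / "proj.json"
        project.save(path)
        loaded = MappingProject.load(path, project.ontology, project.dictionary)
        assert loaded.to_dict() == project.to_dict()
        # loaded project remains operable
        loaded.record_mapping("bob", "Sex", "B")
        assert loaded.status_summary().mapped_count == 2
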