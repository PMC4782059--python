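"""HED vocabulary, tag-string parsing, validation, matching and search."""

from __future__ import annotations

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from esskit.errors import HedParseError, VocabularyError
from esskit.hed import (
    HedString,
    HedTag,
    default_hierarchy,
    load_hierarchy,
    parse_hed_string,
    parse_hed_tag,
    search_event_instances,
    tag_matches,
    validate_hed_string,
)
from esskit.hed import _parse_vocabulary_text
from esskit.model import EventInstance


# ---------------------------------------------------------------------------
# Hierarchy loading


class TestHierarchy:
    def test_snapshot_contains_oddball_paths(self):
        h = default_hierarchy()
        for path in (
            "Participant/Effect/Cognitive/Oddball/Target",
            "Participant/Effect/Cognitive/Expected",
            "Participant/Effect/Auditory",
            "Sensory Presentation/Auditory/Ding",
            "Sensory Presentation/Auditory/Buzz",
            "Event/Category/Experimental stimulus",
        ):
            assert h.find(path.split("/")) is not None, path

    def test_single_root_zero_children(self):
        h = _parse_vocabulary_text("OnlyRoot\n")
        assert [r.name for r in h.roots] == ["OnlyRoot"]
        assert h.roots[0].children == []

    def test_case_insensitive_sibling_clash_rejected(self):
        with pytest.raises(VocabularyError, match="duplicate"):
            _parse_vocabulary_text("Root\n\tA\n\ta\n")

    def test_attribute_flags_parsed(self):
        h = default_hierarchy()
        assert h.find(["Sensory Presentation", "Auditory"]).extension_allowed
        assert h.find(["Event", "Label"]).takes_value

    def test_indentation_jump_rejected(self):
        with pytest.raises(VocabularyError, match="indentation"):
            _parse_vocabulary_text("Root\n\t\t\tTooDeep\n")

    def test_load_from_file(self, tmp_path):
        p = tmp_path / "vocab.txt"
        p.write_text("A\n\tB [takesValue]\n", encoding="utf-8")
        h = load_hierarchy(p)
        assert h.find(["A", "B"]).takes_value


# ---------------------------------------------------------------------------
# Parsing


class TestParse:
    def test_ding_annotation_has_two_tags(self):
        s = parse_hed_string(
            "Sensory Presentation/Auditory/Ding, Participant/Effect/Auditory"
        )
        assert len(s.items) == 2
        assert all(isinstance(i, HedTag) for i in s.items)

    def test_single_tag_path(self):
        s = parse_hed_string("A/B")
        assert s.items == [HedTag(("A", "B"))]

    def test_group_roundtrip(self):
        text = "(A/B, C), D"
        s = parse_hed_string(text)
        assert len(s.items) == 2
        group, tag = s.items
        assert isinstance(group, HedString) and len(group.items) == 2
        assert str(s) == text

    @pytest.mark.parametrize(
        "bad",
        ["(A/B", "A)", "A,,B", ",A", "A,", "( )", "", "   ", "A ~ B", "(A) B"],
    )
    def test_malformed_rejected(self, bad):
        with pytest.raises(HedParseError):
            parse_hed_string(bad)

    def test_whitespace_normalized(self):
        assert parse_hed_string(" A/B ,  ( C , D/E ) ") == parse_hed_string(
            "A/B, (C, D/E)"
        )


# tags drawn mostly from the shipped vocabulary, occasionally off it
_tag_strategy = st.one_of(
    st.sampled_from(
        [
            "Sensory Presentation/Auditory/Ding",
            "Sensory Presentation/Auditory/Buzz",
            "Participant/Effect/Auditory",
            "Participant/Effect/Cognitive/Oddball/Target",
            "Event/Category/Experimental stimulus",
            "Attribute/Onset",
        ]
    ),
    st.lists(
        st.text(alphabet="abXY 3", min_size=1, max_size=4).map(str.strip).filter(bool),
        min_size=1,
        max_size=4,
    ).map("/".join),
).map(parse_hed_tag)


@st.composite
def _hed_strings(draw, depth=0):
    n = draw(st.integers(1, 4))
    items = []
    for _ in range(n):
        if depth < 2 and draw(st.booleans()) and draw(st.booleans()):
            items.append(draw(_hed_strings(depth=depth + 1)))
        else:
            items.append(draw(_tag_strategy))
    return HedString(items)


class TestRoundTripProperty:
    @given(_hed_strings())
    def test_serialize_parse_identity(self, s):
        assert parse_hed_string(str(s)) == s


# ---------------------------------------------------------------------------
# Vocabulary validation


class TestValidate:
    def test_known_path_clean(self):
        s = parse_hed_string("Participant/Effect/Cognitive/Expected")
        assert validate_hed_string(s) == []

    def test_unknown_node_flagged(self):
        s = parse_hed_string("Participant/Nonexistent/X")
        issues = validate_hed_string(s)
        assert len(issues) == 1 and issues[0].kind == "unknown-node"

    def test_extension_below_extensible_node_ok(self):
        s = parse_hed_string("Sensory Presentation/Auditory/Chirp")
        assert validate_hed_string(s) == []

    def test_two_levels_below_rigid_node_flagged(self):
        s = parse_hed_string("Participant/Effect/Cognitive/Expected/X/Y")
        assert len(validate_hed_string(s)) == 1

    def test_value_below_takes_value_ok(self):
        assert validate_hed_string(parse_hed_string("Event/Label/my code 7")) == []
        assert len(validate_hed_string(parse_hed_string("Event/Label/a/b"))) == 1

    def test_extension_acceptance_matches_tree_walk(self):
        """Brute-force oracle: appending an unknown component below node N is
        accepted exactly when N allows extension or takes a value."""
        h = default_hierarchy()
        nodes = []

        def walk(node, path):
            nodes.append((node, path))
            for c in node.children:
                walk(c, path + [c.name])

        for r in h.roots:
            walk(r, [r.name])
        for node, path in nodes:
            s = HedString([HedTag(tuple(path + ["Zzz unknown"]))])
            clean = validate_hed_string(s, h) == []
            assert clean == (node.extension_allowed or node.takes_value), path

    def test_group_members_validated(self):
        s = parse_hed_string("(Participant/Nonexistent/X, Attribute/Onset)")
        assert len(validate_hed_string(s)) == 1


# ---------------------------------------------------------------------------
# Matching and search


class TestMatching:
    @pytest.mark.parametrize(
        "tag,query,expected",
        [
            ("Participant/Effect/Cognitive/Oddball/Target", "Participant/Effect", True),
            ("Participant/Effect/Cognitive/Oddball/Target", "Sensory Presentation", False),
            ("a/b/c", "A/B/C", True),
            ("A/B", "A/B/C", False),
            ("A/B", "A/B", True),
        ],
    )
    def test_prefix_semantics(self, tag, query, expected):
        assert tag_matches(parse_hed_tag(tag), parse_hed_tag(query)) is expected

    @given(_tag_strategy, st.integers(1, 5))
    def test_prefix_transitivity(self, tag, cut):
        """If a tag matches query Q2 and Q1 is a prefix of Q2, it matches Q1."""
        q2 = HedTag(tag.path[: min(cut, len(tag.path))])
        for k in range(1, len(q2.path) + 1):
            q1 = HedTag(q2.path[:k])
            assert tag_matches(tag, q2) and tag_matches(tag, q1)


def _brute_force_search(events, query):
    """Independent oracle: exhaustive scan over every tag of every event,
    comparing lowercased path prefixes directly."""
    q = tuple(p.lower() for p in query.path)
    hits = []
    for ev in events:
        found = False
        stack = list(ev.hed_string.items)
        while stack:
            item = stack.pop()
            if isinstance(item, HedString):
                stack.extend(item.items)
            else:
                p = tuple(x.lower() for x in item.path)
                if p[: len(q)] == q:
                    found = True
        if found:
            hits.append(ev)
    return hits


class TestSearch:
    def _oddball_events(self):
        ding = parse_hed_string(
            "Sensory Presentation/Auditory/Ding, Participant/Effect/Auditory, "
            "Participant/Effect/Cognitive/Expected"
        )
        buzz = parse_hed_string(
            "Sensory Presentation/Auditory/Buzz, Participant/Effect/Auditory, "
            "Participant/Effect/Cognitive/Oddball/Target"
        )
        return [
            EventInstance("ding", 1.0, ding),
            EventInstance("buzz", 2.5, buzz),
            EventInstance("ding", 3.0, ding),
        ]

    def test_oddball_query_selects_only_buzz(self):
        events = self._oddball_events()
        hits = search_event_instances(
            events, parse_hed_tag("Participant/Effect/Cognitive/Oddball")
        )
        assert [e.code for e in hits] == ["buzz"]

    def test_no_match_empty(self):
        assert search_event_instances(
            self._oddball_events(), parse_hed_tag("Action/Button press")
        ) == []

    def test_full_path_query_returns_all_carriers(self):
        events = self._oddball_events()
        hits = search_event_instances(
            events, parse_hed_tag("Sensory Presentation/Auditory/Ding")
        )
        assert [e.code for e in hits] == ["ding", "ding"]

    def test_search_equals_brute_force_on_random_event_sets(self):
        """>= 1000 random events across many sets, vs the exhaustive oracle."""
        rng = random.Random(1234)
        pool = [
            "Sensory Presentation/Auditory/Ding",
            "Sensory Presentation/Auditory/Buzz",
            "Sensory Presentation/Visual/Checkerboard",
            "Participant/Effect/Auditory",
            "Participant/Effect/Cognitive/Oddball/Target",
            "Participant/Effect/Cognitive/Expected",
            "Event/Category/Experimental stimulus",
            "Attribute/Onset",
            "Action/Button press",
        ]
        queries = [
            "Participant",
            "Participant/Effect",
            "Participant/Effect/Cognitive",
            "Sensory Presentation/Auditory",
            "sensory presentation/auditory/ding",
            "Attribute",
            "Item",
        ]
        total = 0
        for _ in range(80):
            events = []
            for k in range(rng.randint(5, 30)):
                tags = rng.sample(pool, rng.randint(1, 4))
                if rng.random() < 0.3:  # wrap some tags in a group
                    text = f"({', '.join(tags[:2])})" + (
                        ", " + ", ".join(tags[2:]) if tags[2:] else ""
                    )
                else:
                    text = ", ".join(tags)
                events.append(EventInstance(f"c{k}", float(k), parse_hed_string(text)))
            total += len(events)
            q = parse_hed_tag(rng.choice(queries))
            expected = _brute_force_search(events, q)
            got = search_event_instances(events, q)
            assert got == expected
            assert all(e in events for e in got)  # subset, order preserved
        assert total >= 1000
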