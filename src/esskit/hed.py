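"""Hierarchical Event Descriptor (HED) vocabulary and tag strings.

HED annotates experimental events with slash-delimited paths into a
tree-structured vocabulary, e.g. ``Sensory Presentation/Auditory/Buzz``.
Because the vocabulary is hierarchical, an annotation can be as coarse or
as fine as the experimenter chooses, and events can later be selected by
any ancestor tag without consulting an external code table.

This module ships a trimmed vocabulary snapshot as package data and
implements parsing, validation against the hierarchy, prefix matching and
event searching.  Tag comparison is case-insensitive throughout; the
canonical spelling is the one in the hierarchy.  The tilde (role) syntax
of full HED 2.0 is not supported and is rejected at parse time.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Union

from .errors import HedParseError, VocabularyError

__all__ = [
    "HedNode",
    "HedHierarchy",
    "HedTag",
    "HedString",
    "EventCodeMapping",
    "parse_hed_string",
    "parse_hed_tag",
    "validate_hed_string",
    "tag_matches",
    "search_event_instances",
    "load_hierarchy",
]

#: Maximum length of an event label/code in a code mapping.
MAX_EVENT_LABEL_LENGTH = 20


# ---------------------------------------------------------------------------
# Vocabulary tree


@dataclass
class HedNode:
    """One node of the vocabulary tree.

    ``extension_allowed`` permits tags to descend below this node with
    terms not present in the vocabulary; ``takes_value`` permits exactly
    one free-form value component directly beneath it.
    """

    name: str
    children: list["HedNode"] = field(default_factory=list)
    extension_allowed: bool = False
    takes_value: bool = False

    def child(self, name: str) -> "HedNode | None":
        low = name.casefold()
        for c in self.children:
            if c.name.casefold() == low:
                return c
        return None


@dataclass
class HedHierarchy:
    """The full vocabulary: a forest of :class:`HedNode` roots."""

    version: str = "2.0"
    roots: list[HedNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.check()

    def check(self) -> None:
        """Verify tree-ness and case-insensitive sibling uniqueness."""
        seen_ids: set[int] = set()

        def walk(node: HedNode, path: str) -> None:
            if id(node) in seen_ids:
                raise VocabularyError(f"cyclic reference at '{path}'")
            seen_ids.add(id(node))
            names: set[str] = set()
            for c in node.children:
                low = c.name.casefold()
                if low in names:
                    raise VocabularyError(
                        f"duplicate sibling name '{c.name}' under '{path}'"
                    )
                names.add(low)
                walk(c, f"{path}/{c.name}")

        root_names: set[str] = set()
        for r in self.roots:
            low = r.name.casefold()
            if low in root_names:
                raise VocabularyError(f"duplicate root name '{r.name}'")
            root_names.add(low)
            walk(r, r.name)

    def find(self, path: Iterable[str]) -> HedNode | None:
        """Return the node at *path* (case-insensitive), or None."""
        parts = list(path)
        if not parts:
            return None
        node = None
        low = parts[0].casefold()
        for r in self.roots:
            if r.name.casefold() == low:
                node = r
                break
        if node is None:
            return None
        for part in parts[1:]:
            node = node.child(part)
            if node is None:
                return None
        return node

    def contains(self, tag: "HedTag") -> bool:
        return self.find(tag.path) is not None


def _parse_vocabulary_text(text: str, version: str = "2.0") -> HedHierarchy:
    roots: list[HedNode] = []
    stack: list[HedNode] = []  # stack[d] = last node at depth d
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        depth = len(raw) - len(raw.lstrip("\t"))
        body = raw.strip()
        ext = "[extensionAllowed]" in body
        val = "[takesValue]" in body
        name = body.replace("[extensionAllowed]", "").replace("[takesValue]", "").strip()
        if not name:
            raise VocabularyError(f"line {lineno}: empty node name")
        if "/" in name:
            raise VocabularyError(f"line {lineno}: node name '{name}' contains '/'")
        if depth > len(stack):
            raise VocabularyError(
                f"line {lineno}: indentation jumps from depth {len(stack)} to {depth}"
            )
        node = HedNode(name=name, extension_allowed=ext, takes_value=val)
        del stack[depth:]
        if depth == 0:
            roots.append(node)
        else:
            stack[depth - 1].children.append(node)
        stack.append(node)
    return HedHierarchy(version=version, roots=roots)


def load_hierarchy(source: str | None = None) -> HedHierarchy:
    """Load a vocabulary document; default is the shipped snapshot.

    The format is one node per line, depth given by leading tabs, with
    optional ``[extensionAllowed]`` / ``[takesValue]`` flags.
    """
    if source is None:
        text = (
            importlib.resources.files("esskit")
            .joinpath("data/hed_vocabulary.txt")
            .read_text(encoding="utf-8")
        )
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    return _parse_vocabulary_text(text)


_DEFAULT_HIERARCHY: HedHierarchy | None = None


def default_hierarchy() -> HedHierarchy:
    """The shipped snapshot, loaded once per process."""
    global _DEFAULT_HIERARCHY
    if _DEFAULT_HIERARCHY is None:
        _DEFAULT_HIERARCHY = load_hierarchy()
    return _DEFAULT_HIERARCHY


# ---------------------------------------------------------------------------
# Tags and tag strings


@dataclass(frozen=True)
class HedTag:
    """A single slash-delimited path into the vocabulary."""

    path: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.path or any(not p for p in self.path):
            raise HedParseError(f"empty component in tag {self.path!r}")

    def __str__(self) -> str:
        return "/".join(self.path)


def parse_hed_tag(text: str) -> HedTag:
    parts = tuple(p.strip() for p in text.strip().split("/"))
    if not parts or any(not p for p in parts):
        raise HedParseError(f"tag '{text.strip()}' has an empty path component")
    return HedTag(parts)


@dataclass
class HedString:
    """A comma-separated sequence of tags and parenthesised groups.

    Groups are nested :class:`HedString` values rendered in parentheses.
    Searching treats groups transparently: a tag inside a group is found
    by the same queries as a top-level tag.
    """

    items: list[Union[HedTag, "HedString"]] = field(default_factory=list)

    def __str__(self) -> str:
        parts = []
        for item in self.items:
            if isinstance(item, HedString):
                parts.append(f"({item})")
            else:
                parts.append(str(item))
        return ", ".join(parts)

    def iter_tags(self) -> Iterator[HedTag]:
        """All tags at any group depth, in document order."""
        for item in self.items:
            if isinstance(item, HedString):
                yield from item.iter_tags()
            else:
                yield item


def parse_hed_string(text: str) -> HedString:
    """Parse a HED tag string.

    Commas at depth 0 separate items; balanced parentheses open groups;
    whitespace around delimiters is ignored.  Unbalanced parentheses,
    empty items and the unsupported tilde syntax raise
    :class:`HedParseError` with a position.
    """
    if not text or not text.strip():
        raise HedParseError("empty HED string")
    pos = 0
    n = len(text)

    def parse_seq(depth: int) -> HedString:
        nonlocal pos
        items: list[HedTag | HedString] = []
        buf_start = pos
        buf: list[str] = []
        # After an item a comma is needed before the next one; a flush is
        # "required" (must yield a token) right after a separating comma.
        item_open = True  # an item (tag or group) is expected here

        def flush() -> None:
            nonlocal item_open
            token = "".join(buf).strip()
            buf.clear()
            if token:
                if "~" in token:
                    raise HedParseError(
                        "tilde (role) syntax is not supported", buf_start
                    )
                items.append(parse_hed_tag(token))
                item_open = False
            elif item_open:
                raise HedParseError("empty item", buf_start)

        while pos < n:
            ch = text[pos]
            if ch == "(":
                if "".join(buf).strip():
                    raise HedParseError("text abuts '('", pos)
                if not item_open:
                    raise HedParseError("group follows ')' without ','", pos)
                pos += 1
                items.append(parse_seq(depth + 1))
                item_open = False
                buf_start = pos
                buf.clear()
            elif ch == ")":
                if depth == 0:
                    raise HedParseError("unbalanced ')'", pos)
                flush()
                pos += 1
                return HedString(items)
            elif ch == ",":
                flush()
                item_open = True
                pos += 1
                buf_start = pos
            else:
                if not item_open and not ch.isspace():
                    raise HedParseError("text follows ')'", pos)
                buf.append(ch)
                pos += 1
        if depth > 0:
            raise HedParseError("unbalanced '('", pos)
        flush()
        return HedString(items)

    result = parse_seq(0)
    if not result.items:
        raise HedParseError("empty HED string")
    return result


# ---------------------------------------------------------------------------
# Validation, matching, search


@dataclass(frozen=True)
class HedIssue:
    """One problem found while validating a HED string against a hierarchy."""

    kind: str  # "unknown-node" | "value-depth"
    tag: str
    message: str


def validate_hed_string(s: HedString, h: HedHierarchy | None = None) -> list[HedIssue]:
    """Check every tag of *s* (at any group depth) against hierarchy *h*.

    A tag is acceptable when its full path exists in the hierarchy, when it
    deviates only below a node flagged ``extensionAllowed``, or when it
    supplies exactly one value component below a ``takesValue`` node.
    Returns a (possibly empty) list of issues; never raises.
    """
    if h is None:
        h = default_hierarchy()
    issues: list[HedIssue] = []
    for tag in s.iter_tags():
        node: HedNode | None = None
        matched = 0
        for i, part in enumerate(tag.path):
            nxt = (
                node.child(part)
                if node is not None
                else h.find(tag.path[: 1])  # root lookup
            )
            if i == 0 and nxt is None:
                break
            if i > 0 and nxt is None:
                break
            node = nxt
            matched = i + 1
        remaining = len(tag.path) - matched
        if remaining == 0:
            continue
        if node is not None and node.extension_allowed:
            continue  # any depth of extension below an extensionAllowed node
        if node is not None and node.takes_value and remaining == 1:
            continue  # a single value component below a takesValue node
        if node is not None and node.takes_value and remaining > 1:
            issues.append(
                HedIssue(
                    "value-depth",
                    str(tag),
                    f"tag '{tag}' supplies {remaining} components below the "
                    f"value node '{node.name}'; only one is allowed",
                )
            )
            continue
        prefix = "/".join(tag.path[:matched]) or "(root)"
        issues.append(
            HedIssue(
                "unknown-node",
                str(tag),
                f"tag '{tag}' leaves the vocabulary after '{prefix}' and "
                "the last matched node does not allow extension",
            )
        )
    return issues


def tag_matches(tag: HedTag, query: HedTag) -> bool:
    """True iff *query*'s path is a case-insensitive prefix of *tag*'s."""
    if len(query.path) > len(tag.path):
        return False
    return all(
        q.casefold() == t.casefold() for q, t in zip(query.path, tag.path)
    )


def search_event_instances(events: list, query: HedTag) -> list:
    """Events (input order) whose HED string contains a tag matching *query*.

    Group nesting is transparent; an event matches if any of its tags, at
    any depth, has *query* as a path prefix.
    """
    out = []
    for ev in events:
        hs = ev.hed_string
        if hs is None or isinstance(hs, str):
            continue
        if any(tag_matches(t, query) for t in hs.iter_tags()):
            out.append(ev)
    return out


# ---------------------------------------------------------------------------
# Event-code mapping


@dataclass
class EventCodeMapping:
    """Maps one experiment event code (label) of a task to its HED annotation.

    Every code must carry a category tag (e.g.
    ``Event/Category/Experimental stimulus``) and may carry an arbitrary
    HED string.  The code is the experiment-specific label, at most
    20 characters; the length constraint is enforced by the validator so
    that a draft manifest with an over-long label can still be loaded and
    reported on.
    """

    task_label: str
    code: str
    category: HedTag | None
    hed_string: HedString | str | None = None
    description: str = ""

    def full_hed_string(self) -> HedString:
        """Category tag plus annotation tags, as written to event files."""
        items: list[HedTag | HedString] = []
        if self.category is not None:
            items.append(self.category)
        if isinstance(self.hed_string, HedString):
            items.extend(self.hed_string.items)
        return HedString(items)
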