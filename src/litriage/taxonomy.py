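"""Category taxonomy for hierarchical abstract triage.

The triage pipeline routes each curatable abstract through a tree of
disease categories: Level 1 is the broad disease area (seven categories
by default), Level 2 a sub-disease, and Level 3 an antigen or topic.
Some branches skip levels — by default Transplantation and Cancer have
no Level 2, and HIV stops at Level 1 entirely.

Every Level-1 category carries a curation priority flag (``high`` or
``low``); misrouting a high-priority abstract into a low-priority
category is the costly error the cost-sensitive combiner is built to
avoid.  Level-2/3 nodes may be flagged ``catch_all`` (an "Other" or
"Various" bucket), which the catch-all cost matrix penalises predicting
into.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

__all__ = [
    "TaxonomyError",
    "TaxonomyNode",
    "Taxonomy",
    "PriorityPartition",
    "load_taxonomy",
    "default_taxonomy",
]

NA = "NA"


class TaxonomyError(ValueError):
    """Raised when a taxonomy config or a label path is invalid."""


@dataclass(frozen=True)
class TaxonomyNode:
    name: str
    level: int  # 1, 2 or 3
    parent: str | None  # None for Level-1 nodes
    priority: str | None = None  # "high"/"low", Level-1 only
    catch_all: bool = False
    skip_levels: frozenset[int] = frozenset()


@dataclass
class PriorityPartition:
    """Disjoint split of the Level-1 categories into high and low priority."""

    high: tuple[str, ...]
    low: tuple[str, ...]

    def priority_of(self, category: str) -> str:
        if category in self.high:
            return "high"
        if category in self.low:
            return "low"
        raise KeyError(f"category {category!r} not in partition")


@dataclass
class Taxonomy:
    """Validated category tree with level-skip rules.

    ``nodes`` maps name -> TaxonomyNode.  Sibling names must be unique;
    node names are additionally required to be globally unique so that a
    label table can name a category without spelling out its full path.
    """

    nodes: dict[str, TaxonomyNode] = field(default_factory=dict)

    # -- structure queries -------------------------------------------------
    def level1(self) -> list[str]:
        return [n.name for n in self.nodes.values() if n.level == 1]

    def children(self, name: str | None) -> list[str]:
        if name is None:
            return self.level1()
        return [n.name for n in self.nodes.values() if n.parent == name]

    def node(self, name: str) -> TaxonomyNode:
        try:
            return self.nodes[name]
        except KeyError:
            raise TaxonomyError(f"unknown taxonomy node {name!r}") from None

    def branch_root(self, name: str) -> str:
        """Level-1 ancestor of a node."""
        node = self.node(name)
        while node.parent is not None:
            node = self.node(node.parent)
        return node.name

    def skips_level(self, level1_name: str, level: int) -> bool:
        return level in self.node(level1_name).skip_levels

    def priority_partition(self) -> PriorityPartition:
        high = tuple(n for n in self.level1() if self.nodes[n].priority == "high")
        low = tuple(n for n in self.level1() if self.nodes[n].priority == "low")
        return PriorityPartition(high=high, low=low)

    def catch_all_flags(self, parent: str) -> dict[str, bool]:
        return {c: self.nodes[c].catch_all for c in self.children(parent)}

    # -- label-path validation --------------------------------------------
    def validate_path(self, level1: str, level2: str, level3: str) -> None:
        """Check that (level1, level2, level3) is a valid root-to-node path.

        ``NA`` marks an absent level.  A branch that skips a level must
        carry ``NA`` there; otherwise an ``NA`` at level k forces ``NA``
        at every deeper level.
        """
        if level1 == NA:
            if (level2, level3) != (NA, NA):
                raise TaxonomyError("levels 2-3 must be NA when level 1 is NA")
            return
        if level1 not in self.nodes or self.nodes[level1].level != 1:
            raise TaxonomyError(f"{level1!r} is not a Level-1 category")
        skip2 = self.skips_level(level1, 2)
        skip3 = self.skips_level(level1, 3)
        if skip2 and level2 != NA:
            raise TaxonomyError(f"branch {level1!r} skips Level 2 but got {level2!r}")
        if skip3 and level3 != NA:
            raise TaxonomyError(f"branch {level1!r} skips Level 3 but got {level3!r}")
        # the parent a Level-3 name must hang off: level2 normally, the
        # Level-1 node when the branch skips Level 2
        parent3 = level2 if not skip2 else level1
        if level2 != NA:
            node = self.node(level2) if level2 in self.nodes else None
            if node is None or node.parent != level1:
                raise TaxonomyError(
                    f"{level2!r} is not a Level-2 child of {level1!r}"
                )
        if level3 != NA:
            if level2 == NA and not skip2:
                raise TaxonomyError(
                    f"Level 3 {level3!r} given but Level 2 is NA in branch {level1!r}"
                )
            node = self.node(level3) if level3 in self.nodes else None
            if node is None or node.parent != parent3:
                raise TaxonomyError(
                    f"{level3!r} is not a child of {parent3!r}"
                )

    # -- traversal ---------------------------------------------------------
    def sibling_sets(self) -> list[tuple[str | None, list[str]]]:
        """All (parent, children) pairs with at least one child.

        The root sibling set (parent ``None``) is the Level-1 categories.
        """
        sets: list[tuple[str | None, list[str]]] = [(None, self.level1())]
        for name in self.nodes:
            kids = self.children(name)
            if kids:
                sets.append((name, kids))
        return sets

    def leaves(self) -> list[str]:
        return [n for n in self.nodes if not self.children(n)]

    def path_to(self, name: str) -> list[str]:
        """Root-to-node list of names."""
        path = [name]
        node = self.node(name)
        while node.parent is not None:
            path.append(node.parent)
            node = self.node(node.parent)
        return path[::-1]

    def to_dict(self) -> dict:
        """Config mapping that :func:`load_taxonomy` round-trips."""

        def spec_for(name: str) -> dict:
            node = self.nodes[name]
            out: dict = {"name": name}
            if node.level == 1:
                out["priority"] = node.priority
                if node.skip_levels:
                    out["skip_levels"] = sorted(node.skip_levels)
            if node.catch_all:
                out["catch_all"] = True
            kids = self.children(name)
            if kids:
                out["children"] = [spec_for(k) for k in kids]
            return out

        return {"level1": [spec_for(n) for n in self.level1()]}

    def path_levels(self, leaf: str) -> tuple[str, str, str]:
        """(level1, level2, level3) label triple for a node, NA-padded."""
        path = self.path_to(leaf)
        l1 = path[0]
        out = {1: l1, 2: NA, 3: NA}
        for name in path[1:]:
            out[self.node(name).level] = name
        return out[1], out[2], out[3]


def _add_subtree(tax: Taxonomy, spec: dict, parent: TaxonomyNode | None) -> None:
    name = spec.get("name")
    if not name:
        raise TaxonomyError(f"node without a name under parent {parent!r}")
    if name in tax.nodes:
        raise TaxonomyError(f"duplicate node name {name!r}")
    if parent is None:
        priority = spec.get("priority")
        if priority not in ("high", "low"):
            raise TaxonomyError(f"Level-1 node {name!r} missing priority flag")
        skips = frozenset(int(x) for x in spec.get("skip_levels", []))
        if not skips <= {2, 3}:
            raise TaxonomyError(f"node {name!r}: skip_levels must be within {{2,3}}")
        node = TaxonomyNode(name, 1, None, priority, bool(spec.get("catch_all", False)), skips)
    else:
        root_skips = tax.node(tax.branch_root(parent.name)).skip_levels if parent.parent else parent.skip_levels
        level = parent.level + 1
        # children of a branch that skips Level 2 sit at Level 3
        while level in root_skips:
            level += 1
        if level > 3:
            raise TaxonomyError(f"node {name!r} would sit below Level 3")
        node = TaxonomyNode(name, level, parent.name, None, bool(spec.get("catch_all", False)))
    tax.nodes[name] = node
    children = spec.get("children", []) or []
    seen = set()
    for child in children:
        cname = child.get("name")
        if cname in seen:
            raise TaxonomyError(f"duplicate sibling name {cname!r} under {name!r}")
        seen.add(cname)
        _add_subtree(tax, child, node)


def load_taxonomy(source) -> Taxonomy:
    """Load and validate a taxonomy from a YAML/JSON mapping or file path.

    The config is a mapping with a ``level1`` list of node specs; each
    node spec has ``name`` and optionally ``priority`` (required at
    Level 1), ``catch_all``, ``skip_levels`` and ``children``.
    """
    if isinstance(source, dict):
        cfg = source
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    if not cfg or not cfg.get("level1"):
        raise TaxonomyError("empty taxonomy config: no Level-1 categories")
    tax = Taxonomy()
    seen = set()
    for spec in cfg["level1"]:
        name = spec.get("name")
        if name in seen:
            raise TaxonomyError(f"duplicate Level-1 name {name!r}")
        seen.add(name)
        _add_subtree(tax, spec, None)
    return tax


def default_taxonomy() -> Taxonomy:
    """The bundled default tree (published nodes only)."""
    ref = importlib.resources.files("litriage.data") / "default_taxonomy.yaml"
    return load_taxonomy(yaml.safe_load(ref.read_text()))
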