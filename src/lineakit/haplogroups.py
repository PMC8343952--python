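"""mtDNA haplogroup assignment from diagnostic variants, and frequency profiles.

A haplogroup tree is a rooted tree of named clades, each node carrying the
diagnostic variants acquired on the branch into it.  The expected variant set
of a node, E(node), is the union of diagnostics along the root-to-node path.
A profile is assigned by scoring every node:

    matched = |E(node) ∩ observed|
    missing = expected diagnostics whose position lies inside the profile's
              coverage but which were not observed
    score   = w_match * matched - w_miss * missing      (unit weights default)

Diagnostics outside the profile's coverage contribute to neither term.  Ties
are broken toward the deeper (more derived) node, then lexicographically —
matching the forensic practice of reporting the finest defensible subclade.
Observed variants not expected anywhere on the best path are reported as
private but never enter the score.

The shipped table (``data/synthetic_haplogroups.tsv``) is a small synthetic
stand-in, not a Phylotree import; loading a full Phylotree-style TSV through
:meth:`HaplogroupTree.from_tsv` is the supported extension point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .matching import HaplotypeDB
from .profiles import MtProfile, Variant, parse_variant


class HaplogroupError(ValueError):
    """Configuration error in a haplogroup tree or frequency request."""


@dataclass(frozen=True)
class HaplogroupNode:
    name: str
    parent: str | None
    diagnostics: frozenset[Variant]


class HaplogroupTree:
    """Rooted tree of named haplogroups with per-branch diagnostic variants."""

    def __init__(self, nodes: Iterable[HaplogroupNode]):
        self.nodes: dict[str, HaplogroupNode] = {}
        for node in nodes:
            if node.name in self.nodes:
                raise HaplogroupError(f"duplicate haplogroup {node.name!r}")
            self.nodes[node.name] = node
        if not self.nodes:
            raise HaplogroupError("empty haplogroup tree")
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise HaplogroupError(f"need exactly one root, found {len(roots)}")
        self.root = roots[0].name
        self.children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise HaplogroupError(
                        f"{node.name!r} references unknown parent {node.parent!r}"
                    )
                self.children[node.parent].append(node.name)
        self._expected: dict[str, frozenset[Variant]] = {}
        self._depth: dict[str, int] = {}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        seen: set[str] = set()
        stack = [self.root]
        while stack:
            name = stack.pop()
            if name in seen:
                raise HaplogroupError(f"cycle at {name!r}")
            seen.add(name)
            stack.extend(self.children[name])
        if seen != set(self.nodes):
            orphans = set(self.nodes) - seen
            raise HaplogroupError(f"nodes unreachable from root: {sorted(orphans)}")

    def depth(self, name: str) -> int:
        if name not in self._depth:
            node = self.nodes[name]
            self._depth[name] = 0 if node.parent is None else self.depth(node.parent) + 1
        return self._depth[name]

    def expected(self, name: str) -> frozenset[Variant]:
        """E(name): union of diagnostics along the root-to-node path."""
        if name not in self._expected:
            node = self.nodes[name]
            base = frozenset() if node.parent is None else self.expected(node.parent)
            self._expected[name] = base | node.diagnostics
        return self._expected[name]

    def is_descendant(self, name: str, ancestor: str) -> bool:
        """True iff ``name`` equals or descends from ``ancestor``."""
        cur: str | None = name
        while cur is not None:
            if cur == ancestor:
                return True
            cur = self.nodes[cur].parent
        return False

    def diagnostic_positions(self) -> frozenset[int]:
        return frozenset(
            v.position for node in self.nodes.values() for v in node.diagnostics
        )

    @classmethod
    def from_tsv(cls, path) -> "HaplogroupTree":
        """Load a TSV of (name, parent, space-separated diagnostic tokens)."""
        nodes = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0].strip() == "name":
                    continue
                name = parts[0].strip()
                parent = parts[1].strip() if len(parts) > 1 and parts[1].strip() else None
                tokens = parts[2].split() if len(parts) > 2 else []
                nodes.append(
                    HaplogroupNode(
                        name, parent, frozenset(parse_variant(t) for t in tokens)
                    )
                )
        return cls(nodes)

    @classmethod
    def default(cls) -> "HaplogroupTree":
        """The shipped synthetic stand-in table (see module docstring)."""
        ref = resources.files("lineakit.data").joinpath("synthetic_haplogroups.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass(frozen=True)
class HaplogroupAssignment:
    best: str
    score: float
    matched: int
    missing: int
    private: int
    runners_up: tuple[tuple[str, float], ...]


def assign_haplogroup(
    profile: MtProfile,
    tree: HaplogroupTree,
    weights: tuple[float, float] = (1.0, 1.0),
) -> HaplogroupAssignment:
    """Score every haplogroup for a profile and return the best assignment."""
    if profile.is_empty:
        raise HaplogroupError(f"profile {profile.sample_id} has empty coverage")
    w_match, w_miss = weights
    observed = profile.informative_variants(profile.coverage)
    scored: list[tuple[float, int, str, int, int]] = []
    for name in tree.nodes:
        expected = tree.expected(name)
        in_cov = frozenset(
            v for v in expected if any(v.position in r for r in profile.coverage)
        )
        matched = len(in_cov & observed)
        missing = len(in_cov) - matched
        score = w_match * matched - w_miss * missing
        scored.append((score, tree.depth(name), name, matched, missing))
    # best = max score; ties to greater depth, then lexicographically smaller name
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    score, _, best, matched, missing = scored[0]
    private = len(observed - tree.expected(best))
    return HaplogroupAssignment(
        best=best,
        score=score,
        matched=matched,
        missing=missing,
        private=private,
        runners_up=tuple((name, s) for s, _, name, _, _ in scored[1:]),
    )


def haplogroup_frequency_profile(
    db: HaplotypeDB,
    tree: HaplogroupTree,
    groups: Sequence[str],
) -> dict[str, float]:
    """Relative frequency of each requested haplogroup (or its descendants).

    Every record is assigned, then counted toward the most specific (deepest)
    requested group it equals or descends from; remaining mass is reported
    under ``"other"``.  Frequencies sum to 1 over ``groups + ["other"]``.
    """
    if not groups:
        raise HaplogroupError("groups must be non-empty")
    for g in groups:
        if g not in tree.nodes:
            raise HaplogroupError(f"unknown haplogroup {g!r}")
    counts = {g: 0 for g in groups}
    other = 0
    by_depth = sorted(groups, key=lambda g: (-tree.depth(g), g))
    for rec in db.records:
        best = assign_haplogroup(rec, tree).best
        for g in by_depth:
            if tree.is_descendant(best, g):
                counts[g] += 1
                break
        else:
            other += 1
    n = db.n
    if n == 0:
        raise HaplogroupError(f"database {db.population!r} is empty")
    freqs = {g: counts[g] / n for g in groups}
    freqs["other"] = other / n
    return freqs


def frequency_profile_table(
    dbs: Sequence[HaplotypeDB],
    tree: HaplogroupTree,
    groups: Sequence[str],
) -> pd.DataFrame:
    """Population x haplogroup relative-frequency matrix (plus 'other')."""
    rows = {}
    for db in dbs:
        rows[db.population] = haplogroup_frequency_profile(db, tree, groups)
    return pd.DataFrame.from_dict(rows, orient="index")
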