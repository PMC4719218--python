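"""Haplogroup tree representation, classification and clade indicators.

A haplogroup tree is a rooted tree of named clades; each branch carries
the set of defining variants acquired on that branch. The variant set
expected for a clade is the union of defining variants along the
root-to-clade path, with later branches overriding earlier alleles at
the same position (back-mutation semantics).

Classification scores each clade against an individual's observed
variant set with a symmetric recall/precision measure (a
Kulczynski-type score)::

    score = (|E ∩ O| / |E| + |E ∩ O| / |O|) / 2

where ``E`` is the clade's cumulative variant set and ``O`` the
observed set. The score is 1 when both sets are empty (the individual
matches the reference/root exactly) and 0 when exactly one is empty.
It is monotone in overlap and penalises both missing and extra
variants, which makes assignments reproducible without an external
classifier database. HSD export (``pileup.write_hsd``) is provided for
interoperability with external tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError, InputContractError
from .genome import format_variant_token, parse_variant_token


@dataclass(frozen=True)
class HaplogroupNode:
    name: str
    parent: str | None
    variants: frozenset[tuple[int, str]]


@dataclass
class HaplogroupTree:
    """Rooted tree of named haplogroups with branch-defining variants."""

    nodes: dict[str, HaplogroupNode]
    root: str
    #: node-name prefixes that collapse to their own major clade label
    #: (e.g. {"HV": "HV"} keeps HV* distinct from H*).
    major_overrides: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.root not in self.nodes:
            raise InputContractError(f"root {self.root!r} not among nodes")
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1 or roots[0].name != self.root:
            raise InputContractError("tree must have exactly one parentless root node")
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise InputContractError(
                    f"node {node.name!r} has unknown parent {node.parent!r}"
                )
        # reachability + acyclicity via path walks
        for name in self.nodes:
            self.path_from_root(name)

    def path_from_root(self, name: str) -> list[str]:
        """Node names from the root down to ``name`` (inclusive)."""
        if name not in self.nodes:
            raise InputContractError(f"unknown haplogroup node {name!r}")
        path: list[str] = []
        seen: set[str] = set()
        cur: str | None = name
        while cur is not None:
            if cur in seen:
                raise InputContractError(f"cycle detected at node {cur!r}")
            seen.add(cur)
            path.append(cur)
            cur = self.nodes[cur].parent
        path.reverse()
        if path[0] != self.root:
            raise InputContractError(f"node {name!r} not reachable from root")
        return path

    def depth(self, name: str) -> int:
        return len(self.path_from_root(name)) - 1

    def children(self, name: str) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if n.parent == name)

    def leaves(self) -> list[str]:
        have_child = {n.parent for n in self.nodes.values() if n.parent is not None}
        return sorted(n for n in self.nodes if n not in have_child)

    def major_clade(self, name: str) -> str:
        """Collapse a node name to its major clade label.

        Longest matching override prefix wins; otherwise the leading run
        of alphabetic characters (so ``H2a1`` collapses to ``H`` while a
        multi-letter clade name such as ``HV`` stays distinct from
        ``H``). Overrides allow arbitrary re-mapping when node naming
        does not follow that convention.
        """
        if name not in self.nodes:
            raise InputContractError(f"unknown haplogroup node {name!r}")
        for prefix in sorted(self.major_overrides, key=len, reverse=True):
            if name.startswith(prefix):
                return self.major_overrides[prefix]
        alpha = ""
        for ch in name:
            if ch.isalpha():
                alpha += ch
            else:
                break
        return alpha or name


@dataclass(frozen=True)
class HaplogroupAssignment:
    individual_id: str
    haplogroup: str
    score: float
    major_clade: str


def cumulative_variants(tree: HaplogroupTree, node: str) -> frozenset[tuple[int, str]]:
    """Expected variant set of a clade: path union with positional override."""
    alleles: dict[int, str] = {}
    for name in tree.path_from_root(node):
        for pos, allele in tree.nodes[name].variants:
            alleles[pos] = allele
    return frozenset(alleles.items())


def score_node(variants, tree: HaplogroupTree, node: str) -> float:
    """Symmetric recall/precision concordance of an observed variant set."""
    observed = frozenset(getattr(variants, "variants", variants))
    expected = cumulative_variants(tree, node)
    if not expected and not observed:
        return 1.0
    if not expected or not observed:
        return 0.0
    inter = len(expected & observed)
    return (inter / len(expected) + inter / len(observed)) / 2.0


def classify(variants, tree: HaplogroupTree) -> HaplogroupAssignment:
    """Assign a variant set to the best-scoring clade.

    Ties on score are broken toward the deeper (more refined) clade,
    then by lexicographic node name.
    """
    observed = frozenset(getattr(variants, "variants", variants))
    individual_id = getattr(variants, "individual_id", "")
    best: tuple[float, int, str] | None = None
    best_name = tree.root
    for name in tree.nodes:
        s = score_node(observed, tree, name)
        key = (s, tree.depth(name))
        if (
            best is None
            or key[0] > best[0]
            or (key[0] == best[0] and key[1] > best[1])
            or (key[0] == best[0] and key[1] == best[1] and name < best_name)
        ):
            best = (key[0], key[1], name)
            best_name = name
    assert best is not None
    return HaplogroupAssignment(
        individual_id=individual_id,
        haplogroup=best_name,
        score=best[0],
        major_clade=tree.major_clade(best_name),
    )


def haplogroup_covariates(assignments, min_freq: float = 0.05) -> pd.DataFrame:
    """Binary clade-membership indicators for clades above a cohort frequency.

    Returns an individuals × major-clade 0/1 table containing one column
    per clade whose cohort frequency is at least ``min_freq``. Clades are
    mutually exclusive, so every row sums to at most 1.
    """
    if not assignments:
        raise InputContractError("no assignments given")
    ids = [a.individual_id for a in assignments]
    clades = pd.Series([a.major_clade for a in assignments], index=ids)
    freqs = clades.value_counts(normalize=True)
    kept = sorted(freqs.index[freqs >= min_freq])
    table = pd.DataFrame(
        {clade: (clades == clade).astype(int) for clade in kept}, index=ids
    )
    table.index.name = "individual_id"
    return table


def write_tree_json(tree: HaplogroupTree, path) -> None:
    payload = {
        "root": tree.root,
        "major_overrides": tree.major_overrides,
        "nodes": [
            {
                "name": n.name,
                "parent": n.parent,
                "variants": [
                    format_variant_token(p, a) for p, a in sorted(n.variants)
                ],
            }
            for n in tree.nodes.values()
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_tree_json(path) -> HaplogroupTree:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        nodes = {
            n["name"]: HaplogroupNode(
                name=n["name"],
                parent=n["parent"],
                variants=frozenset(parse_variant_token(t) for t in n["variants"]),
            )
            for n in payload["nodes"]
        }
        return HaplogroupTree(
            nodes=nodes,
            root=payload["root"],
            major_overrides=dict(payload.get("major_overrides", {})),
        )
    except KeyError as exc:
        raise ConfigurationError(f"tree file {path} missing field {exc}") from exc
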