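"""Rooted trees, species-tree branch indexing, and gene families.

Every downstream computation (likelihood, reconciliation sampling,
simulation) addresses the species tree through integer *branch ids*.  Each
node owns exactly one branch -- the edge above it -- including the root,
whose branch is the "root stem".  A rooted binary tree with n leaves
therefore has N = 2n - 1 branches, and originations and transfer recipients
range uniformly over all N of them.

Branch ids are a pure function of topology and leaf names: leaves take ids
0..n-1 in alphabetical order of their name, internal nodes take ids n..N-1
in post-order (children visited in order of their smallest descendant leaf
name), so the root stem always has the largest id N-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Node",
    "NewickError",
    "TreeValidationError",
    "parse_newick",
    "write_newick",
    "SpeciesTree",
    "index_species_tree",
    "GeneFamily",
    "map_genes",
    "MappingError",
    "prune_tree",
    "prune_family",
    "prune_species_tree",
    "read_tree_file",
    "read_tree_sample",
    "read_mapping_file",
]


class NewickError(ValueError):
    """Malformed newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class TreeValidationError(ValueError):
    pass


class Node:
    """A node of a rooted tree; owns the branch above itself."""

    __slots__ = ("name", "children", "parent", "length")

    def __init__(self, name: str = "", length: float | None = None):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        stack = [self]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def postorder(self) -> list["Node"]:
        out: list[Node] = []
        stack: list[tuple[Node, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                out.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        return out

    def copy(self) -> "Node":
        new = Node(self.name, self.length)
        for child in self.children:
            new.add(child.copy())
        return new

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({write_newick(self)})"


_TOKEN_STOP = set("(),;:")


def parse_newick(text: str, expect_rooted: bool = False) -> Node:
    """Parse a single newick string into a :class:`Node` tree.

    Leaf names are preserved verbatim (quoted labels supported).  With
    ``expect_rooted`` the top-level node must have exactly two children;
    otherwise a trifurcating (or higher-arity) top level is accepted, which
    is how unrooted topologies are conventionally written.
    """
    s = text.strip()
    if not s:
        raise NewickError("empty newick string", 0)
    pos = 0
    n = len(s)

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_label() -> str:
        nonlocal pos
        if pos < n and s[pos] in "'\"":
            quote = s[pos]
            pos += 1
            start = pos
            while pos < n and s[pos] != quote:
                pos += 1
            if pos >= n:
                raise error("unterminated quoted label")
            label = s[start:pos]
            pos += 1
            return label
        start = pos
        while pos < n and s[pos] not in _TOKEN_STOP and not s[pos].isspace():
            pos += 1
        return s[start:pos]

    def parse_length() -> float | None:
        nonlocal pos
        if pos < n and s[pos] == ":":
            pos += 1
            start = pos
            while pos < n and (s[pos] in "+-eE." or s[pos].isdigit()):
                pos += 1
            try:
                return float(s[start:pos])
            except ValueError:
                raise error("invalid branch length") from None
        return None

    def parse_subtree() -> Node:
        nonlocal pos
        node = Node()
        if pos < n and s[pos] == "(":
            pos += 1
            while True:
                node.add(parse_subtree())
                if pos >= n:
                    raise error("unexpected end of string inside clade")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {s[pos]!r}")
            node.name = parse_label()
        else:
            node.name = parse_label()
            if not node.name:
                raise error("expected a leaf label")
        node.length = parse_length()
        return node

    root = parse_subtree()
    if pos >= n or s[pos] != ";":
        raise NewickError("expected ';' terminating the tree", pos)
    if pos != n - 1:
        raise NewickError("trailing characters after ';'", pos + 1)

    names = root.leaf_names()
    dupes = {x for x in names if names.count(x) > 1}
    if dupes:
        raise TreeValidationError(f"duplicate leaf names: {sorted(dupes)}")
    if any(not x for x in names):
        raise TreeValidationError("empty leaf name")
    if expect_rooted and len(root.children) not in (0, 2):
        raise TreeValidationError(
            f"expected a rooted binary tree but the top-level node has "
            f"{len(root.children)} children"
        )
    return root


def write_newick(root: Node, lengths: bool = False) -> str:
    def rec(node: Node) -> str:
        if node.is_leaf:
            base = node.name
        else:
            base = "(" + ",".join(rec(c) for c in node.children) + ")" + node.name
        if lengths and node.length is not None:
            base += f":{node.length:g}"
        return base

    return rec(root) + ";"


def _min_leaf(node: Node, cache: dict[int, str]) -> str:
    key = id(node)
    if key not in cache:
        if node.is_leaf:
            cache[key] = node.name
        else:
            cache[key] = min(_min_leaf(c, cache) for c in node.children)
    return cache[key]


@dataclass(frozen=True)
class SpeciesTree:
    """A rooted binary species tree indexed by branch id (see module doc)."""

    n_leaves: int
    parent: np.ndarray          # parent branch id; -1 for the root stem
    left: np.ndarray            # child branch ids; -1 at leaves
    right: np.ndarray
    leaf_index: dict[str, int]  # leaf name -> branch id
    names: tuple[str, ...]      # per-branch label ("" if unnamed internal)
    lengths: np.ndarray         # display only; nan when absent
    newick: str

    @property
    def n_branches(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_branches - 1

    def is_leaf_branch(self, e: int) -> bool:
        return self.left[e] < 0

    @property
    def leaf_mask(self) -> np.ndarray:
        return self.left < 0

    def children(self, e: int) -> tuple[int, int]:
        return int(self.left[e]), int(self.right[e])

    def leaf_names(self) -> list[str]:
        return sorted(self.leaf_index, key=self.leaf_index.get)

    def branch_label(self, e: int) -> str:
        return self.names[e] if self.names[e] else f"b{e}"

    def path_branches(self, a: int, b: int) -> list[int]:
        """Branches on the path between branches a and b (inclusive)."""
        anc_a = []
        e = a
        while e >= 0:
            anc_a.append(e)
            e = int(self.parent[e])
        in_a = set(anc_a)
        path_b = []
        e = b
        while e not in in_a:
            path_b.append(e)
            e = int(self.parent[e])
        mrca = e
        out = []
        for x in anc_a:
            out.append(x)
            if x == mrca:
                break
        return out + path_b

    def __eq__(self, other) -> bool:
        return isinstance(other, SpeciesTree) and self.newick == other.newick

    def __hash__(self) -> int:
        return hash(self.newick)


def index_species_tree(tree: Node | str) -> SpeciesTree:
    """Assign deterministic branch ids to a rooted binary tree."""
    if isinstance(tree, str):
        tree = parse_newick(tree, expect_rooted=True)
    for node in tree.postorder():
        if node.children and len(node.children) != 2:
            raise TreeValidationError(
                f"non-binary node with {len(node.children)} children"
            )
    leaves = sorted(tree.leaf_names())
    n = len(leaves)
    N = 2 * n - 1
    leaf_index = {name: i for i, name in enumerate(leaves)}

    cache: dict[int, str] = {}
    ids: dict[int, int] = {}
    next_internal = n

    def assign(node: Node) -> int:
        nonlocal next_internal
        if node.is_leaf:
            ids[id(node)] = leaf_index[node.name]
            return ids[id(node)]
        kids = sorted(node.children, key=lambda c: _min_leaf(c, cache))
        for kid in kids:
            assign(kid)
        ids[id(node)] = next_internal
        next_internal += 1
        return ids[id(node)]

    assign(tree)

    parent = np.full(N, -1, dtype=np.int64)
    left = np.full(N, -1, dtype=np.int64)
    right = np.full(N, -1, dtype=np.int64)
    names = [""] * N
    lengths = np.full(N, np.nan)
    for node in tree.postorder():
        e = ids[id(node)]
        names[e] = node.name
        if node.length is not None:
            lengths[e] = node.length
        if node.children:
            kids = sorted(node.children, key=lambda c: _min_leaf(c, cache))
            c1, c2 = ids[id(kids[0])], ids[id(kids[1])]
            left[e], right[e] = c1, c2
            parent[c1] = e
            parent[c2] = e

    canonical = _canonical_newick(tree, cache)
    return SpeciesTree(
        n_leaves=n,
        parent=parent,
        left=left,
        right=right,
        leaf_index=leaf_index,
        names=tuple(names),
        lengths=lengths,
        newick=canonical,
    )


def _canonical_newick(tree: Node, cache: dict[int, str]) -> str:
    def rec(node: Node) -> str:
        if node.is_leaf:
            return node.name
        kids = sorted(node.children, key=lambda c: _min_leaf(c, cache))
        return "(" + ",".join(rec(c) for c in kids) + ")"

    return rec(tree) + ";"


class MappingError(ValueError):
    pass


def map_genes(gene_names: list[str], rule: str | dict[str, str]) -> dict[str, str]:
    """Map gene names to species names.

    ``rule`` is either ``"prefix:SEP"`` -- the species is the gene name up
    to the first occurrence of separator ``SEP`` (default convention
    ``prefix:_``, gene names like ``SPECIES_gene``) -- or an explicit
    gene -> species dict.
    """
    if isinstance(rule, dict):
        missing = [g for g in gene_names if g not in rule]
        if missing:
            raise MappingError(f"genes with no species mapping: {missing}")
        return {g: rule[g] for g in gene_names}
    if not rule.startswith("prefix:"):
        raise MappingError(f"unknown mapping rule {rule!r}")
    sep = rule[len("prefix:"):]
    if not sep:
        raise MappingError("empty separator in prefix rule")
    out = {}
    bad = []
    for g in gene_names:
        head, _, tail = g.partition(sep)
        if not tail or not head:
            bad.append(g)
        else:
            out[g] = head
    if bad:
        raise MappingError(f"genes without separator {sep!r}: {bad}")
    return out


@dataclass
class GeneFamily:
    """A gene family: its genes, species mapping, and a sample of topologies."""

    family_id: str
    genes: list[str]
    gene_to_species: dict[str, str]
    tree_sample: list[str]
    rooted: bool = False
    dropped: bool = False

    def __post_init__(self):
        if not self.dropped:
            self.validate()

    def validate(self, species_tree: SpeciesTree | None = None) -> None:
        if not self.tree_sample:
            raise TreeValidationError(f"family {self.family_id}: empty tree sample")
        gene_set = set(self.genes)
        missing = gene_set - set(self.gene_to_species)
        if missing:
            raise MappingError(
                f"family {self.family_id}: unmapped genes {sorted(missing)}"
            )
        for i, nwk in enumerate(self.tree_sample):
            tree = parse_newick(nwk, expect_rooted=self.rooted)
            if set(tree.leaf_names()) != gene_set:
                raise TreeValidationError(
                    f"family {self.family_id}: tree {i} leaf set differs from "
                    f"the family's gene set"
                )
        if species_tree is not None:
            bad = {
                s for s in self.gene_to_species.values()
                if s not in species_tree.leaf_index
            }
            if bad:
                raise MappingError(
                    f"family {self.family_id}: species not in tree: {sorted(bad)}"
                )

    @property
    def size(self) -> int:
        return len(self.genes)

    def species_represented(self) -> set[str]:
        return {self.gene_to_species[g] for g in self.genes}


def prune_tree(root: Node, keep_leaves: set[str]) -> Node | None:
    """Restrict a tree to ``keep_leaves``, suppressing degree-2 nodes."""

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            return node.copy() if node.name in keep_leaves else None
        kept = [rec(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        new = Node(node.name, node.length)
        for c in kept:
            new.add(c)
        return new

    return rec(root)


def prune_family(
    family: GeneFamily, keep_species: set[str], min_genes: int = 2
) -> GeneFamily:
    """Restrict a family to genes of ``keep_species``.

    Families left with fewer than ``min_genes`` genes are returned with
    ``dropped=True`` (a 1-gene family carries only origination/loss signal
    and is excluded from likelihood computations by default).
    """
    if not keep_species:
        raise ValueError("keep_species must be non-empty")
    kept_genes = [g for g in family.genes if family.gene_to_species[g] in keep_species]
    if len(kept_genes) < min_genes:
        return GeneFamily(
            family.family_id, kept_genes,
            {g: family.gene_to_species[g] for g in kept_genes},
            [], rooted=family.rooted, dropped=True,
        )
    keep = set(kept_genes)
    sample = []
    for nwk in family.tree_sample:
        pruned = prune_tree(parse_newick(nwk), keep)
        sample.append(write_newick(pruned))
    return GeneFamily(
        family.family_id, kept_genes,
        {g: family.gene_to_species[g] for g in kept_genes},
        sample, rooted=family.rooted,
    )


def prune_species_tree(tree: SpeciesTree, keep: set[str]) -> SpeciesTree:
    unknown = keep - set(tree.leaf_index)
    if unknown:
        raise ValueError(f"species not in tree: {sorted(unknown)}")
    if len(keep) < 1:
        raise ValueError("keep must be non-empty")
    pruned = prune_tree(parse_newick(tree.newick), keep)
    assert pruned is not None
    return index_species_tree(pruned)


def read_tree_file(path: str, expect_rooted: bool = True) -> SpeciesTree:
    with open(path) as fh:
        return index_species_tree(parse_newick(fh.read(), expect_rooted=expect_rooted))


def read_tree_sample(path: str) -> list[str]:
    """One newick per line; blank lines and #-comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_mapping_file(path: str) -> dict[str, str]:
    out = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MappingError(f"{path}:{i}: expected 2 tab-separated fields")
            out[parts[0]] = parts[1]
    return out
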