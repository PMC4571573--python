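"""Conditional clade probabilities (CCPs) from gene-tree samples.

A sample of topologies for one gene family is condensed into clade counts
n(gamma) and split counts n(gamma -> gamma1, gamma2), giving conditional
split probabilities q(gamma1, gamma2 | gamma).  These are the amalgamation
substrate: the reconciliation DP sums over every rooted tree that can be
pieced together from observed clades, a set that is usually vastly larger
than the sample itself.

Clades are bitsets (Python ints) over the family's genes, ordered by gene
name so clade identities are reproducible across runs.

Two observation modes:

* ``unrooted`` (default; posterior samples of topologies are effectively
  unrooted): every *directed* edge of each unrooted topology contributes
  one count to the clade on its far side and to the split induced there,
  and every undirected edge contributes one possible root split of the full
  gene set Gamma.
* ``rooted``: every node of each rooted tree contributes one clade count
  and one split count (used for simulator output and single-tree
  reductions).

No pseudo-counts and no smoothing: only observed clades and splits
participate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phylo import GeneFamily, Node, parse_newick

__all__ = ["CCPTable", "CCPError", "observe_sample", "parse_ccp", "observe_trees"]


class CCPError(ValueError):
    pass


@dataclass
class CCPTable:
    family_id: str
    genes: list[str]                       # sorted; bit i <-> genes[i]
    gene_to_species: dict[str, str]
    mode: str                              # "rooted" | "unrooted"
    sample_size: int
    clade_counts: dict[int, float]
    # parent clade -> list of (child1, child2, count); child1 < child2
    split_counts: dict[int, list[tuple[int, int, float]]]

    @property
    def gamma(self) -> int:
        """Bitset of the full gene set."""
        return (1 << len(self.genes)) - 1

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_bit(self, gene: str) -> int:
        return 1 << self.genes.index(gene)

    def clades_by_size(self) -> list[int]:
        cached = getattr(self, "_clade_order", None)
        if cached is None:
            cached = sorted(self.clade_counts, key=lambda c: (c.bit_count(), c))
            self._clade_order = cached
        return cached

    def singleton_species(self, clade: int) -> str:
        i = clade.bit_length() - 1
        return self.gene_to_species[self.genes[i]]

    def split_distribution(self, clade: int) -> list[tuple[int, int, float]]:
        """All recorded splits of ``clade`` as (child1, child2, q), q summing
        to 1; singletons return an empty list."""
        cache = getattr(self, "_split_cache", None)
        if cache is None:
            cache = {}
            self._split_cache = cache
        hit = cache.get(clade)
        if hit is not None:
            return hit
        if clade not in self.clade_counts:
            raise CCPError(f"clade {clade:#x} not observed")
        if clade.bit_count() == 1:
            out: list[tuple[int, int, float]] = []
        else:
            splits = self.split_counts.get(clade, [])
            total = sum(c for _, _, c in splits)
            out = [(c1, c2, cnt / total) for c1, c2, cnt in splits]
            out.sort(key=lambda t: (t[0], t[1]))
        cache[clade] = out
        return out

    def clade_names(self, clade: int) -> list[str]:
        return [g for i, g in enumerate(self.genes) if clade >> i & 1]

    def serialize(self) -> str:
        lines = [
            "#ccp\t1",
            "family\t" + self.family_id,
            "genes\t" + ",".join(self.genes),
            "species\t" + ",".join(self.gene_to_species[g] for g in self.genes),
            f"mode\t{self.mode}",
            f"nsamples\t{self.sample_size}",
        ]
        for clade in sorted(self.clade_counts):
            lines.append(f"clade\t{clade:x}\t{self.clade_counts[clade]:.12g}")
        for parent in sorted(self.split_counts):
            for c1, c2, cnt in sorted(self.split_counts[parent]):
                lines.append(f"split\t{parent:x}\t{c1:x}\t{c2:x}\t{cnt:.12g}")
        lines.append(f"end\t{len(lines) + 1}")
        return "\n".join(lines) + "\n"

    def validate(self) -> None:
        gamma = self.gamma
        if gamma not in self.clade_counts:
            raise CCPError("full gene set missing from clade counts")
        for clade in self.clade_counts:
            if clade <= 0 or clade & ~gamma:
                raise CCPError(f"clade {clade:#x} outside the gene set")
        for parent, splits in self.split_counts.items():
            for c1, c2, cnt in splits:
                if c1 | c2 != parent or c1 & c2:
                    raise CCPError(
                        f"split {c1:#x}|{c2:#x} is not a partition of {parent:#x}"
                    )
                if cnt <= 0:
                    raise CCPError("non-positive split count")
        for clade in self.clade_counts:
            if clade.bit_count() > 1:
                q = self.split_distribution(clade)
                s = sum(p for _, _, p in q)
                if abs(s - 1.0) > 1e-12:
                    raise CCPError(f"split probabilities of {clade:#x} sum to {s}")


def observe_sample(family: GeneFamily, mode: str | None = None) -> CCPTable:
    """Build the CCP table for one family from its tree sample."""
    if not family.tree_sample:
        raise CCPError(f"family {family.family_id}: empty tree sample")
    if mode is None:
        mode = "rooted" if family.rooted else "unrooted"
    return observe_trees(
        family.family_id,
        family.tree_sample,
        family.gene_to_species,
        mode=mode,
    )


def observe_trees(
    family_id: str,
    newicks: list[str],
    gene_to_species: dict[str, str],
    mode: str = "unrooted",
) -> CCPTable:
    if mode not in ("rooted", "unrooted"):
        raise CCPError(f"unknown mode {mode!r}")
    if not newicks:
        raise CCPError("empty tree sample")
    first = parse_newick(newicks[0])
    genes = sorted(first.leaf_names())
    index = {g: i for i, g in enumerate(genes)}
    missing = [g for g in genes if g not in gene_to_species]
    if missing:
        raise CCPError(f"genes without species mapping: {missing}")

    clade_counts: dict[int, float] = {}
    split_counts: dict[int, dict[tuple[int, int], float]] = {}

    def add_clade(c: int, w: float = 1.0) -> None:
        clade_counts[c] = clade_counts.get(c, 0.0) + w

    def add_split(parent: int, c1: int, c2: int, w: float = 1.0) -> None:
        key = (c1, c2) if c1 < c2 else (c2, c1)
        d = split_counts.setdefault(parent, {})
        d[key] = d.get(key, 0.0) + w

    gamma = (1 << len(genes)) - 1

    for k, nwk in enumerate(newicks):
        tree = parse_newick(nwk, expect_rooted=(mode == "rooted"))
        if set(tree.leaf_names()) != set(genes):
            raise CCPError(f"tree {k}: leaf set differs from tree 0")
        if mode == "rooted":
            _observe_rooted(tree, index, add_clade, add_split)
        else:
            _observe_unrooted(tree, index, gamma, add_clade, add_split)

    table = CCPTable(
        family_id=family_id,
        genes=genes,
        gene_to_species={g: gene_to_species[g] for g in genes},
        mode=mode,
        sample_size=len(newicks),
        clade_counts=clade_counts,
        split_counts={
            p: [(c1, c2, w) for (c1, c2), w in d.items()]
            for p, d in split_counts.items()
        },
    )
    table.validate()
    return table


def _observe_rooted(tree: Node, index, add_clade, add_split) -> None:
    sets: dict[int, int] = {}
    for node in tree.postorder():
        if node.is_leaf:
            c = 1 << index[node.name]
        else:
            if len(node.children) != 2:
                raise CCPError("rooted observation requires binary trees")
            c1 = sets[id(node.children[0])]
            c2 = sets[id(node.children[1])]
            c = c1 | c2
            add_split(c, c1, c2)
        sets[id(node)] = c
        add_clade(c)


def _observe_unrooted(tree: Node, index, gamma: int, add_clade, add_split) -> None:
    # Build the unrooted adjacency: suppress a bifurcating top-level node.
    if len(tree.children) == 2:
        a, b = tree.children
        a.parent = None
        if a.is_leaf:          # 2-leaf tree: a single edge
            if not b.is_leaf:
                a, b = b, a
        if a.is_leaf and b.is_leaf:
            ca, cb = 1 << index[a.name], 1 << index[b.name]
            add_clade(ca)
            add_clade(cb)
            add_split(gamma, ca, cb)
            add_clade(gamma)
            return
        if a.is_leaf:
            raise CCPError("degenerate topology")
        b.parent = None
        a.add(b)
        tree = a
    elif tree.is_leaf:
        raise CCPError("single-leaf tree has no clades to observe")

    # Adjacency lists over node ids.
    nodes: dict[int, Node] = {}
    adj: dict[int, list[int]] = {}

    def collect(node: Node) -> None:
        nodes[id(node)] = node
        adj.setdefault(id(node), [])
        for c in node.children:
            adj[id(node)].append(id(c))
            adj.setdefault(id(c), []).append(id(node))
            collect(c)

    collect(tree)

    # clade on the far side of each directed edge (u -> v): leaves beyond v.
    clade_of: dict[tuple[int, int], int] = {}

    def far_clade(u: int, v: int) -> int:
        key = (u, v)
        if key in clade_of:
            return clade_of[key]
        node = nodes[v]
        rest = [w for w in adj[v] if w != u]
        if not rest:
            c = 1 << index[node.name]
        else:
            if len(rest) != 2:
                raise CCPError("unrooted observation requires binary topologies")
            c = far_clade(v, rest[0]) | far_clade(v, rest[1])
        clade_of[key] = c
        return c

    seen_edges = set()
    for u in adj:
        for v in adj[u]:
            if (min(u, v), max(u, v)) not in seen_edges:
                seen_edges.add((min(u, v), max(u, v)))
                c_uv = far_clade(u, v)
                c_vu = far_clade(v, u)
                # root split on this edge
                add_split(gamma, c_uv, c_vu)
            # directed edge u -> v observes the far clade and its split
            c = far_clade(u, v)
            add_clade(c)
            rest = [w for w in adj[v] if w != u]
            if rest:
                add_split(c, far_clade(v, rest[0]), far_clade(v, rest[1]))
    add_clade(gamma)


def parse_ccp(text: str) -> CCPTable:
    lines = text.splitlines()
    if not lines or not lines[0].startswith("#ccp"):
        raise CCPError("not a CCP file (missing #ccp header)")
    meta: dict[str, str] = {}
    clade_counts: dict[int, float] = {}
    split_counts: dict[int, list[tuple[int, int, float]]] = {}
    end_seen = False
    for i, line in enumerate(lines):
        fields = line.split("\t")
        tag = fields[0]
        try:
            if tag in ("family", "genes", "species", "mode", "nsamples"):
                if len(fields) != 2:
                    raise CCPError(f"line {i + 1}: expected 2 fields")
                meta[tag] = fields[1]
            elif tag == "clade":
                if len(fields) != 3:
                    raise CCPError(f"line {i + 1}: expected 3 fields")
                c = int(fields[1], 16)
                if c <= 0:
                    raise CCPError(f"line {i + 1}: empty clade")
                clade_counts[c] = float(fields[2])
            elif tag == "split":
                if len(fields) != 5:
                    raise CCPError(f"line {i + 1}: expected 5 fields")
                p, c1, c2 = (int(x, 16) for x in fields[1:4])
                split_counts.setdefault(p, []).append((c1, c2, float(fields[4])))
            elif tag == "end":
                if int(fields[1]) != i + 1:
                    raise CCPError("line-count checksum mismatch (truncated file?)")
                end_seen = True
        except ValueError as exc:
            raise CCPError(f"line {i + 1}: {exc}") from None
    if not end_seen:
        raise CCPError("missing end line (truncated file?)")
    for key in ("family", "genes", "species", "mode", "nsamples"):
        if key not in meta:
            raise CCPError(f"missing {key} line")
    genes = meta["genes"].split(",")
    species = meta["species"].split(",")
    if len(genes) != len(species):
        raise CCPError("genes/species length mismatch")
    table = CCPTable(
        family_id=meta["family"],
        genes=genes,
        gene_to_species=dict(zip(genes, species)),
        mode=meta["mode"],
        sample_size=int(meta["nsamples"]),
        clade_counts=clade_counts,
        split_counts=split_counts,
    )
    table.validate()
    return table
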