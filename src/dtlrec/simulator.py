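"""Forward simulation under the exact undated DTL generative process.

``simulate_family`` is the generative mirror of the likelihood model and
serves as its independent oracle: a lineage entering branch e draws an
event with the normalized probabilities (p_S, p_D, p_T, p_L); S sends one
lineage into each child branch (at a species-tree leaf it is the sampling
event), D re-enters the same branch twice, T re-enters once and sends one
copy to a branch drawn uniformly among all N branches (the donor included),
L dies.  Extinct lineages are pruned from the output.

``perturb_tree_sample`` emulates posterior tree-sample noise at desk scale
by independent random NNI rearrangements of the true topology.

``simulate_genomes`` additionally evolves ordered circular single-chromosome
genomes so that gene adjacency carries signal: transfers can co-transfer
the current right neighbour (blocks of size 2), gains insert, losses
delete.  Because ordered genomes must be constructed top-down along the
species tree, a transfer whose uniformly drawn recipient was already
swept in the fixed pre-order cannot be delivered and is treated as a
transfer whose moved copy went extinct; realized transfers therefore flow
only forward along the sweep.  The per-family oracle above keeps the
exact uniform-recipient semantics.

``enumerate_outcomes`` exhaustively enumerates event histories on tiny
species trees with exact probability mass -- the brute-force cross-check
for both the simulator and the DP.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from random import Random

from .model import DTLRates, normalize_rates
from .phylo import GeneFamily, Node, SpeciesTree, parse_newick, write_newick

__all__ = [
    "SimNode",
    "SimFamily",
    "GenomeOrder",
    "TransferRecord",
    "SimulationExplosion",
    "simulate_family",
    "simulate_dataset",
    "perturb_tree_sample",
    "simulate_genomes",
    "transferred_leaf_genes",
    "enumerate_outcomes",
    "outcome_frequencies",
    "canonical_outcome",
]


class SimulationExplosion(RuntimeError):
    pass


class SimNode:
    """A lineage segment in the true gene history."""

    __slots__ = ("branch", "event", "children", "parent", "moved", "gene")

    def __init__(self, branch: int, parent: "SimNode | None" = None,
                 moved: bool = False):
        self.branch = branch
        self.event: str | None = None    # S, D, T, L, C
        self.children: list[SimNode] = []
        self.parent = parent
        self.moved = moved               # this copy arrived by transfer
        self.gene: str | None = None

    def spawn(self, branch: int, moved: bool = False) -> "SimNode":
        child = SimNode(branch, parent=self, moved=moved)
        self.children.append(child)
        return child


@dataclass
class SimFamily:
    family_id: str
    root: SimNode                       # full history, extinct lineages included
    newick: str | None                  # pruned true tree (None if <2 survivors)
    genes: list[str]
    gene_to_species: dict[str, str]
    origination: int
    seed: int
    events: list[tuple] = field(default_factory=list)  # (kind, branch[, recipient])

    @property
    def dropped(self) -> bool:
        return len(self.genes) < 2

    @property
    def size(self) -> int:
        return len(self.genes)

    def to_family(self, tree_sample: list[str] | None = None,
                  rooted: bool = True) -> GeneFamily:
        if self.dropped:
            raise ValueError(f"family {self.family_id} has <2 surviving genes")
        return GeneFamily(
            self.family_id, list(self.genes), dict(self.gene_to_species),
            tree_sample if tree_sample is not None else [self.newick],
            rooted=rooted,
        )

    def surviving_transfers(self) -> list[tuple[int, int]]:
        """(donor, recipient) of transfers whose moved copy left sampled
        descendants."""
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            stack.extend(node.children)
            if node.event == "T":
                moved = next(c for c in node.children if c.moved)
                if _has_survivor(moved):
                    out.append((node.branch, moved.branch))
        return out


def _has_survivor(node: SimNode) -> bool:
    stack = [node]
    while stack:
        n = stack.pop()
        if n.event == "C":
            return True
        stack.extend(n.children)
    return False


def _prune_history(node: SimNode) -> Node | None:
    """Binary pruned tree over sampled genes; unary pass-throughs removed."""
    if node.event == "C":
        return Node(node.gene)
    kept = [_prune_history(c) for c in node.children]
    kept = [k for k in kept if k is not None]
    if not kept:
        return None
    if len(kept) == 1:
        return kept[0]
    out = Node()
    for k in kept:
        out.add(k)
    return out


def _draw_kind(rng: Random, t_s: float, t_d: float, t_t: float) -> str:
    r = rng.random()
    if r < t_s:
        return "S"
    if r < t_d:
        return "D"
    if r < t_t:
        return "T"
    return "L"


def simulate_family(
    tree: SpeciesTree,
    rates: DTLRates,
    seed: int | None = None,
    rng: Random | None = None,
    family_id: str = "fam",
    origination: str | int = "uniform",
    recipient: str | int = "uniform",
    max_genes: int = 10_000,
) -> SimFamily:
    """Simulate one gene family forward along the species tree.

    ``origination`` and ``recipient`` may be fixed branch ids (the latter
    forces every transfer onto one recipient branch -- used to plant
    transfer highways).
    """
    if rng is None:
        rng = Random(seed)
    probs = normalize_rates(rates, tree)
    p_s, p_d, p_t = float(probs.p_s[0]), float(probs.p_d[0]), float(probs.p_t[0])
    t_s, t_d, t_t = p_s, p_s + p_d, p_s + p_d + p_t
    N = tree.n_branches

    e0 = rng.randrange(N) if origination == "uniform" else int(origination)
    root = SimNode(e0)
    events: list[tuple] = [("O", e0)]
    pending = [root]
    survivors: list[SimNode] = []
    processed = 0
    while pending:
        node = pending.pop()
        processed += 1
        if processed > max_genes:
            raise SimulationExplosion(
                f"family exceeded {max_genes} lineages (runaway birth rates)"
            )
        e = node.branch
        kind = _draw_kind(rng, t_s, t_d, t_t)
        if kind == "S":
            if tree.is_leaf_branch(e):
                node.event = "C"
                survivors.append(node)
                events.append(("C", e))
            else:
                node.event = "S"
                f, g = tree.children(e)
                pending.append(node.spawn(f))
                pending.append(node.spawn(g))
                events.append(("S", e))
        elif kind == "D":
            node.event = "D"
            pending.append(node.spawn(e))
            pending.append(node.spawn(e))
            events.append(("D", e))
        elif kind == "T":
            node.event = "T"
            h = rng.randrange(N) if recipient == "uniform" else int(recipient)
            pending.append(node.spawn(e))
            pending.append(node.spawn(h, moved=True))
            events.append(("T", e, h))
        else:
            node.event = "L"
            events.append(("L", e))

    counters: dict[str, int] = {}
    genes = []
    gene_to_species = {}
    for node in survivors:
        sp = _leaf_name(tree, node.branch)
        counters[sp] = counters.get(sp, 0) + 1
        name = f"{sp}_g{counters[sp]}"
        node.gene = name
        genes.append(name)
        gene_to_species[name] = sp

    pruned = _prune_history(root)
    newick = write_newick(pruned) if pruned is not None and len(genes) >= 2 else None
    return SimFamily(
        family_id=family_id, root=root, newick=newick,
        genes=genes, gene_to_species=gene_to_species,
        origination=e0, seed=seed if seed is not None else -1, events=events,
    )


def _leaf_name(tree: SpeciesTree, branch: int) -> str:
    for name, e in tree.leaf_index.items():
        if e == branch:
            return name
    raise ValueError(f"branch {branch} is not a leaf branch")


def simulate_dataset(
    tree: SpeciesTree,
    rates: DTLRates,
    n_families: int,
    seed: int,
    min_genes: int = 2,
    max_attempts_factor: int = 200,
    **kwargs,
) -> list[SimFamily]:
    """Simulate families until ``n_families`` have at least ``min_genes``
    surviving genes (families below the threshold are discarded, mirroring
    the treatment of 1-2 gene families in real pipelines)."""
    rng = Random(seed)
    out = []
    attempts = 0
    while len(out) < n_families:
        attempts += 1
        if attempts > max_attempts_factor * n_families:
            raise RuntimeError("too many extinct families; rates too loss-heavy")
        fam = simulate_family(
            tree, rates, rng=rng, family_id=f"fam{len(out):04d}", **kwargs
        )
        if fam.size >= min_genes:
            out.append(fam)
    return out


def perturb_tree_sample(
    true_tree: str, n_trees: int, nni_prob: float, seed: int
) -> list[str]:
    """Posterior-like sample: each output tree is the true rooted topology
    with every internal edge independently NNI-rearranged with probability
    ``nni_prob``."""
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not 0.0 <= nni_prob <= 1.0:
        raise ValueError("nni_prob must be in [0, 1]")
    rng = Random(seed)

    def swap(pa: Node, a: Node, pb: Node, b: Node) -> None:
        pa.children[pa.children.index(a)] = b
        pb.children[pb.children.index(b)] = a
        a.parent, b.parent = pb, pa

    out = []
    for _ in range(n_trees):
        tree = parse_newick(true_tree, expect_rooted=True)
        # edges of the *unrooted* topology joining two internal vertices:
        # (parent, child) with both internal and parent not the root, plus
        # the edge between the root's two children when both are internal
        edges: list[tuple[Node, Node]] = [
            (node, child)
            for node in tree.postorder()
            if node.children and node is not tree
            for child in node.children
            if child.children
        ]
        root_edge = None
        if len(tree.children) == 2 and all(c.children for c in tree.children):
            root_edge = (tree.children[0], tree.children[1])
        for u, v in edges:
            if rng.random() >= nni_prob:
                continue
            if v not in u.children:   # relation broken by an earlier swap
                continue
            sibs = [c for c in u.children if c is not v]
            if not sibs or not v.children:
                continue
            # swap the sibling of v with a random child of v (the two child
            # choices realize both NNI alternatives of this edge)
            swap(u, sibs[0], v, v.children[rng.randrange(len(v.children))])
        if root_edge is not None and rng.random() < nni_prob:
            v1, v2 = root_edge
            if v1.parent is tree and v2.parent is tree and \
                    v1.children and v2.children:
                swap(v1, v1.children[rng.randrange(len(v1.children))],
                     v2, v2.children[rng.randrange(len(v2.children))])
        out.append(write_newick(tree))
    return out


@dataclass
class GenomeOrder:
    """Per-species ordered gene lists along one circular chromosome."""

    orders: dict[str, list[tuple[str, str]]]   # species -> [(family_id, gene)]

    def neighbours(self, species: str, position: int) -> list[tuple[str, str]]:
        order = self.orders[species]
        n = len(order)
        if n <= 1:
            return []
        if n == 2:
            return [order[1 - position]]
        return [order[(position - 1) % n], order[(position + 1) % n]]

    def position_of(self, species: str) -> dict[str, int]:
        return {gene: i for i, (_, gene) in enumerate(self.orders[species])}

    def to_rows(self) -> list[tuple[str, int, str, str]]:
        rows = []
        for sp in sorted(self.orders):
            for i, (fid, gene) in enumerate(self.orders[sp]):
                rows.append((sp, i, fid, gene))
        return rows


@dataclass(frozen=True)
class TransferRecord:
    donor: int
    recipient: int
    block_size: int
    families: tuple[str, ...]


class _Cell:
    __slots__ = ("fid", "node", "resolved")

    def __init__(self, fid: str, node: SimNode):
        self.fid = fid
        self.node = node
        self.resolved = False


def simulate_genomes(
    tree: SpeciesTree,
    rates: DTLRates,
    n_families: int,
    block_prob: float,
    seed: int,
    max_genes: int = 100_000,
) -> tuple[list[SimFamily], GenomeOrder, list[TransferRecord]]:
    """Simulate ``n_families`` families together with ordered genomes.

    All families originate on the root stem; genomes evolve top-down in
    pre-order; with probability ``block_prob`` a transfer co-transfers the
    donor gene's current right neighbour (block size 2), and transferred
    blocks are inserted at a uniform random position of the recipient
    genome.
    """
    if not 0.0 <= block_prob <= 1.0:
        raise ValueError("block_prob must be in [0, 1]")
    rng = Random(seed)
    probs = normalize_rates(rates, tree)
    p_s = float(probs.p_s[0])
    p_d = float(probs.p_d[0])
    p_t = float(probs.p_t[0])
    t_s, t_d, t_t = p_s, p_s + p_d, p_s + p_d + p_t
    N = tree.n_branches

    fam_ids = [f"fam{i:04d}" for i in range(n_families)]
    roots = {fid: SimNode(tree.root) for fid in fam_ids}
    events: dict[str, list[tuple]] = {fid: [("O", tree.root)] for fid in fam_ids}

    # pre-order sweep
    order: list[int] = []
    stack = [tree.root]
    while stack:
        e = stack.pop()
        order.append(e)
        if not tree.is_leaf_branch(e):
            f, g = tree.children(e)
            stack.append(g)
            stack.append(f)
    visited: set[int] = set()
    pending_in: dict[int, list[list[_Cell]]] = {e: [] for e in order}
    truth: list[TransferRecord] = []
    leaf_orders: dict[str, list[tuple[str, str]]] = {}
    genome_at: dict[int, list[_Cell]] = {}

    stem_cells = [_Cell(fid, roots[fid]) for fid in fam_ids]
    rng.shuffle(stem_cells)
    genome_at[tree.root] = stem_cells

    total_lineages = 0
    for e in order:
        visited.add(e)
        genome = genome_at.pop(e, [])
        for block in pending_in[e]:
            pos = rng.randrange(len(genome) + 1) if genome else 0
            genome[pos:pos] = block
        queue = [c for c in genome]
        while queue:
            cell = queue.pop()
            if cell.resolved or cell.node.event is not None:
                continue
            total_lineages += 1
            if total_lineages > max_genes:
                raise SimulationExplosion(
                    f"genome simulation exceeded {max_genes} lineages"
                )
            kind = _draw_kind(rng, t_s, t_d, t_t)
            if kind == "S":
                cell.resolved = True
                continue           # survives to branch end; event set below
            if kind == "L":
                cell.node.event = "L"
                events[cell.fid].append(("L", e))
                genome.remove(cell)
                continue
            if kind == "D":
                cell.node.event = "D"
                events[cell.fid].append(("D", e))
                c1 = cell.node.spawn(e)
                c2 = cell.node.spawn(e)
                new = _Cell(cell.fid, c2)
                idx = genome.index(cell)
                genome.insert(idx + 1, new)
                fresh = _Cell(cell.fid, c1)
                genome[idx] = fresh
                queue.append(fresh)
                queue.append(new)
                continue
            # transfer: recipient uniform over all N branches; a draw onto a
            # branch already swept (other than the donor itself) cannot be
            # delivered into an ordered genome and is treated as a transfer
            # whose moved copy went extinct
            h = rng.randrange(N)
            if h in visited and h != e:
                queue.append(cell)   # the donor copy evolves on
                continue
            idx = genome.index(cell)
            block_cells = [cell]
            if rng.random() < block_prob and len(genome) > 1:
                block_cells.append(genome[(idx + 1) % len(genome)])
            moved_block: list[_Cell] = []
            for bc in block_cells:
                stay = bc.node.spawn(e)
                moved = bc.node.spawn(h, moved=True)
                bc.node.event = "T"
                events[bc.fid].append(("T", e, h))
                replacement = _Cell(bc.fid, stay)
                replacement.resolved = bc.resolved
                genome[genome.index(bc)] = replacement
                if not replacement.resolved:
                    queue.append(replacement)
                moved_block.append(_Cell(bc.fid, moved))
            truth.append(TransferRecord(
                donor=e, recipient=h, block_size=len(moved_block),
                families=tuple(c.fid for c in moved_block),
            ))
            if h == e:
                pos = rng.randrange(len(genome) + 1)
                genome[pos:pos] = moved_block
                queue.extend(moved_block)
            else:
                pending_in[h].append(moved_block)

        if tree.is_leaf_branch(e):
            sp = _leaf_name(tree, e)
            for cell in genome:
                cell.node.event = "C"
                events[cell.fid].append(("C", e))
            leaf_orders[sp] = genome      # gene names filled in below
        else:
            f, g = tree.children(e)
            gf, gg = [], []
            for cell in genome:
                cell.node.event = "S"
                events[cell.fid].append(("S", e))
                gf.append(_Cell(cell.fid, cell.node.spawn(f)))
                gg.append(_Cell(cell.fid, cell.node.spawn(g)))
            genome_at[f] = gf
            genome_at[g] = gg

    # name sampled genes and assemble outputs
    counters: dict[tuple[str, str], int] = {}
    orders: dict[str, list[tuple[str, str]]] = {}
    fam_genes: dict[str, list[str]] = {fid: [] for fid in fam_ids}
    fam_map: dict[str, dict[str, str]] = {fid: {} for fid in fam_ids}
    for sp in sorted(leaf_orders):
        row = []
        for cell in leaf_orders[sp]:
            key = (sp, cell.fid)
            counters[key] = counters.get(key, 0) + 1
            name = f"{sp}_{cell.fid}g{counters[key]}"
            cell.node.gene = name
            row.append((cell.fid, name))
            fam_genes[cell.fid].append(name)
            fam_map[cell.fid][name] = sp
        orders[sp] = row

    families = []
    for fid in fam_ids:
        pruned = _prune_history(roots[fid])
        genes = fam_genes[fid]
        newick = write_newick(pruned) if pruned is not None and len(genes) >= 2 else None
        families.append(SimFamily(
            family_id=fid, root=roots[fid], newick=newick, genes=genes,
            gene_to_species=fam_map[fid], origination=tree.root,
            seed=seed, events=events[fid],
        ))
    return families, GenomeOrder(orders), truth


def transferred_leaf_genes(
    families: list[SimFamily], tree: SpeciesTree
) -> dict[str, set[str]]:
    """Genes whose lineage arrived on their terminal branch by transfer
    (from the simulation truth): per species, the set of such gene names."""
    out: dict[str, set[str]] = {name: set() for name in tree.leaf_index}
    for fam in families:
        stack = [fam.root]
        while stack:
            node = stack.pop()
            stack.extend(node.children)
            if node.event == "C":
                leaf_branch = node.branch
                cur = node
                hit = False
                while cur is not None and cur.branch == leaf_branch:
                    if cur.moved:
                        hit = True
                        break
                    cur = cur.parent
                if hit:
                    out[fam.gene_to_species[node.gene]].add(node.gene)
    return out


# ---------------------------------------------------------------------------
# exhaustive enumeration and fast outcome sampling (tiny-instance oracles)

def canonical_outcome(node) -> str:
    """Canonical string of a pruned species-labelled topology: leaves are
    species names, children sorted lexicographically."""
    if isinstance(node, str):
        return node
    parts = sorted(canonical_outcome(c) for c in node)
    return "(" + ",".join(parts) + ")"


def enumerate_outcomes(
    tree: SpeciesTree,
    rates: DTLRates,
    max_events: int = 12,
    prune_mass: float = 0.0,
) -> tuple[dict[str, float], float]:
    """Exact outcome-class probabilities by exhaustive history enumeration.

    Returns (class -> probability, unexplored tail mass).  Classes are
    canonical pruned topologies over species names, "extinct" for no
    survivors; origination is uniform over branches.  Only sensible for
    species trees with at most ~3 leaves.
    """
    if tree.n_leaves > 3:
        raise ValueError("exhaustive enumeration is limited to <=3-leaf trees")
    probs = normalize_rates(rates, tree)
    p_s = float(probs.p_s[0]); p_d = float(probs.p_d[0])
    p_t = float(probs.p_t[0]); p_l = float(probs.p_l[0])
    N = tree.n_branches
    leaf_of = {e: name for name, e in tree.leaf_index.items()}
    acc: dict[str, float] = {}
    tail = 0.0

    # The partial outcome is a nested mutable list rooted at outcome[0];
    # each pending lineage points into it by a child-index path.  States
    # are copied on branching, so sharing between alternatives is safe.
    def explore2(pending, outcome, prob, n_events):
        nonlocal tail
        if prune_mass > 0.0 and prob <= prune_mass:
            tail += prob
            return
        if not pending:
            frozen = _freeze(outcome)
            key = "extinct" if frozen is None else canonical_outcome(frozen)
            acc[key] = acc.get(key, 0.0) + prob
            return
        if n_events >= max_events:
            tail += prob
            return
        (e, path), rest = pending[0], pending[1:]
        if tree.is_leaf_branch(e):
            o2 = _set_path(outcome, path, leaf_of[e])
            explore2(rest, o2, prob * p_s, n_events + 1)
        else:
            f, g = tree.children(e)
            o2 = _set_path(outcome, path, [None, None])
            explore2(rest + [(f, path + (0,)), (g, path + (1,))],
                     o2, prob * p_s, n_events + 1)
        o2 = _set_path(outcome, path, [None, None])
        explore2(rest + [(e, path + (0,)), (e, path + (1,))],
                 o2, prob * p_d, n_events + 1)
        if p_t > 0:
            for h in range(N):
                explore2(rest + [(e, path + (0,)), (h, path + (1,))],
                         o2, prob * p_t / N, n_events + 1)
        o3 = _set_path(outcome, path, "DEAD")
        explore2(rest, o3, prob * p_l, n_events + 1)

    for e0 in range(N):
        explore2([(e0, ())], [None], 1.0 / N, 0)
    return acc, tail


def _freeze(outcome):
    node = outcome[0]
    def rec(x):
        if x == "DEAD" or x is None:
            return None
        if isinstance(x, str):
            return x
        kids = [rec(c) for c in x]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return tuple(kids)
    return rec(node)


def _set_path(outcome, path, value):
    import copy
    out = copy.deepcopy(outcome)
    cur = out
    idx = 0
    for p in path:
        cur = cur[idx]
        idx = p
    cur[idx] = value
    return out


def labeled_topologies(items: list[str]) -> list:
    """All distinct rooted binary labeled topologies over ``items`` as nested
    tuples ((2k-3)!! of them); each unordered shape appears exactly once."""
    if len(items) == 1:
        return [items[0]]
    first, rest = items[0], items[1:]
    out = []
    # subsets of rest joining `first` in the left subtree
    for mask in range(1 << len(rest)):
        left = [first] + [rest[i] for i in range(len(rest)) if mask >> i & 1]
        right = [rest[i] for i in range(len(rest)) if not mask >> i & 1]
        if not right:
            continue
        for lt in labeled_topologies(left):
            for rt in labeled_topologies(right):
                out.append((lt, rt))
    return out


def dp_class_probabilities(
    tree: SpeciesTree, rates: DTLRates, max_genes: int = 3
) -> dict[str, float]:
    """Probability of every outcome class with at most ``max_genes`` sampled
    genes, computed through the amalgamation DP.

    For each gene multiset over the species, every distinct labeled rooted
    topology is scored with a one-tree CCP; the class (canonical pruned
    species-labelled shape) accumulates the sum divided by the number of
    interchangeable gene labelings (prod_s n_s!) -- under the ordered-copy
    convention of the DP this equals the probability a forward simulation
    estimates as the class frequency.  The "extinct" class is the mean
    extinction probability over origination branches.
    """
    from itertools import combinations_with_replacement

    from .ccp import observe_trees
    from .model import compute_extinction, family_loglik

    species = sorted(tree.leaf_index)
    probs = normalize_rates(rates, tree)
    out = {"extinct": compute_extinction(probs, tree).Ebar}

    def to_newick(t) -> str:
        if isinstance(t, str):
            return t
        return "(" + to_newick(t[0]) + "," + to_newick(t[1]) + ")"

    def species_shape(t):
        if isinstance(t, str):
            return t.rsplit("_", 1)[0]
        return (species_shape(t[0]), species_shape(t[1]))

    for k in range(1, max_genes + 1):
        for combo in combinations_with_replacement(species, k):
            genes = []
            counter: dict[str, int] = {}
            for sp in combo:
                counter[sp] = counter.get(sp, 0) + 1
                genes.append(f"{sp}_g{counter[sp]}")
            mapping = {g: g.rsplit("_", 1)[0] for g in genes}
            labelings = 1.0
            for c in counter.values():
                labelings *= math.factorial(c)
            for topo in labeled_topologies(genes):
                key = canonical_outcome(species_shape(topo))
                ccp = observe_trees("o", [to_newick(topo) + ";"], mapping,
                                    mode="rooted")
                ll = family_loglik(ccp, tree, rates)
                if math.isfinite(ll):
                    out[key] = out.get(key, 0.0) + math.exp(ll) / labelings
    return out


def outcome_frequencies(
    tree: SpeciesTree,
    rates: DTLRates,
    n_draws: int,
    seed: int,
    max_survivors: int = 3,
    cap: int = 200,
) -> Counter:
    """Empirical outcome-class frequencies from ``n_draws`` forward draws.

    Classes match :func:`enumerate_outcomes`; outcomes with more than
    ``max_survivors`` sampled genes are lumped into "big".  Optimized inner
    loop (this backs the simulator-vs-DP oracle comparisons at 10^6 draws).
    """
    rng = Random(seed)
    probs = normalize_rates(rates, tree)
    p_s = float(probs.p_s[0]); p_d = float(probs.p_d[0]); p_t = float(probs.p_t[0])
    t_s, t_d, t_t = p_s, p_s + p_d, p_s + p_d + p_t
    N = tree.n_branches
    is_leaf = [tree.is_leaf_branch(e) for e in range(N)]
    kids = [tree.children(e) if not is_leaf[e] else None for e in range(N)]
    leaf_of = {e: name for name, e in tree.leaf_index.items()}
    rand = rng.random
    randrange = rng.randrange
    counts: Counter = Counter()

    for _ in range(n_draws):
        # each lineage: [branch, parent_slot]; build nested structure lazily
        survivors = 0
        steps = 0
        overflow = False

        def grow(e: int):
            nonlocal survivors, steps, overflow
            if overflow:
                return None
            while True:
                steps += 1
                if steps > cap or survivors > max_survivors:
                    overflow = True
                    return None
                r = rand()
                if r < t_s:
                    if is_leaf[e]:
                        survivors += 1
                        return leaf_of[e]
                    f, g = kids[e]
                    a = grow(f)
                    b = grow(g)
                    break
                elif r < t_d:
                    a = grow(e)
                    b = grow(e)
                    break
                elif r < t_t:
                    h = randrange(N)
                    a = grow(e)
                    b = grow(h)
                    break
                else:
                    return None
            if a is None:
                return b
            if b is None:
                return a
            return (a, b)

        out = grow(randrange(N))
        if overflow:
            counts["big"] += 1
        elif out is None:
            counts["extinct"] += 1
        else:
            counts[canonical_outcome(out)] += 1
    return counts
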