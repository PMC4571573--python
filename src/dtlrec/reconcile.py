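"""Sampling reconciliations and aggregating event histories.

A reconciliation is drawn by stochastic backtracking through the converged
amalgamation DP: the origination branch is drawn proportional to
pi(Gamma, e), and at each DP cell (clade, branch) one realized term --
split choice x event type x transfer recipient -- is drawn proportional to
its contribution to pi(clade, branch).

Event vocabulary (branch ids refer to the species tree):

O   origination of the family on a branch
S   speciation, both daughter lineages survive
SL  speciation where one daughter lineage goes extinct (the loss is
    charged to the branch where the lineage died, i.e. the lost child)
D   duplication, both copies survive
T   transfer, both copies survive (recipient branch recorded)
TL  transfer where the donor copy goes extinct (loss charged to the donor)
C   sampling of a gene at a species-tree leaf

DP terms in which a born copy immediately goes extinct (duplication with
one extinct copy, transfer whose transferred copy dies) leave no observable
trace and are traversed silently.

Per-branch copy numbers count lineages alive when the end of the branch is
reached: one per S, SL or C event on the branch.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from random import Random

import numpy as np
import pandas as pd

from .ccp import CCPTable
from .model import DPTables, DTLRates, compute_dp
from .phylo import SpeciesTree

__all__ = [
    "Event",
    "RecNode",
    "Reconciliation",
    "EventSummary",
    "sample_reconciliations",
    "summarize_events",
    "summarize_families",
    "ancestral_copy_numbers",
    "replacement_fraction",
]

LOSS_KINDS = ("SL", "TL")


@dataclass(frozen=True)
class Event:
    kind: str                 # O, S, SL, D, T, TL, C
    branch: int
    recipient: int | None = None   # T/TL only
    lost: int | None = None        # SL only: child branch where the copy died
    clade: int = 0

    def __post_init__(self):
        if (self.recipient is not None) != (self.kind in ("T", "TL")):
            raise ValueError(f"recipient must be set iff kind is T/TL ({self.kind})")


class RecNode:
    """Node of a sampled reconciled gene tree; leaves carry gene names.

    ``edge_transfers`` counts the transfer hops (moved copy of a T, or a TL
    relocation) on the lineage segment between this node and its parent;
    ``arrived_transfer`` marks a sampled gene whose *last* entry onto its
    terminal branch was a transfer.
    """

    __slots__ = ("clade", "event", "branch", "children", "gene", "parent",
                 "edge_transfers", "arrived_transfer")

    def __init__(self, clade: int, event: str, branch: int,
                 children: list["RecNode"] | None = None, gene: str | None = None,
                 edge_transfers: int = 0, arrived_transfer: bool = False):
        self.clade = clade
        self.event = event
        self.branch = branch
        self.children = []
        self.gene = gene
        self.parent: RecNode | None = None
        self.edge_transfers = edge_transfers
        self.arrived_transfer = arrived_transfer
        for c in children or []:
            self.adopt(c)

    def adopt(self, child: "RecNode") -> None:
        child.parent = self
        self.children.append(child)

    def walk(self):
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def newick(self) -> str:
        def rec(n: RecNode) -> str:
            if not n.children:
                return n.gene or ""
            return "(" + ",".join(rec(c) for c in n.children) + ")"
        return rec(self) + ";"


@dataclass
class Reconciliation:
    family_id: str
    root: RecNode | None     # None when rebuilt from an event log
    events: list[Event]
    n_branches: int
    sample_index: int
    seed: int

    @property
    def newick(self) -> str:
        if self.root is None:
            raise ValueError("no topology: reconciliation was rebuilt from a log")
        return self.root.newick()

    def leaf_count(self) -> int:
        return sum(1 for e in self.events if e.kind == "C")

    def leaf_nodes(self) -> dict[str, RecNode]:
        return {n.gene: n for n in self.root.walk() if n.event == "C"}

    def transfer_arrivals(self) -> dict[str, bool]:
        """Per sampled gene: did its lineage arrive on its terminal branch
        by transfer (rather than by speciation from the parent branch)?"""
        return {n.gene: n.arrived_transfer for n in self.root.walk()
                if n.event == "C"}

    def path_transferred(self, gene_a: str, gene_b: str) -> bool:
        """Whether any transfer hop lies on the gene-tree path between two
        sampled genes (the classification rule for transferred genes in
        pairwise synteny comparisons)."""
        leaves = self.leaf_nodes()
        na, nb = leaves[gene_a], leaves[gene_b]
        anc_a = []
        cur = na
        while cur is not None:
            anc_a.append(cur)
            cur = cur.parent
        in_a = {id(x): i for i, x in enumerate(anc_a)}
        hops = 0
        cur = nb
        while id(cur) not in in_a:
            hops += cur.edge_transfers
            cur = cur.parent
        for x in anc_a[: in_a[id(cur)]]:
            hops += x.edge_transfers
        return hops > 0

    def loss_branches(self) -> set[int]:
        out = set()
        for ev in self.events:
            if ev.kind == "SL":
                out.add(ev.lost)
            elif ev.kind == "TL":
                out.add(ev.branch)
        return out


def _weighted_choice(rng: Random, weights: list[float]) -> int:
    total = 0.0
    cum = []
    for w in weights:
        total += w
        cum.append(total)
    if total <= 0.0:
        raise RuntimeError("no positive-weight option at a DP cell")
    return bisect_right(cum, rng.random() * total)


def sample_reconciliations(
    ccp: CCPTable,
    tree: SpeciesTree,
    rates: DTLRates,
    n_samples: int = 100,
    seed: int = 0,
    model: str = "DTL",
    conditioning: str = "none",
    dp: DPTables | None = None,
    max_steps: int = 1_000_000,
) -> list[Reconciliation]:
    """Draw ``n_samples`` reconciliations for one family (reproducible given
    ``seed``)."""
    if dp is None:
        dp = compute_dp(ccp, tree, rates, model=model, conditioning=conditioning)
    if not math.isfinite(dp.loglik):
        raise ValueError(f"family {ccp.family_id}: zero likelihood; cannot sample")
    if n_samples == 0:
        return []

    rng = Random(seed)
    N = tree.n_branches
    pi, scale = dp.pi, dp.logscale
    p_s, p_d, p_t = dp.probs.p_s, dp.probs.p_d, dp.probs.p_t
    E, ebar = dp.ext.E, dp.ext.Ebar
    gamma = ccp.gamma
    splits_of = {c: ccp.split_distribution(c) for c in ccp.clade_counts}
    gene_of_bit = {1 << i: g for i, g in enumerate(ccp.genes)}

    def draw_branch(arr: np.ndarray) -> int:
        cum = np.cumsum(arr)
        if cum[-1] <= 0:
            raise RuntimeError("cannot draw a branch: all-zero weights")
        return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))

    root_weights = pi[gamma]

    out = []
    for k in range(n_samples):
        events: list[Event] = []
        steps = 0

        def build(clade: int, e: int, moved: bool = False) -> RecNode:
            nonlocal steps
            single = clade.bit_count() == 1
            edge_tr = 1 if moved else 0   # transfer hops on the edge above
            via = moved                   # last branch entry was a transfer
            while True:
                steps += 1
                if steps > max_steps:
                    raise RuntimeError("reconciliation sampling did not terminate")
                options: list[float] = []
                actions: list[tuple] = []
                if single and tree.is_leaf_branch(e) and \
                        tree.leaf_index[ccp.singleton_species(clade)] == e:
                    options.append(p_s[e] * math.exp(-scale[clade]))
                    actions.append(("C",))
                for c1, c2, q in splits_of[clade]:
                    w = q * math.exp(scale[c1] + scale[c2] - scale[clade])
                    if w == 0.0:
                        continue
                    p1, p2 = pi[c1], pi[c2]
                    options.append(w * 2.0 * p_d[e] * p1[e] * p2[e])
                    actions.append(("D", c1, c2))
                    options.append(w * p_t[e] * float(p1.mean()) * p2[e])
                    actions.append(("T", c1, c2))     # c1 transferred out
                    options.append(w * p_t[e] * float(p2.mean()) * p1[e])
                    actions.append(("T", c2, c1))
                    if not tree.is_leaf_branch(e):
                        fe, ge = tree.children(e)
                        options.append(w * p_s[e] * p1[fe] * p2[ge])
                        actions.append(("S", c1, fe, c2, ge))
                        options.append(w * p_s[e] * p1[ge] * p2[fe])
                        actions.append(("S", c1, ge, c2, fe))
                cur = pi[clade]
                if not tree.is_leaf_branch(e):
                    fe, ge = tree.children(e)
                    options.append(p_s[e] * cur[fe] * E[ge])
                    actions.append(("SL", fe, ge))
                    options.append(p_s[e] * cur[ge] * E[fe])
                    actions.append(("SL", ge, fe))
                options.append(2.0 * p_d[e] * cur[e] * E[e])
                actions.append(("D0",))
                options.append(p_t[e] * float(cur.mean()) * E[e])
                actions.append(("TL",))
                options.append(p_t[e] * ebar * cur[e])
                actions.append(("T0",))

                act = actions[_weighted_choice(rng, options)]
                kind = act[0]
                if kind == "C":
                    events.append(Event("C", e, clade=clade))
                    return RecNode(clade, "C", e, gene=gene_of_bit[clade],
                                   edge_transfers=edge_tr, arrived_transfer=via)
                if kind == "D":
                    _, c1, c2 = act
                    events.append(Event("D", e, clade=clade))
                    return RecNode(clade, "D", e, [build(c1, e), build(c2, e)],
                                   edge_transfers=edge_tr)
                if kind == "T":
                    _, mclade, stay = act
                    h = draw_branch(pi[mclade])
                    events.append(Event("T", e, recipient=h, clade=clade))
                    return RecNode(clade, "T", e,
                                   [build(mclade, h, moved=True), build(stay, e)],
                                   edge_transfers=edge_tr)
                if kind == "S":
                    _, c1, b1, c2, b2 = act
                    events.append(Event("S", e, clade=clade))
                    return RecNode(clade, "S", e, [build(c1, b1), build(c2, b2)],
                                   edge_transfers=edge_tr)
                if kind == "SL":
                    _, surv, lost = act
                    events.append(Event("SL", e, lost=lost, clade=clade))
                    e = surv
                    via = False
                    continue
                if kind == "TL":
                    h = draw_branch(cur)
                    events.append(Event("TL", e, recipient=h, clade=clade))
                    e = h
                    edge_tr += 1
                    via = True
                    continue
                # D0 / T0: a born copy went immediately extinct; no trace.

        e0 = draw_branch(root_weights)
        events.append(Event("O", e0, clade=gamma))
        root = build(gamma, e0)
        out.append(Reconciliation(
            family_id=ccp.family_id, root=root, events=events,
            n_branches=N, sample_index=k, seed=seed,
        ))
    return out


@dataclass
class EventSummary:
    """Mean per-branch / per-branch-pair event counts.

    Means are over reconciliation samples within a family; summaries of
    different families add.
    """

    n_branches: int
    D: np.ndarray
    T_in: np.ndarray
    T_out: np.ndarray
    L: np.ndarray
    O: np.ndarray
    S: np.ndarray
    copies: np.ndarray
    pair_counts: dict[tuple[int, int], float] = field(default_factory=dict)
    n_families: int = 1

    @classmethod
    def zeros(cls, n_branches: int) -> "EventSummary":
        z = lambda: np.zeros(n_branches)
        return cls(n_branches, z(), z(), z(), z(), z(), z(), z(), {}, 0)

    def add(self, other: "EventSummary") -> "EventSummary":
        if other.n_branches != self.n_branches:
            raise ValueError("summaries refer to different species trees")
        out = EventSummary(
            self.n_branches,
            self.D + other.D, self.T_in + other.T_in, self.T_out + other.T_out,
            self.L + other.L, self.O + other.O, self.S + other.S,
            self.copies + other.copies,
            dict(self.pair_counts), self.n_families + other.n_families,
        )
        for k, v in other.pair_counts.items():
            out.pair_counts[k] = out.pair_counts.get(k, 0.0) + v
        return out

    def totals(self) -> dict[str, float]:
        return {
            "T": float(self.T_in.sum()),
            "D": float(self.D.sum()),
            "L": float(self.L.sum()),
            "O": float(self.O.sum()),
            "S": float(self.S.sum()),
        }

    @property
    def gains(self) -> np.ndarray:
        """Gene gains arriving on each branch: incoming transfers plus
        originations."""
        return self.T_in + self.O

    def to_frame(self, tree: SpeciesTree | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "branch": np.arange(self.n_branches),
            "parent": tree.parent if tree is not None else -1,
            "D": self.D, "T_in": self.T_in, "T_out": self.T_out,
            "L": self.L, "O": self.O, "S": self.S, "copies": self.copies,
        })
        if tree is not None:
            df["label"] = [tree.branch_label(e) for e in range(self.n_branches)]
        return df

    def pair_frame(self) -> pd.DataFrame:
        rows = [(d, r, c) for (d, r), c in sorted(self.pair_counts.items())]
        return pd.DataFrame(rows, columns=["donor", "recipient", "count"])


def summarize_events(
    recs: list[Reconciliation], weight: float | None = None
) -> EventSummary:
    """Aggregate one family's sampled reconciliations into mean counts."""
    if not recs:
        raise ValueError("no reconciliations to summarize")
    n = recs[0].n_branches
    if any(r.n_branches != n for r in recs):
        raise ValueError("reconciliations refer to different species trees")
    if weight is None:
        weight = 1.0 / len(recs)
    out = EventSummary.zeros(n)
    out.n_families = 1
    for rec in recs:
        for ev in rec.events:
            if ev.kind == "D":
                out.D[ev.branch] += weight
            elif ev.kind == "O":
                out.O[ev.branch] += weight
            elif ev.kind == "S":
                out.S[ev.branch] += weight
                out.copies[ev.branch] += weight
            elif ev.kind == "C":
                out.copies[ev.branch] += weight
            elif ev.kind == "SL":
                out.S[ev.branch] += weight
                out.copies[ev.branch] += weight
                out.L[ev.lost] += weight
            elif ev.kind in ("T", "TL"):
                out.T_out[ev.branch] += weight
                out.T_in[ev.recipient] += weight
                key = (ev.branch, ev.recipient)
                out.pair_counts[key] = out.pair_counts.get(key, 0.0) + weight
                if ev.kind == "TL":
                    out.L[ev.branch] += weight
    return out


def summarize_families(
    recs_by_family: list[list[Reconciliation]]
) -> EventSummary:
    """Sum of per-family mean summaries across families."""
    if not recs_by_family:
        raise ValueError("no families")
    out = summarize_events(recs_by_family[0])
    for recs in recs_by_family[1:]:
        out = out.add(summarize_events(recs))
    return out


def ancestral_copy_numbers(summaries: list[EventSummary]) -> np.ndarray:
    """Per-branch genome size: the sum over families of mean copy numbers.

    At leaf branches this equals the observed number of genes per species.
    """
    if not summaries:
        raise ValueError("no summaries")
    out = np.zeros(summaries[0].n_branches)
    for s in summaries:
        if s.n_branches != out.shape[0]:
            raise ValueError("summaries refer to different species trees")
        out += s.copies
    return out


def replacement_fraction(
    recs_by_family: list[list[Reconciliation]], n_branches: int | None = None
) -> tuple[np.ndarray, float | None]:
    """Branch-wise fraction of incoming transfers compensated by a loss of
    the same family on the same branch within the same sampled
    reconciliation ("replacement transfers"), and the median over branches
    that receive any transfer.  Returns (fractions, median); the median is
    None when no transfers occur anywhere.
    """
    if n_branches is None:
        n_branches = recs_by_family[0][0].n_branches
    total = np.zeros(n_branches)
    comp = np.zeros(n_branches)
    for recs in recs_by_family:
        for rec in recs:
            losses = rec.loss_branches()
            for ev in rec.events:
                if ev.kind in ("T", "TL"):
                    total[ev.recipient] += 1
                    if ev.recipient in losses:
                        comp[ev.recipient] += 1
    mask = total > 0
    frac = np.zeros(n_branches)
    frac[mask] = comp[mask] / total[mask]
    med = float(np.median(frac[mask])) if mask.any() else None
    return frac, med
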