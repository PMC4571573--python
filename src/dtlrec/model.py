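"""The undated DTL birth-death model and its amalgamation likelihood.

Model.  A gene lineage on a species-tree branch undergoes one of four
events: speciation (S, rate normalized to 1), duplication (D, rate delta),
transfer (T, rate tau) or loss (L, rate lambda).  Because the species tree
carries no time order ("undated"), rates enter only through per-branch
event probabilities

    p_S = 1/(1+d+t+l),  p_D = d/(1+d+t+l),  p_T = t/(1+d+t+l),
    p_L = l/(1+d+t+l),

and transfers land uniformly on any of the N = 2n-1 branches (including
the donor; a self-transfer is indistinguishable from a duplication and
contributes O(1/N)).  At a species-tree leaf, p_S is the probability of the
sampling/observation event.  Originations are uniform over branches with
prior 1/N.

Extinction.  E(e) is the probability that a single lineage entering branch
e leaves no sampled descendant; it solves the per-branch fixed point

    E(e) = p_L + p_D E(e)^2 + p_T E(e) Ebar + p_S E(f) E(g),

with E(f)E(g) -> 0 on leaf branches and Ebar the mean of E over branches.

Likelihood.  pi(gamma, e) is the probability that a single lineage entering
branch e gives rise to exactly the observed genes of clade gamma, summed
over every amalgamatable resolution of gamma weighted by its conditional
clade probability q.  Duplication daughter copies follow the ordered
convention (factor 2), matching the forward process in which the two
copies' fates are independent draws.  Clades are processed in ascending
size; within one clade the equations are mutually recursive across
branches (speciation-loss, duplication- and transfer-with-extinction
feedback), a linear system that is identical for every clade and is
therefore LU-factorized once per rate vector and solved exactly per clade
(:func:`gene_tree_loglik` keeps an independent fixed-point implementation
of the same equations as a cross-check).  The family likelihood is
(1/N) sum_e pi(Gamma, e), optionally divided by the survival probability
1 - Ebar.  The DL variant simply forces tau = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ccp import CCPTable
from .phylo import Node, SpeciesTree, parse_newick

__all__ = [
    "DTLRates",
    "EventProbs",
    "ExtinctionVector",
    "DPTables",
    "normalize_rates",
    "compute_extinction",
    "compute_dp",
    "family_loglik",
    "gene_tree_loglik",
    "total_loglik",
    "optimize_rates",
    "OptimizeResult",
    "RATE_BOUNDS",
]

RATE_BOUNDS = (1e-6, 10.0)


@dataclass(frozen=True)
class DTLRates:
    """Duplication, transfer and loss rates relative to a speciation rate
    of 1 (the undated model only ever identifies relative rates)."""

    delta: float
    tau: float
    lam: float

    def __post_init__(self):
        for name, v in (("delta", self.delta), ("tau", self.tau), ("lam", self.lam)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"rate {name}={v} must be finite and >= 0")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delta, self.tau, self.lam)

    def without_transfer(self) -> "DTLRates":
        return DTLRates(self.delta, 0.0, self.lam)


@dataclass(frozen=True)
class EventProbs:
    """Per-branch event probabilities; rows sum to one."""

    p_s: np.ndarray
    p_d: np.ndarray
    p_t: np.ndarray
    p_l: np.ndarray

    def validate(self) -> None:
        total = self.p_s + self.p_d + self.p_t + self.p_l
        if not np.allclose(total, 1.0, atol=1e-12):
            raise ValueError("event probabilities do not sum to 1")


@dataclass(frozen=True)
class ExtinctionVector:
    E: np.ndarray
    residual: float

    @property
    def Ebar(self) -> float:
        return float(self.E.mean())


def normalize_rates(rates: DTLRates, tree: SpeciesTree) -> EventProbs:
    N = tree.n_branches
    z = 1.0 + rates.delta + rates.tau + rates.lam
    return EventProbs(
        p_s=np.full(N, 1.0 / z),
        p_d=np.full(N, rates.delta / z),
        p_t=np.full(N, rates.tau / z),
        p_l=np.full(N, rates.lam / z),
    )


def compute_extinction(
    probs: EventProbs,
    tree: SpeciesTree,
    tol: float = 1e-12,
    max_iter: int = 10000,
) -> ExtinctionVector:
    """Solve the extinction fixed point by iteration from E = 0."""
    N = tree.n_branches
    internal = ~tree.leaf_mask
    f = np.where(internal, tree.left, 0)
    g = np.where(internal, tree.right, 0)
    E = np.zeros(N)
    for _ in range(max_iter):
        ebar = E.mean()
        spec = np.where(internal, E[f] * E[g], 0.0)
        E_new = probs.p_l + probs.p_d * E * E + probs.p_t * E * ebar + probs.p_s * spec
        resid = float(np.max(np.abs(E_new - E)))
        E = E_new
        if resid < tol:
            return ExtinctionVector(E=E, residual=resid)
    raise RuntimeError(
        f"extinction fixed point did not converge (residual {resid:.3g})"
    )


@dataclass
class DPTables:
    """Converged DP state for one family; the sampler backtracks through it.

    ``pi[clade]`` is scaled so its largest entry is O(1); the log of the
    factor taken out is in ``logscale[clade]``.
    """

    ccp: CCPTable
    tree: SpeciesTree
    probs: EventProbs
    ext: ExtinctionVector
    pi: dict[int, np.ndarray]
    logscale: dict[int, float]
    loglik: float
    conditioning: str


def feedback_solver(tree: SpeciesTree, probs: EventProbs, ext: ExtinctionVector):
    """LU factorization of (I - M), where M is the within-clade feedback
    operator (speciation-loss, duplication with one extinct copy, transfer
    with one extinct copy).  M does not depend on the clade, so one
    factorization serves every clade of every family at a given rate
    vector."""
    from scipy.linalg import lu_factor

    N = tree.n_branches
    E = ext.E
    M = np.outer(probs.p_t * E, np.full(N, 1.0 / N))
    idx = np.arange(N)
    M[idx, idx] += 2.0 * probs.p_d * E + probs.p_t * ext.Ebar
    for e in np.nonzero(~tree.leaf_mask)[0]:
        fe, ge = tree.children(e)
        M[e, fe] += probs.p_s[e] * E[ge]
        M[e, ge] += probs.p_s[e] * E[fe]
    return lu_factor(np.eye(N) - M)


def compute_dp(
    ccp: CCPTable,
    tree: SpeciesTree,
    rates: DTLRates,
    model: str = "DTL",
    conditioning: str = "none",
    ext: ExtinctionVector | None = None,
    probs: EventProbs | None = None,
    solver=None,
) -> DPTables:
    from scipy.linalg import lu_solve

    if model == "DL":
        rates = rates.without_transfer()
    elif model != "DTL":
        raise ValueError(f"unknown model {model!r}")
    if conditioning not in ("none", "survival"):
        raise ValueError(f"unknown conditioning {conditioning!r}")
    if probs is None:
        probs = normalize_rates(rates, tree)
    if ext is None:
        ext = compute_extinction(probs, tree)
    if solver is None:
        solver = feedback_solver(tree, probs, ext)

    N = tree.n_branches
    inv_n = 1.0 / N
    int_idx = np.nonzero(~tree.leaf_mask)[0]
    f_int = tree.left[int_idx]
    g_int = tree.right[int_idx]
    p_s, p_d, p_t = probs.p_s, probs.p_d, probs.p_t
    p_s_int = p_s[int_idx]
    pd2 = 2.0 * p_d

    pi: dict[int, np.ndarray] = {}
    pibar: dict[int, float] = {}
    logscale: dict[int, float] = {}

    for clade in ccp.clades_by_size():
        splits = ccp.split_distribution(clade)
        if splits:
            target = max(logscale[c1] + logscale[c2] for c1, c2, _ in splits)
            A = np.zeros(N)
            for c1, c2, q in splits:
                w = q * math.exp(logscale[c1] + logscale[c2] - target)
                if w == 0.0:
                    continue
                p1, p2 = pi[c1], pi[c2]
                # ordered convention throughout: the two daughter copies of a
                # duplication are distinguishable, as in the forward process
                term = (pd2 * p1 + pibar[c1] * p_t) * p2 \
                    + (pibar[c2] * p_t) * p1
                term[int_idx] += p_s_int * (
                    p1[f_int] * p2[g_int] + p1[g_int] * p2[f_int])
                A += w * term
        else:
            target = 0.0
            A = np.zeros(N)
            sp = ccp.singleton_species(clade)
            leaf = tree.leaf_index.get(sp)
            if leaf is None:
                raise ValueError(f"species {sp!r} absent from tree")
            A[leaf] = p_s[leaf]

        cur = lu_solve(solver, A)
        np.maximum(cur, 0.0, out=cur)   # numerical guard

        m = float(cur.max())
        if m > 0.0:
            cur = cur / m
            target += math.log(m)
        pi[clade] = cur
        pibar[clade] = float(cur.sum()) * inv_n
        logscale[clade] = target

    gamma = ccp.gamma
    total = float(pi[gamma].mean())
    if total <= 0.0:
        ll = -math.inf
    else:
        ll = math.log(total) + logscale[gamma]
        if conditioning == "survival":
            surv = 1.0 - ext.Ebar
            if surv <= 0.0:
                raise ValueError("survival probability is zero; cannot condition")
            ll -= math.log(surv)
    return DPTables(
        ccp=ccp, tree=tree, probs=probs, ext=ext,
        pi=pi, logscale=logscale, loglik=ll, conditioning=conditioning,
    )


def family_loglik(
    ccp: CCPTable,
    tree: SpeciesTree,
    rates: DTLRates,
    model: str = "DTL",
    conditioning: str = "none",
    ext: ExtinctionVector | None = None,
) -> float:
    """Natural-log likelihood of one family's tree sample (via its CCPs)."""
    return compute_dp(
        ccp, tree, rates, model=model, conditioning=conditioning, ext=ext,
    ).loglik


def total_loglik(
    ccps: list[CCPTable],
    tree: SpeciesTree,
    rates: DTLRates,
    model: str = "DTL",
    conditioning: str = "none",
) -> float:
    """Sum of family log-likelihoods; the extinction vector and feedback
    factorization are computed once per rate vector and shared."""
    if not ccps:
        raise ValueError("no families")
    eff = rates.without_transfer() if model == "DL" else rates
    probs = normalize_rates(eff, tree)
    ext = compute_extinction(probs, tree)
    solver = feedback_solver(tree, probs, ext)
    out = 0.0
    for ccp in ccps:
        ll = compute_dp(
            ccp, tree, eff, model="DTL", conditioning=conditioning,
            ext=ext, probs=probs, solver=solver,
        ).loglik
        if ll == -math.inf:
            return -math.inf
        out += ll
    return out


def gene_tree_loglik(
    gene_tree: str | Node,
    gene_to_species: dict[str, str],
    tree: SpeciesTree,
    rates: DTLRates,
    conditioning: str = "none",
    inner_tol: float = 1e-10,
    max_inner: int = 100,
) -> float:
    """Reconciliation likelihood of one *fixed* rooted gene tree.

    Deliberately independent of the amalgamation DP (plain per-node scalar
    recursion, no CCP table): the two routes are compared in tests, and a
    one-tree CCP must reduce the amalgamated likelihood to this value.
    """
    if isinstance(gene_tree, str):
        gene_tree = parse_newick(gene_tree, expect_rooted=True)
    probs = normalize_rates(rates, tree)
    ext = compute_extinction(probs, tree)
    E = ext.E
    ebar = ext.Ebar
    N = tree.n_branches

    pi: dict[int, list[float]] = {}
    logscale: dict[int, float] = {}
    for u in gene_tree.postorder():
        base = [0.0] * N
        if u.is_leaf:
            sp = gene_to_species.get(u.name)
            if sp is None:
                raise ValueError(f"gene {u.name!r} has no species mapping")
            leaf = tree.leaf_index[sp]
            base[leaf] = probs.p_s[leaf]
            scale = 0.0
        else:
            c1, c2 = u.children
            u1, u2 = pi[id(c1)], pi[id(c2)]
            scale = logscale[id(c1)] + logscale[id(c2)]
            for e in range(N):
                acc = 2.0 * probs.p_d[e] * u1[e] * u2[e]
                m1 = sum(u1) / N
                m2 = sum(u2) / N
                acc += probs.p_t[e] * (m1 * u2[e] + m2 * u1[e])
                if not tree.is_leaf_branch(e):
                    fe, ge = tree.children(e)
                    acc += probs.p_s[e] * (u1[fe] * u2[ge] + u1[ge] * u2[fe])
                base[e] = acc
        cur = list(base)
        for _ in range(max_inner):
            mbar = sum(cur) / N
            nxt = [0.0] * N
            for e in range(N):
                v = base[e]
                if not tree.is_leaf_branch(e):
                    fe, ge = tree.children(e)
                    v += probs.p_s[e] * (cur[fe] * E[ge] + cur[ge] * E[fe])
                v += 2.0 * probs.p_d[e] * cur[e] * E[e]
                v += probs.p_t[e] * (mbar * E[e] + ebar * cur[e])
                nxt[e] = v
            delta = max(abs(a - b) for a, b in zip(nxt, cur))
            ref = max(max(nxt), 1e-300)
            cur = nxt
            if delta / ref < inner_tol:
                break
        m = max(cur)
        if m > 0.0:
            cur = [v / m for v in cur]
            scale += math.log(m)
        pi[id(u)] = cur
        logscale[id(u)] = scale

    total = sum(pi[id(gene_tree)]) / N
    if total <= 0.0:
        return -math.inf
    ll = math.log(total) + logscale[id(gene_tree)]
    if conditioning == "survival":
        ll -= math.log(1.0 - ebar)
    return ll


@dataclass
class OptimizeResult:
    rates: DTLRates
    loglik: float
    trace: list[tuple[DTLRates, float]]
    n_evals: int
    converged: bool


def optimize_rates(
    ccps: list[CCPTable],
    tree: SpeciesTree,
    model: str = "DTL",
    init: tuple[float, float, float] = (0.1, 0.1, 0.1),
    bounds: tuple[float, float] = RATE_BOUNDS,
    conditioning: str = "none",
    xatol: float = 1e-3,
    fatol: float = 1e-4,
    maxiter: int | None = None,
) -> OptimizeResult:
    """Maximum-likelihood DTL (or DL) rates by Nelder-Mead on log rates.

    Deterministic given the initial point.  In DL mode only (delta, lambda)
    are free and tau is pinned to 0.
    """
    from scipy.optimize import minimize

    if model not in ("DTL", "DL"):
        raise ValueError(f"unknown model {model!r}")
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    trace: list[tuple[DTLRates, float]] = []

    def unpack(x: np.ndarray) -> DTLRates:
        v = np.exp(np.clip(x, lo, hi))
        if model == "DL":
            return DTLRates(float(v[0]), 0.0, float(v[1]))
        return DTLRates(float(v[0]), float(v[1]), float(v[2]))

    def objective(x: np.ndarray) -> float:
        r = unpack(x)
        ll = total_loglik(ccps, tree, r, model=model,
                          conditioning=conditioning)
        trace.append((r, ll))
        return 1e300 if ll == -math.inf else -ll

    if model == "DL":
        x0 = np.log(np.clip([init[0], init[2]], bounds[0], bounds[1]))
    else:
        x0 = np.log(np.clip(list(init), bounds[0], bounds[1]))
    bnds = [(lo, hi)] * len(x0)
    res = minimize(
        objective, x0, method="Nelder-Mead", bounds=bnds,
        options={"xatol": xatol, "fatol": fatol,
                 **({"maxiter": maxiter} if maxiter else {})},
    )
    best = unpack(res.x)
    ll = -res.fun if res.fun < 1e299 else -math.inf
    if ll == -math.inf:
        raise RuntimeError(
            "likelihood is zero everywhere the optimizer looked; check that "
            "the families are reconcilable with this species tree and model"
        )
    return OptimizeResult(rates=best, loglik=ll, trace=trace,
                          n_evals=len(trace), converged=bool(res.success))
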