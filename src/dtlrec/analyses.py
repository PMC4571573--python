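"""Genome-dynamics statistics built on reconciliation samples.

Covers the downstream analyses of the reconciliation pipeline: event
ratios T/(T+D) (fraction of transfers among gene birth events) and
L/(T+D+L), rarefaction over random genome subsamples with saturating-
exponential extrapolation, ranking of transfer highways between branch
pairs, tandem-transfer adjacency enrichment against a permutation null,
pairwise synteny conservation of transferred vs non-transferred genes, and
rank-sum comparison of ancestral vs extant genome sizes.

All statistics are pure functions of their tabular inputs; every
randomized step (subsampling, permutation nulls) is seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from random import Random

import numpy as np
import pandas as pd

from .ccp import observe_sample
from .model import DTLRates, optimize_rates
from .phylo import GeneFamily, SpeciesTree, prune_family, prune_species_tree
from .reconcile import (EventSummary, Reconciliation, sample_reconciliations,
                        summarize_events, summarize_families)

__all__ = [
    "RatioPoint",
    "SaturationFit",
    "event_ratios",
    "rarefaction",
    "fit_saturation",
    "rank_highways",
    "transferred_calls",
    "tandem_enrichment",
    "tandem_analytic_null",
    "synteny_transfer_comparison",
    "compare_ancestral_extant",
    "ancestral_vs_extant_sizes",
]


@dataclass
class RatioPoint:
    """Event totals and ratios for one (subsample, replicate) analysis."""

    n_species: int
    replicate: int
    T: float
    D: float
    L: float

    @property
    def t_ratio(self) -> float | None:
        """T/(T+D): fraction of transfers among gene birth events."""
        return self.T / (self.T + self.D) if self.T + self.D > 0 else None

    @property
    def l_ratio(self) -> float | None:
        """L/(T+D+L): fraction of losses among all gene events."""
        tot = self.T + self.D + self.L
        return self.L / tot if tot > 0 else None


def event_ratios(summary: EventSummary, n_species: int = 0,
                 replicate: int = 0) -> RatioPoint:
    t = summary.totals()
    return RatioPoint(n_species=n_species, replicate=replicate,
                      T=t["T"], D=t["D"], L=t["L"])


def rarefaction(
    families: list[GeneFamily],
    tree: SpeciesTree,
    sizes: list[int],
    replicates: int,
    seed: int,
    n_samples: int = 20,
    model: str = "DTL",
    min_genes: int = 2,
    min_species: int = 3,
    opt_kwargs: dict | None = None,
) -> list[RatioPoint]:
    """Re-run the full inference on random genome subsamples.

    For every (size, replicate): draw a uniform subsample of species,
    prune species tree and families, rebuild CCPs, re-optimize rates,
    sample reconciliations and record event totals.  Deterministic given
    ``seed``; subsamples leaving fewer than ``min_species`` species (or no
    usable family) are skipped.
    """
    species = sorted(tree.leaf_index)
    out: list[RatioPoint] = []
    opt_kwargs = opt_kwargs or {}
    for size in sizes:
        if size > len(species):
            raise ValueError(f"subsample size {size} exceeds {len(species)} species")
        for rep in range(replicates):
            sub_seed = (seed * 1000003 + size * 1009 + rep) % (2**31)
            rng = Random(sub_seed)
            keep = set(rng.sample(species, size))
            if len(keep) < min_species:
                continue
            sub_tree = prune_species_tree(tree, keep)
            sub_fams = []
            for fam in families:
                pf = prune_family(fam, keep, min_genes=min_genes)
                if not pf.dropped:
                    sub_fams.append(pf)
            if not sub_fams:
                continue
            ccps = [observe_sample(f) for f in sub_fams]
            res = optimize_rates(ccps, sub_tree, model=model, **opt_kwargs)
            recs = [
                sample_reconciliations(
                    ccp, sub_tree, res.rates, n_samples=n_samples,
                    seed=(sub_seed + 7919 * i) % (2**31), model=model,
                )
                for i, ccp in enumerate(ccps)
            ]
            summary = summarize_families(recs)
            out.append(event_ratios(summary, n_species=size, replicate=rep))
    return out


@dataclass
class SaturationFit:
    """Parameters of y(n) = a - (a - y0) * exp(-n / s).

    ``a`` is the saturation asymptote (value at complete taxon sampling),
    ``y0`` the value extrapolated to zero species, ``s`` the scale in
    species counts.
    """

    a: float
    y0: float
    s: float
    se_a: float
    se_y0: float
    se_s: float
    rss: float


def _saturating(n, a, y0, s):
    return a - (a - y0) * np.exp(-n / s)


def fit_saturation(points: list[tuple[float, float]]) -> SaturationFit:
    """Least-squares Levenberg-Marquardt fit of the saturating exponential.

    Initialization: a = max y, y0 = min y, s = median n.  Standard errors
    come from the Jacobian at the optimum.  Constant data degenerate to
    a = y0 = c exactly.
    """
    from scipy.optimize import curve_fit

    n = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if len(set(n.tolist())) < 3:
        raise ValueError("need at least 3 distinct n values")
    if np.allclose(y, y[0]):
        return SaturationFit(a=float(y[0]), y0=float(y[0]),
                             s=float(np.median(n)), se_a=0.0, se_y0=0.0,
                             se_s=0.0, rss=0.0)
    p0 = (float(y.max()), float(y.min()), float(np.median(n)))
    try:
        popt, pcov = curve_fit(_saturating, n, y, p0=p0, method="lm",
                               maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"saturation fit did not converge: {exc}") from None
    resid = y - _saturating(n, *popt)
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(pcov))
    ses = np.where(np.isfinite(ses), ses, np.inf)
    return SaturationFit(
        a=float(popt[0]), y0=float(popt[1]), s=float(abs(popt[2])),
        se_a=float(ses[0]), se_y0=float(ses[1]), se_s=float(ses[2]),
        rss=float(resid @ resid),
    )


def rank_highways(
    summary: EventSummary, top_k: int | None = None, ordered: bool = True
) -> tuple[list[tuple[int, int, float]], np.ndarray]:
    """Branch pairs sorted by mean transfer count, descending.

    Returns (top pairs as (donor, recipient, count), the full decreasing
    count curve).  With ``ordered=False``, (donor, recipient) and
    (recipient, donor) counts are pooled.
    """
    counts = summary.pair_counts
    if not ordered:
        pooled: dict[tuple[int, int], float] = {}
        for (d, r), c in counts.items():
            key = (min(d, r), max(d, r))
            pooled[key] = pooled.get(key, 0.0) + c
        counts = pooled
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    curve = np.array([c for _, c in ranked])
    pairs = [(d, r, c) for (d, r), c in ranked]
    if top_k is not None:
        pairs = pairs[:top_k]
    return pairs, curve


def transferred_calls(
    recs_by_family: list[list[Reconciliation]],
    threshold: float = 0.5,
) -> dict[str, bool]:
    """Per-gene transfer call: a gene counts as transferred if the fraction
    of reconciliation samples in which its lineage arrived on its terminal
    branch by transfer exceeds ``threshold`` (default: majority rule)."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    out: dict[str, bool] = {}
    for recs in recs_by_family:
        tally: dict[str, int] = {}
        for rec in recs:
            for gene, hit in rec.transfer_arrivals().items():
                tally[gene] = tally.get(gene, 0) + (1 if hit else 0)
        for gene, k in tally.items():
            out[gene] = (k / len(recs)) > threshold
    return out


def tandem_enrichment(
    transferred: dict[str, set[str]],
    orders,
    permutations: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, dict], float | None]:
    """Adjacency enrichment of transferred genes along each genome.

    ``transferred`` maps species -> set of transferred gene names (from
    reconciliation-sample majority calls or from simulation truth).  For
    each genome with >= 2 transferred genes: f_obs is the fraction of
    transferred genes with at least one transferred chromosomal neighbour
    (circular adjacency); f_null the mean of the same statistic over
    ``permutations`` uniform random placements of the same number of
    transferred labels; fold = f_obs / f_null.  Returns per-genome results
    and the mean fold across usable genomes (None if no genome qualifies).
    """
    rng = Random(seed)
    per_genome: dict[str, dict] = {}
    folds = []
    for sp in sorted(orders.orders):
        genes = [g for _, g in orders.orders[sp]]
        n = len(genes)
        marked = [g in transferred.get(sp, ()) for g in genes]
        k = sum(marked)
        if k < 2 or n < 3:
            per_genome[sp] = {"n": n, "k": k, "note": "skipped: <2 transferred"}
            continue
        f_obs = _adjacent_fraction(marked)
        null_total = 0.0
        for _ in range(permutations):
            perm = [False] * n
            for i in rng.sample(range(n), k):
                perm[i] = True
            null_total += _adjacent_fraction(perm)
        f_null = null_total / permutations
        entry = {"n": n, "k": k, "f_obs": f_obs, "f_null": f_null,
                 "f_null_analytic": tandem_analytic_null(n, k)}
        if f_null > 0:
            entry["fold"] = f_obs / f_null
            folds.append(entry["fold"])
        else:
            entry["note"] = "null fraction is zero"
        per_genome[sp] = entry
    mean_fold = float(np.mean(folds)) if folds else None
    return per_genome, mean_fold


def _adjacent_fraction(marked: list[bool]) -> float:
    n = len(marked)
    hits = 0
    total = 0
    for i, m in enumerate(marked):
        if not m:
            continue
        total += 1
        if marked[(i - 1) % n] or marked[(i + 1) % n]:
            hits += 1
    return hits / total if total else 0.0


def tandem_analytic_null(n: int, k: int) -> float:
    """P(a transferred gene has a transferred neighbour) under uniform
    placement of k labels on a circular genome of n genes: one minus the
    hypergeometric chance that both neighbour slots miss the other k-1
    labels.  Cross-check for the permutation null."""
    if k < 2 or n < 3:
        return 0.0
    # both neighbours untransferred: choose k-1 positions among n-3 of n-1
    p_miss = math.comb(n - 3, k - 1) / math.comb(n - 1, k - 1) \
        if k - 1 <= n - 3 else 0.0
    return 1.0 - p_miss


def synteny_transfer_comparison(
    families: list[GeneFamily],
    recs_by_family: list[list[Reconciliation]],
    orders,
    species_pairs: list[tuple[str, str]],
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Pairwise synteny conservation of transferred vs non-transferred genes.

    For each species pair (X, Y) only families with exactly one gene in
    each of X and Y enter.  A family's gene pair is *transferred* when, in
    a majority (> ``threshold``) of reconciliation samples, at least one
    transfer lies on the gene-tree path between the two genes; synteny is
    *conserved* when some neighbour of the X-gene belongs to a family
    whose own X/Y single-copy orthologue pair places its Y-gene next to
    the Y-orthologue.
    """
    rec_index = {recs[0].family_id: recs for recs in recs_by_family if recs}
    rows = []
    for x_sp, y_sp in species_pairs:
        # single-copy families for this pair
        pair_fams: dict[str, tuple[str, str]] = {}
        for fam in families:
            gx = [g for g in fam.genes if fam.gene_to_species[g] == x_sp]
            gy = [g for g in fam.genes if fam.gene_to_species[g] == y_sp]
            if len(gx) == 1 and len(gy) == 1:
                pair_fams[fam.family_id] = (gx[0], gy[0])
        if not pair_fams:
            rows.append({"species_x": x_sp, "species_y": y_sp, "n_families": 0,
                         "note": "no single-copy families"})
            continue
        x_pos = orders.position_of(x_sp)
        y_pos = orders.position_of(y_sp)
        fam_of_gene = {g: fid for fid, (gx, gy) in pair_fams.items()
                       for g in (gx, gy)}
        y_of_fam = {fid: gy for fid, (_, gy) in pair_fams.items()}

        def conserved(fid: str) -> bool:
            gx, gy = pair_fams[fid]
            if gx not in x_pos or gy not in y_pos:
                return False
            y_neigh = {g for _, g in orders.neighbours(y_sp, y_pos[gy])}
            for _, ng in orders.neighbours(x_sp, x_pos[gx]):
                nfid = fam_of_gene.get(ng)
                if nfid is None or nfid == fid:
                    continue
                if y_of_fam[nfid] in y_neigh:
                    return True
            return False

        stats = {True: [0, 0], False: [0, 0]}   # transferred -> [conserved, total]
        for fid, (gx, gy) in pair_fams.items():
            recs = rec_index.get(fid)
            if not recs:
                continue
            hits = sum(1 for rec in recs if rec.path_transferred(gx, gy))
            is_transferred = (hits / len(recs)) > threshold
            stats[is_transferred][1] += 1
            if conserved(fid):
                stats[is_transferred][0] += 1
        rows.append({
            "species_x": x_sp, "species_y": y_sp,
            "n_families": len(pair_fams),
            "n_transferred": stats[True][1],
            "n_nontransferred": stats[False][1],
            "conserved_transferred":
                stats[True][0] / stats[True][1] if stats[True][1] else np.nan,
            "conserved_nontransferred":
                stats[False][0] / stats[False][1] if stats[False][1] else np.nan,
        })
    return pd.DataFrame(rows)


def ancestral_vs_extant_sizes(
    copy_numbers: np.ndarray, tree: SpeciesTree
) -> tuple[np.ndarray, np.ndarray]:
    """Split per-branch genome sizes into ancestral (internal branches,
    root stem included) and extant (leaf branches)."""
    leaf = tree.leaf_mask
    return copy_numbers[~leaf], copy_numbers[leaf]


def compare_ancestral_extant(
    ancestral: np.ndarray, extant: np.ndarray, mode: str = "two-sided"
) -> dict:
    """Rank-sum (Mann-Whitney/Wilcoxon) comparison of ancestral and extant
    genome-size distributions.

    ``mode="two-sided"`` asks whether ancestral sizes fall within the
    extant distribution (the transfer-aware expectation); ``mode="greater"``
    is the one-sided test for systematic ancestral inflation (the
    duplication-loss-only pathology)."""
    from scipy.stats import mannwhitneyu

    ancestral = np.asarray(ancestral, dtype=float)
    extant = np.asarray(extant, dtype=float)
    if ancestral.size == 0 or extant.size == 0:
        raise ValueError("both size distributions must be non-empty")
    if mode not in ("two-sided", "greater"):
        raise ValueError(f"unknown mode {mode!r}")
    if np.all(ancestral == ancestral[0]) and np.all(extant == ancestral[0]):
        stat, p = ancestral.size * extant.size / 2.0, 1.0
    else:
        res = mannwhitneyu(ancestral, extant, alternative=mode)
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "statistic": stat,
        "p_value": p,
        "mode": mode,
        "n_ancestral": int(ancestral.size),
        "n_extant": int(extant.size),
        "median_ancestral": float(np.median(ancestral)),
        "median_extant": float(np.median(extant)),
    }
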