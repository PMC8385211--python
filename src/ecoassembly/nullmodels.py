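"""Phylogenetic and taxonomic null models for community assembly inference.

The inference follows the now-standard two-step framework for partitioning
pairwise community turnover into ecological processes:

1. beta-mean-nearest-taxon distance (betaMNTD) between every sample pair,
   compared against a "taxa shuffle" null (tip labels permuted on the
   cophenetic matrix, community composition untouched) to give the
   beta-nearest-taxon index, betaNTI = (obs - null mean) / null sd.
   betaNTI > +2 -> variable selection; betaNTI < -2 -> homogeneous
   selection.
2. For pairs with |betaNTI| < 2, a Bray-Curtis-based Raup-Crick null
   (RC_bray): null communities preserve each sample's observed richness
   and read total, drawing species with probability proportional to their
   metacommunity occupancy frequency and assigning reads proportionally
   to metacommunity relative abundance.  RC > +0.95 -> dispersal
   limitation; RC < -0.95 -> homogenizing dispersal; the remainder is
   "undominated" (weak selection, weak dispersal, diversification, drift).

A Mantel correlogram of between-OTU niche distance against phylogenetic
distance (short-distance classes) verifies the phylogenetic signal that
makes nearest-taxon metrics ecologically interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    CommunityTable,
    DistanceMatrix,
    PhyloTree,
    ValidationError,
    cophenetic_matrix,
    match_tree_to_table,
    relative_abundance,
)
from .stats import bray_curtis

__all__ = [
    "PROCESSES",
    "beta_mntd",
    "taxa_shuffle",
    "beta_nti_matrix",
    "rc_bray_matrix",
    "assign_process",
    "partition_processes",
    "niche_optima",
    "phylo_signal_correlogram",
    "Correlogram",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_CUT = 2.0
RC_CUT = 0.95


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI
# ---------------------------------------------------------------------------


def beta_mntd(fa, fb, D: DistanceMatrix, weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance.

    ``fa`` and ``fb`` are abundance vectors aligned to ``D.labels``.  Each
    present OTU contributes the phylogenetic distance to its nearest
    relative in the other community (a shared OTU contributes 0), averaged
    with relative-abundance weights (``weighted``) or uniformly, and the
    two directions are averaged.
    """
    fa = np.asarray(fa, dtype=float)
    fb = np.asarray(fb, dtype=float)
    n = len(D.labels)
    if fa.shape != (n,) or fb.shape != (n,):
        raise ValidationError("abundance vectors must align with D labels")
    ia = np.flatnonzero(fa > 0)
    ib = np.flatnonzero(fb > 0)
    if len(ia) == 0 or len(ib) == 0:
        raise ValidationError("empty community")
    min_a_to_b = D.values[np.ix_(ia, ib)].min(axis=1)
    min_b_to_a = D.values[np.ix_(ib, ia)].min(axis=1)
    if weighted:
        wa = fa[ia] / fa[ia].sum()
        wb = fb[ib] / fb[ib].sum()
    else:
        wa = np.full(len(ia), 1.0 / len(ia))
        wb = np.full(len(ib), 1.0 / len(ib))
    return float(0.5 * ((wa * min_a_to_b).sum() + (wb * min_b_to_a).sum()))


def taxa_shuffle(D: DistanceMatrix, seed: int) -> DistanceMatrix:
    """One null draw: permute tip identities on the distance matrix.

    Rows and columns are permuted jointly, preserving the zero diagonal
    and the off-diagonal distance multiset while decoupling tip identity
    from phylogenetic position.
    """
    rng = np.random.default_rng(seed)
    p = rng.permutation(len(D.labels))
    return DistanceMatrix(list(D.labels), D.values[np.ix_(p, p)])


def _all_pair_beta_mntd(D: np.ndarray, W: np.ndarray, present: list[np.ndarray]) -> np.ndarray:
    """betaMNTD for every sample pair at once.

    ``W`` is the (OTU x sample) weight matrix (zero where absent, columns
    summing to 1), ``present`` the per-sample index arrays.  For sample b,
    ``M[:, b]`` holds each OTU's distance to its nearest member of b, so
    sum_i W[i, a] M[i, b] is one direction of the pair (a, b).
    """
    n_otus, n_samples = W.shape
    M = np.empty((n_otus, n_samples))
    for s in range(n_samples):
        M[:, s] = D[:, present[s]].min(axis=1)
    T = W.T @ M
    return 0.5 * (T + T.T)


def _weights(table: CommunityTable, weighted: bool) -> tuple[np.ndarray, list[np.ndarray]]:
    counts = table.counts.astype(float)
    present = [np.flatnonzero(counts[:, s] > 0) for s in range(counts.shape[1])]
    empty = [table.sample_ids[s] for s, p in enumerate(present) if len(p) == 0]
    if empty:
        raise ValidationError(f"empty samples: {empty}")
    if weighted:
        W = counts / counts.sum(axis=0)
    else:
        W = np.zeros_like(counts)
        for s, p in enumerate(present):
            W[p, s] = 1.0 / len(p)
    return W, present


def beta_nti_matrix(
    table: CommunityTable,
    tree: PhyloTree,
    reps: int = 999,
    weighted: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """betaNTI for every sample pair under the taxa-shuffle null.

    Returns a tidy DataFrame with one row per unordered sample pair:
    ``sample_a, sample_b, beta_mntd_obs, null_mean, null_sd, beta_nti``.
    A degenerate null (sd = 0, e.g. identical samples) leaves betaNTI NaN;
    such pairs are reported but excluded from process summaries.
    """
    if reps < 2:
        raise ValidationError("need at least 2 null replicates")
    tree = match_tree_to_table(tree, table)
    D = cophenetic_matrix(tree).reorder(table.otu_ids).values
    W, present = _weights(table, weighted)
    n_samples = len(table.sample_ids)

    obs = _all_pair_beta_mntd(D, W, present)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(obs)
    null_sq = np.zeros_like(obs)
    for _ in range(reps):
        p = rng.permutation(D.shape[0])
        Dp = D[np.ix_(p, p)]
        b = _all_pair_beta_mntd(Dp, W, present)
        null_sum += b
        null_sq += b * b
    mean = null_sum / reps
    var = (null_sq - reps * mean * mean) / (reps - 1)
    sd = np.sqrt(np.maximum(var, 0.0))

    rows = []
    for a in range(n_samples):
        for b in range(a + 1, n_samples):
            s = sd[a, b]
            bnti = (obs[a, b] - mean[a, b]) / s if s > 1e-12 else np.nan
            rows.append(
                (
                    table.sample_ids[a],
                    table.sample_ids[b],
                    obs[a, b],
                    mean[a, b],
                    s,
                    bnti,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["sample_a", "sample_b", "beta_mntd_obs", "null_mean", "null_sd", "beta_nti"],
    )


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis) null
# ---------------------------------------------------------------------------


def _null_selections(rng, occ_freq, richness, reps):
    """Species draws for all replicates at once: ``richness`` species per
    replicate, probability proportional to occupancy frequency, without
    replacement (Efraimidis-Spirakis weighted-key sampling)."""
    keys = np.log(rng.random((reps, len(occ_freq)))) / occ_freq
    return np.argpartition(keys, -richness, axis=1)[:, -richness:]


def rc_bray_matrix(
    table: CommunityTable,
    reps: int = 999,
    seed: int = 0,
    pairs: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Raup-Crick metric on Bray-Curtis for every (or selected) sample pair.

    For each pair, ``reps`` null community pairs are simulated from the
    metacommunity (all samples of ``table``): each null community draws
    the observed number of species with probability proportional to
    occupancy frequency, then distributes the observed read total with
    probability proportional to metacommunity relative abundance.  The
    observed Bray-Curtis is located in the null distribution and rescaled:
    ``RC = 2 ((#{null < obs} + 0.5 #{null == obs}) / reps) - 1``, in
    [-1, 1].

    Null draws are keyed by (seed, pair), so RC(a, b) = RC(b, a) and the
    result is independent of iteration order.
    """
    counts = table.counts.astype(float)
    n_otus, n_samples = counts.shape
    if n_samples < 2:
        raise ValidationError("need at least 2 samples")
    occupancy = (counts > 0).sum(axis=1).astype(float)
    pool = np.flatnonzero(occupancy > 0)
    occ_freq = occupancy[pool]
    totals_by_otu = counts.sum(axis=1)
    rel_abund = totals_by_otu[pool] / totals_by_otu[pool].sum()
    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0).astype(int)

    if pairs is None:
        pairs = [(a, b) for a in range(n_samples) for b in range(a + 1, n_samples)]
    buf_a = np.zeros(n_otus)
    buf_b = np.zeros(n_otus)
    rows = []
    for a, b in pairs:
        a, b = min(a, b), max(a, b)
        rng = np.random.default_rng([seed, a, b])
        obs = bray_curtis(counts[:, a], counts[:, b])
        sel_a = _null_selections(rng, occ_freq, int(richness[a]), reps)
        sel_b = _null_selections(rng, occ_freq, int(richness[b]), reps)
        less = equal = 0
        for r in range(reps):
            pa = rel_abund[sel_a[r]]
            pb = rel_abund[sel_b[r]]
            buf_a[:] = 0.0
            buf_a[pool[sel_a[r]]] = rng.multinomial(int(totals[a]), pa / pa.sum())
            buf_b[:] = 0.0
            buf_b[pool[sel_b[r]]] = rng.multinomial(int(totals[b]), pb / pb.sum())
            bc = bray_curtis(buf_a, buf_b)
            if np.isclose(bc, obs, atol=1e-12):
                equal += 1
            elif bc < obs:
                less += 1
        rc = 2.0 * ((less + 0.5 * equal) / reps) - 1.0
        rows.append((table.sample_ids[a], table.sample_ids[b], obs, rc))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "bray_curtis_obs", "rc_bray"])


# ---------------------------------------------------------------------------
# process partition
# ---------------------------------------------------------------------------


def assign_process(beta_nti: float, rc_bray: float) -> str:
    """Map one pair's (betaNTI, RC_bray) to its ecological process."""
    if np.isnan(beta_nti):
        return "undefined"
    if beta_nti > BNTI_CUT:
        return "variable_selection"
    if beta_nti < -BNTI_CUT:
        return "homogeneous_selection"
    if np.isnan(rc_bray):
        return "undefined"
    if rc_bray > RC_CUT:
        return "dispersal_limitation"
    if rc_bray < -RC_CUT:
        return "homogenizing_dispersal"
    return "undominated"


def partition_processes(
    bnti: pd.DataFrame,
    rc: pd.DataFrame,
    sample_groups: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign a process to every pair and summarise fractions per grouping.

    Returns ``(pairs, summary)``: the merged per-pair table with a
    ``process`` column, and a summary with one row per grouping ("all",
    "within:<group>", "between") giving the fraction of defined pairs
    assigned to each process (fractions sum to 1) plus the count of
    undefined pairs.
    """
    key = ["sample_a", "sample_b"]
    pairs = bnti.merge(rc, on=key, how="left")
    pairs["process"] = [
        assign_process(b, r) for b, r in zip(pairs["beta_nti"], pairs["rc_bray"])
    ]

    def summarise(sub: pd.DataFrame, label: str):
        defined = sub[sub["process"] != "undefined"]
        n = len(defined)
        row = {"grouping": label, "n_pairs": n,
               "n_undefined": int((sub["process"] == "undefined").sum())}
        for proc in PROCESSES:
            row[proc] = (defined["process"] == proc).mean() if n else np.nan
        return row

    records = [summarise(pairs, "all")]
    if sample_groups is not None:
        ga = pairs["sample_a"].map(sample_groups)
        gb = pairs["sample_b"].map(sample_groups)
        for g in sorted(set(sample_groups.values())):
            records.append(summarise(pairs[(ga == g) & (gb == g)], f"within:{g}"))
        records.append(summarise(pairs[ga != gb], "between"))
    return pairs, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# niche optima and phylogenetic signal
# ---------------------------------------------------------------------------


def niche_optima(table: CommunityTable, env_var: str) -> pd.Series:
    """Abundance-weighted mean environment: each OTU's habitat optimum.

    ``optimum_i = sum_s RA_is E_s / sum_s RA_is``; OTUs absent everywhere
    are excluded.
    """
    if table.env is None or env_var not in table.env.columns:
        raise ValidationError(f"environmental variable {env_var!r} not available")
    env = table.env.loc[table.sample_ids, env_var].to_numpy(dtype=float)
    ra = relative_abundance(table).values
    weight_sums = ra.sum(axis=1)
    present = weight_sums > 0
    optima = (ra[present] @ env) / weight_sums[present]
    return pd.Series(optima, index=pd.Index(np.asarray(table.otu_ids)[present],
                                            name="otu_id"), name=env_var)


@dataclass
class Correlogram:
    """Per-distance-class Mantel correlation of niche vs phylogenetic distance."""

    class_bounds: list[tuple[float, float]]
    mantel_r: list[float]
    p_values: list[float]
    n_pairs: list[int]
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d_min": [b[0] for b in self.class_bounds],
                "d_max": [b[1] for b in self.class_bounds],
                "mantel_r": self.mantel_r,
                "p_value": self.p_values,
                "n_pairs": self.n_pairs,
            }
        )


def phylo_signal_correlogram(
    optima: pd.Series,
    D: DistanceMatrix,
    n_classes: int = 5,
    permutations: int = 999,
    seed: int = 0,
) -> Correlogram:
    """Phylogenetic signal in niche optima across distance classes.

    Pairs are binned into ``n_classes`` equal-frequency phylogenetic
    distance classes; within each class the Pearson correlation between
    phylogenetic distance and niche distance |opt_i - opt_j| is tested by
    permuting optima across tips (class membership stays fixed).  Brownian
    trait evolution produces positive, significant r in the shortest
    class.  One class reduces to a plain Mantel test on all pairs.
    """
    otus = [o for o in D.labels if o in set(optima.index)]
    if len(otus) < 10:
        raise ValidationError("need at least 10 OTUs with optima")
    Dm = D.reorder(otus).values
    o = optima.loc[otus].to_numpy(dtype=float)
    n = len(otus)
    iu, ju = np.triu_indices(n, k=1)
    pd_flat = Dm[iu, ju]
    if np.ptp(o) == 0:
        bounds = [(float(pd_flat.min()), float(pd_flat.max()))] * n_classes
        return Correlogram(bounds, [np.nan] * n_classes, [np.nan] * n_classes,
                           [0] * n_classes, degenerate=True)

    qs = np.quantile(pd_flat, np.linspace(0, 1, n_classes + 1))
    cls = np.clip(np.searchsorted(qs, pd_flat, side="right") - 1, 0, n_classes - 1)

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(n) for _ in range(permutations)]
    nd_flat = np.abs(o[iu] - o[ju])

    rs, ps, bounds, npairs = [], [], [], []
    for k in range(n_classes):
        mask = cls == k
        xi, xj = iu[mask], ju[mask]
        x = pd_flat[mask]
        y = nd_flat[mask]
        bounds.append((float(qs[k]), float(qs[k + 1])))
        npairs.append(int(mask.sum()))
        if mask.sum() < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rs.append(np.nan)
            ps.append(np.nan)
            continue
        obs = np.corrcoef(x, y)[0, 1]
        exceed = 0
        for p in perms:
            yp = np.abs(o[p][xi] - o[p][xj])
            if np.ptp(yp) == 0:
                continue
            if np.corrcoef(x, yp)[0, 1] >= obs - 1e-12:
                exceed += 1
        rs.append(float(obs))
        ps.append((1 + exceed) / (permutations + 1))
    return Correlogram(bounds, rs, ps, npairs)
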