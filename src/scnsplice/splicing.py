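"""Junction clustering and Dirichlet-multinomial differential splicing.

Junctions sharing a donor or acceptor coordinate are grouped into splice
clusters (connected components, with low-support junctions pruned
iteratively).  Within a cluster, per-sample junction counts
y_s ~ DirichletMultinomial(n_s, alpha * p_s) model overdispersed usage
proportions; group differences (e.g. prenatal vs postnatal) are tested by
a likelihood-ratio between

    null:        p_sj = softmax(mu_j)
    alternative: p_sj = softmax(mu_j + x_s * beta_j),   x_s in {0, 1}

with mu and beta sum-to-zero for identifiability and the concentration
alpha shared.  The LRT statistic is referred to chi-square with J-1
degrees of freedom; an empirical permutation p-value is available for
small cohorts.

Sashimi-style summaries report each junction's share of all split reads
in a genomic window, per group, and a mutual-exclusivity score checks
that reads support flank<->A or flank<->N junctions rather than A<->N;
double-skip (flank->flank) reads are tallied separately because skipping
both exon copies is a real isoform for the 18A/18N pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .annotation import CONSISTENT, CountingBin, MxePair
from .counting import JunctionTable


@dataclass
class SpliceCluster:
    cluster_id: str
    chrom: str
    strand: str
    junctions: list[tuple]  # full (chrom, donor_end, acceptor_start, strand) keys
    counts: pd.DataFrame  # samples x junctions

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(j[1] for j in self.junctions),
            max(j[2] for j in self.junctions),
        )


def cluster_junctions(
    junctions: JunctionTable,
    min_cluster_reads: int = 30,
    min_junction_fraction: float = 0.001,
) -> tuple[list[SpliceCluster], list[tuple[tuple, str]]]:
    """Group junctions into splice clusters; returns (clusters, dropped).

    Components are formed over shared donor/acceptor coordinates (same
    chromosome and strand).  Junctions carrying less than
    ``min_junction_fraction`` of their component's reads are pruned and
    components recomputed until stable.  Components with fewer than two
    junctions or fewer than ``min_cluster_reads`` pooled reads are
    dropped, with the reason recorded so silent failures (e.g. a pair too
    weakly expressed to cluster) stay observable.
    """
    totals = junctions.counts.sum(axis=1)
    active = set(junctions.counts.index)
    dropped: list[tuple[tuple, str]] = []

    def components(keys):
        g = nx.Graph()
        g.add_nodes_from(keys)
        by_coord: dict[tuple, list] = {}
        for key in keys:
            chrom, donor, acceptor, strand = key
            by_coord.setdefault((chrom, strand, "d", donor), []).append(key)
            by_coord.setdefault((chrom, strand, "a", acceptor), []).append(key)
        for members in by_coord.values():
            for other in members[1:]:
                g.add_edge(members[0], other)
        return [sorted(c) for c in nx.connected_components(g)]

    while True:
        pruned = False
        for comp in components(active):
            ctot = sum(totals[k] for k in comp)
            if ctot <= 0:
                continue
            for k in comp:
                if totals[k] < min_junction_fraction * ctot:
                    active.discard(k)
                    dropped.append((k, "below min_junction_fraction"))
                    pruned = True
        if not pruned:
            break

    clusters: list[SpliceCluster] = []
    comps = sorted(components(active), key=lambda c: (c[0][0], c[0][1], c[0][2]))
    i = 0
    for comp in comps:
        ctot = int(sum(totals[k] for k in comp))
        if len(comp) < 2:
            dropped.append((comp[0], "singleton component"))
            continue
        if ctot < min_cluster_reads:
            for k in comp:
                dropped.append((k, f"cluster total {ctot} < min_cluster_reads"))
            continue
        i += 1
        clusters.append(
            SpliceCluster(
                cluster_id=f"clu_{i}",
                chrom=comp[0][0],
                strand=comp[0][3],
                junctions=list(comp),
                counts=junctions.counts.loc[comp].T.copy(),
            )
        )
    return clusters, dropped


def dm_loglik(y: np.ndarray, p: np.ndarray, alpha: float) -> float:
    """Dirichlet-multinomial log-likelihood (without multinomial coefficient).

    sum_s [ lnG(a) - lnG(n_s + a) + sum_j ( lnG(y_sj + a p_sj) - lnG(a p_sj) ) ]
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    p = np.broadcast_to(np.atleast_2d(np.asarray(p, dtype=float)), y.shape)
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if np.any(p <= 0) or not np.allclose(p.sum(axis=1), 1.0):
        raise ValueError("rows of p must be positive and sum to 1")
    n = y.sum(axis=1)
    a = alpha * p
    ll = np.sum(special.gammaln(alpha) - special.gammaln(n + alpha))
    ll += np.sum(special.gammaln(y + a) - special.gammaln(a))
    return float(ll)


@dataclass
class DmGlmResult:
    null_loglik: float
    alt_loglik: float
    lrt_statistic: float
    df: int
    p_value: float
    beta: np.ndarray  # per-junction logit effects, sum to zero
    alpha: float
    n_samples: int
    dropped_junctions: list = field(default_factory=list)
    permutation_p: float | None = None


def _softmax(eta: np.ndarray) -> np.ndarray:
    m = eta.max(axis=-1, keepdims=True)
    e = np.exp(eta - m)
    return e / e.sum(axis=-1, keepdims=True)


def _unpack(params: np.ndarray, J: int, fit_beta: bool):
    mu_free = params[: J - 1]
    mu = np.append(mu_free, -mu_free.sum())
    if fit_beta:
        beta_free = params[J - 1 : 2 * (J - 1)]
        beta = np.append(beta_free, -beta_free.sum())
    else:
        beta = np.zeros(J)
    log_alpha = params[-1]
    return mu, beta, log_alpha


def _dm_negloglik_grad(params, y, x, fit_beta):
    S, J = y.shape
    mu, beta, log_alpha = _unpack(params, J, fit_beta)
    alpha = np.exp(log_alpha)
    eta = mu[None, :] + x[:, None] * beta[None, :]
    p = _softmax(eta)
    a = alpha * p
    n = y.sum(axis=1)

    ll = np.sum(special.gammaln(alpha) - special.gammaln(n + alpha))
    ll += np.sum(special.gammaln(y + a) - special.gammaln(a))

    d = special.digamma(y + a) - special.digamma(a)  # dL/da_sj
    # gradient through the softmax: g_sk = p_sk (alpha d_sk - sum_j alpha d_sj p_sj)
    ad = alpha * d
    g = p * (ad - np.sum(ad * p, axis=1, keepdims=True))
    grad_mu_free = (g[:, :-1] - g[:, -1:]).sum(axis=0)
    grad_log_alpha = alpha * (
        np.sum(special.digamma(alpha) - special.digamma(n + alpha)) + np.sum(d * p)
    )
    if fit_beta:
        gb = g * x[:, None]
        grad_beta_free = (gb[:, :-1] - gb[:, -1:]).sum(axis=0)
        grad = np.concatenate([grad_mu_free, grad_beta_free, [grad_log_alpha]])
    else:
        grad = np.concatenate([grad_mu_free, [grad_log_alpha]])
    return -ll, -grad


def _fit_dm(y, x, fit_beta, starts, tol=1e-8):
    best = None
    for p0 in starts:
        res = optimize.minimize(
            _dm_negloglik_grad,
            p0,
            args=(y, x, fit_beta),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": tol, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def dm_glm_test(
    counts: pd.DataFrame,
    group: pd.Series,
    n_restarts: int = 2,
    jitter_sd: float = 0.25,
    permutations: int = 0,
    seed: int = 0,
) -> DmGlmResult:
    """Dirichlet-multinomial GLM likelihood-ratio test for one cluster.

    ``counts`` is samples x junctions; ``group`` a binary per-sample
    label (coerced to 0/1 by sorted level order).  Junctions with zero
    reads in all samples are dropped with a warning; samples with zero
    cluster reads are ignored.  ``permutations > 0`` adds an empirical
    p-value from label permutations for small cohorts.
    """
    group = group.reindex(counts.index)
    levels = sorted(pd.unique(group.dropna()))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    x_all = (group == levels[1]).to_numpy(dtype=float)

    y_all = counts.to_numpy(dtype=float)
    dropped = [c for c, tot in zip(counts.columns, y_all.sum(axis=0)) if tot == 0]
    if dropped:
        warnings.warn(f"dropping all-zero junction(s): {dropped}", stacklevel=2)
        keep_j = y_all.sum(axis=0) > 0
        y_all = y_all[:, keep_j]
    keep_s = y_all.sum(axis=1) > 0
    y, x = y_all[keep_s], x_all[keep_s]
    S, J = y.shape
    if J < 2:
        raise ValueError("cluster needs at least 2 junctions with reads")
    for lv in (0.0, 1.0):
        if (x == lv).sum() < 2:
            raise ValueError("both groups need >= 2 samples with cluster reads")

    rng = np.random.default_rng(seed)
    pooled = y.sum(axis=0) + 0.5
    mu0 = np.log(pooled / pooled.sum())
    mu0 = mu0 - mu0.mean()
    base_null = np.concatenate([mu0[:-1], [np.log(10.0)]])
    null_starts = [base_null] + [
        base_null + rng.normal(0, jitter_sd, base_null.shape) for _ in range(n_restarts)
    ]
    null_fit = _fit_dm(y, x, fit_beta=False, starts=null_starts)
    mu_hat, _, la_hat = _unpack(null_fit.x, J, fit_beta=False)

    # group-wise moment initialization for the alternative
    p1 = y[x == 1].sum(axis=0) + 0.5
    p0 = y[x == 0].sum(axis=0) + 0.5
    m0 = np.log(p0 / p0.sum())
    b0 = np.log(p1 / p1.sum()) - m0
    m0, b0 = m0 - m0.mean(), b0 - b0.mean()
    alt_base = np.concatenate([mu_hat[:-1], np.zeros(J - 1), [la_hat]])
    alt_moment = np.concatenate([m0[:-1], b0[:-1], [la_hat]])
    alt_starts = [alt_base, alt_moment] + [
        alt_base + rng.normal(0, jitter_sd, alt_base.shape) for _ in range(n_restarts)
    ]
    alt_fit = _fit_dm(y, x, fit_beta=True, starts=alt_starts)

    null_ll, alt_ll = -null_fit.fun, -alt_fit.fun
    lrt = max(0.0, 2.0 * (alt_ll - null_ll))
    df = J - 1
    p = float(stats.chi2.sf(lrt, df))
    _, beta_hat, la_alt = _unpack(alt_fit.x, J, fit_beta=True)

    perm_p = None
    if permutations > 0:
        perm_rng = np.random.default_rng(seed + 1)
        hits = 0
        for _ in range(permutations):
            xp = perm_rng.permutation(x)
            nf = _fit_dm(y, xp, fit_beta=False, starts=[null_fit.x])
            af = _fit_dm(
                y, xp, fit_beta=True,
                starts=[np.concatenate([null_fit.x[:-1], np.zeros(J - 1), [null_fit.x[-1]]])],
            )
            if max(0.0, 2.0 * (nf.fun - af.fun)) >= lrt:
                hits += 1
        perm_p = (hits + 1) / (permutations + 1)

    return DmGlmResult(
        null_loglik=float(null_ll),
        alt_loglik=float(alt_ll),
        lrt_statistic=float(lrt),
        df=df,
        p_value=p,
        beta=beta_hat,
        alpha=float(np.exp(la_alt)),
        n_samples=S,
        dropped_junctions=dropped,
        permutation_p=perm_p,
    )


@dataclass
class SashimiSummary:
    window: tuple[str, int, int]
    proportions: dict[str, pd.Series]  # group -> per-junction proportion
    pooled_counts: dict[str, pd.Series]


def sashimi_summary(
    junctions: JunctionTable,
    group: pd.Series,
    window: tuple[str, int, int],
) -> SashimiSummary:
    """Per-group junction proportions over pooled split reads in a window."""
    chrom, start, end = window
    idx = [
        k
        for k in junctions.counts.index
        if k[0] == chrom and k[1] >= start and k[2] <= end
    ]
    if not idx:
        raise ValueError(f"no junctions in window {chrom}:{start}-{end}")
    sub = junctions.counts.loc[idx]
    props: dict[str, pd.Series] = {}
    pooled: dict[str, pd.Series] = {}
    for level in sorted(pd.unique(group.dropna())):
        samples = [s for s in sub.columns if group.get(s) == level]
        tot = sub[samples].sum(axis=1).astype(float)
        pooled[str(level)] = tot
        props[str(level)] = tot / tot.sum() if tot.sum() > 0 else tot
    return SashimiSummary(window=window, proportions=props, pooled_counts=pooled)


@dataclass
class MxeConsistency:
    category_counts: dict[str, int]
    consistent_fraction: float
    skip_fraction: float
    cross_fraction: float
    total_reads: int


def mxe_window_geometry(
    bins: list[CountingBin], pair: MxePair, chrom: str | None = None
) -> dict:
    """Locate the A/N exons and their nearest consistent flanks.

    Pass ``chrom`` whenever junctions from several chromosomes may share
    coordinates; it is stored in the geometry and used to restrict the
    window.
    """
    by_id = {b.bin_id: b for b in bins if b.gene_id == pair.gene_id}
    a, n = by_id[pair.bin_a], by_id[pair.bin_n]
    first = min(a, n, key=lambda b: b.start)
    last = max(a, n, key=lambda b: b.start)
    up = [b for b in bins if b.bin_class == CONSISTENT and b.end <= first.start]
    down = [b for b in bins if b.bin_class == CONSISTENT and b.start >= last.end]
    if not up or not down:
        raise ValueError("pair lacks consistent flanking bins")
    flank_up = max(up, key=lambda b: b.end)
    flank_down = min(down, key=lambda b: b.start)
    return {
        "flank_up": (flank_up.start, flank_up.end),
        "exon_a": (a.start, a.end),
        "exon_n": (n.start, n.end),
        "flank_down": (flank_down.start, flank_down.end),
        "chrom": chrom,
    }


def mxe_consistency(
    junctions: JunctionTable,
    geometry: dict[str, tuple[int, int]],
    samples: list[str] | None = None,
) -> MxeConsistency:
    """Fraction of split reads consistent with mutually exclusive usage.

    Consistent: flank->A, A->flank, flank->N, N->flank.  Cross (A<->N)
    reads violate mutual exclusivity.  Double-skip (flank->flank) is
    reported separately as a real isoform; the consistency denominator is
    consistent + cross reads.
    """
    u = geometry["flank_up"]
    a = geometry["exon_a"]
    n = geometry["exon_n"]
    d = geometry["flank_down"]
    first, second = (a, n) if a[0] < n[0] else (n, a)

    def classify(donor: int, acceptor: int) -> str:
        if donor == u[1] and acceptor in (a[0], n[0]):
            return "consistent"
        if donor in (a[1], n[1]) and acceptor == d[0]:
            return "consistent"
        if donor == first[1] and acceptor == second[0]:
            return "cross"
        if donor == u[1] and acceptor == d[0]:
            return "skip"
        return "other"

    cols = samples or list(junctions.counts.columns)
    cats = {"consistent": 0, "cross": 0, "skip": 0, "other": 0}
    lo, hi = u[0], d[1]
    want_chrom = geometry.get("chrom")
    for key in junctions.counts.index:
        chrom, donor, acceptor, strand = key
        if want_chrom is not None and chrom != want_chrom:
            continue
        if donor < lo or acceptor > hi:
            continue
        cats[classify(donor, acceptor)] += int(junctions.counts.loc[key, cols].sum())
    total = sum(cats.values())
    denom = cats["consistent"] + cats["cross"]
    return MxeConsistency(
        category_counts=cats,
        consistent_fraction=cats["consistent"] / denom if denom else float("nan"),
        skip_fraction=cats["skip"] / total if total else float("nan"),
        cross_fraction=cats["cross"] / total if total else float("nan"),
        total_reads=total,
    )
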