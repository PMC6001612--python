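"""Offset-anchored similarity, family coherence scores, and the bootstrap null.

The similarity between two expression vectors X and Y over N conditions is

    S(X, Y) = (1/N) * sum_i ((X_i - X_off) / phi_X) * ((Y_i - Y_off) / phi_Y)

with phi_G = sqrt(sum_i (G_i - G_off)^2 / N).  It is a Pearson-style product
moment anchored at a fixed reference value (here the unperturbed t = 0 state,
which is 0 after normalization) instead of the sample mean; with offsets set
to the sample means it reduces exactly to the textbook correlation
coefficient.  |S| <= 1 by Cauchy-Schwarz, S is symmetric, and S is invariant
to positive rescaling of either centred vector.

Family coherence compares the *cluster score* (mean within-cluster pairwise
S, averaged over clusters) against the *singleton score* (mean S over every
unordered pair of singletons — every possible pairing partner for every
unpaired gene).  The bootstrap null resamples same-size random groupings of
family genes with replacement and locates the observed cluster score within
the resulting distribution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .expression import ExpressionSet, concatenate_conditions
from .genome import ClusterPartition, GeneFamily

logger = logging.getLogger(__name__)

#: Per-condition cluster-vs-singleton difference reported as "higher".
HIGHER_THRESHOLD = 0.05
#: Difference reported as "markedly higher" (cell-cycle-style analyses).
MARKEDLY_HIGHER_THRESHOLD = 0.10

#: Minimum shared observed positions for a pair's S to enter family means.
MIN_PAIR_OVERLAP = 3


def similarity(
    x: np.ndarray,
    y: np.ndarray,
    x_offset: float = 0.0,
    y_offset: float = 0.0,
) -> float:
    """Offset-anchored similarity S(X, Y); NaN if undefined.

    Positions where either vector is missing are excluded (the offsets and
    phi values are computed over the shared positions).  A vector constant at
    its offset has phi = 0 and an undefined score, returned as NaN — never
    coerced to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got {x.shape} vs {y.shape}")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 2:
        return float("nan")
    dx = x[mask] - x_offset
    dy = y[mask] - y_offset
    sx = float(np.sqrt(np.sum(dx * dx) / n))
    sy = float(np.sqrt(np.sum(dy * dy) / n))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    s = float(np.sum(dx * dy) / (n * sx * sy))
    # guard against rounding pushing |S| infinitesimally past 1
    return min(1.0, max(-1.0, s))


@dataclass(frozen=True)
class CoherenceResult:
    """Singleton and cluster coherence scores for one family."""

    family_id: str
    singleton_score: float  # NaN when < 2 scorable singletons
    cluster_score: float    # NaN when no scorable cluster
    n_singletons: int
    n_clustered: int
    n_excluded_pairs: int = 0
    per_condition: dict[str, tuple[float, float]] | None = None

    @property
    def difference(self) -> float:
        return self.cluster_score - self.singleton_score

    def flag(self) -> str:
        """'' / 'higher' / 'markedly_higher' by the composite difference."""
        d = self.difference
        if np.isnan(d):
            return ""
        if d > MARKEDLY_HIGHER_THRESHOLD:
            return "markedly_higher"
        if d > HIGHER_THRESHOLD:
            return "higher"
        return ""


def _gene_vectors(
    expr: ExpressionSet, genes: list[str], condition: str | None = None
) -> dict[str, np.ndarray]:
    if condition is None:
        return {g: concatenate_conditions(expr, g)[0] for g in genes}
    s = expr.get(condition)
    return {g: s.vector(g) for g in genes}


def _mean_pairwise(
    vectors: dict[str, np.ndarray], pairs: list[tuple[str, str]]
) -> tuple[float, int]:
    """Mean similarity over pairs; NaN pairs (undefined or < MIN_PAIR_OVERLAP
    shared positions) are excluded and counted."""
    scores = []
    excluded = 0
    for a, b in pairs:
        x, y = vectors[a], vectors[b]
        if int((~(np.isnan(x) | np.isnan(y))).sum()) < MIN_PAIR_OVERLAP:
            excluded += 1
            continue
        s = similarity(x, y)
        if np.isnan(s):
            excluded += 1
        else:
            scores.append(s)
    if not scores:
        return float("nan"), excluded
    return float(np.mean(scores)), excluded


def _cluster_pairs(
    partition: ClusterPartition, within: str = "all"
) -> list[list[tuple[str, str]]]:
    """Pairs scored within each cluster: every unordered pair (default) or
    only directly adjacent pairs."""
    out = []
    for c in partition.clusters:
        if within == "all":
            out.append(list(itertools.combinations(c, 2)))
        elif within == "adjacent":
            out.append([(c[i], c[i + 1]) for i in range(len(c) - 1)])
        else:
            raise ValueError(f"unknown within-cluster pairing {within!r}")
    return out


def family_scores(
    partition: ClusterPartition,
    expr: ExpressionSet,
    mode: str = "composite",
    cluster_pairing: str = "all",
) -> CoherenceResult:
    """Singleton and cluster coherence for one partitioned family.

    ``mode='composite'`` scores concatenated per-condition vectors;
    ``mode='per_condition'`` additionally reports each condition separately
    (the composite is always filled in).  The singleton score is the mean S
    over all unordered singleton pairs; the cluster score is the mean over
    clusters of the mean pairwise S within each cluster (a two-gene cluster
    contributes its single pair's S).
    """
    if mode not in ("composite", "per_condition"):
        raise ValueError(f"unknown mode {mode!r}")
    genes = list(partition.singletons) + partition.clustered_genes()
    singleton_pairs = list(itertools.combinations(partition.singletons, 2))
    per_cluster = _cluster_pairs(partition, cluster_pairing)

    def score(condition: str | None) -> tuple[float, float, int]:
        vectors = _gene_vectors(expr, genes, condition)
        s_single, excl_s = _mean_pairwise(vectors, singleton_pairs)
        cluster_means = []
        excl_c = 0
        for pairs in per_cluster:
            m, e = _mean_pairwise(vectors, pairs)
            excl_c += e
            if not np.isnan(m):
                cluster_means.append(m)
        s_cluster = float(np.mean(cluster_means)) if cluster_means else float("nan")
        return s_single, s_cluster, excl_s + excl_c

    s_single, s_cluster, excluded = score(None)
    if excluded:
        logger.warning(
            "family %s: %d pair score(s) undefined/under-observed, excluded",
            partition.family_id, excluded,
        )
    per_condition = None
    if mode == "per_condition":
        per_condition = {}
        for s in expr.series:
            ps, pc, _ = score(s.condition_id)
            per_condition[s.condition_id] = (ps, pc)
    return CoherenceResult(
        family_id=partition.family_id,
        singleton_score=s_single,
        cluster_score=s_cluster,
        n_singletons=len(partition.singletons),
        n_clustered=partition.j_clustered,
        n_excluded_pairs=excluded,
        per_condition=per_condition,
    )


# ---------------------------------------------------------------------------
# bootstrap null

@dataclass(frozen=True)
class BootstrapNull:
    """Null distribution of mean within-pair similarity over random groupings."""

    n_iterations: int
    null_scores: np.ndarray
    observed_score: float
    empirical_percentile: float       # Pr(null <= observed), (r+1)/(n+1)
    upper_percentile: float           # Pr(null >= observed), (r+1)/(n+1)
    selection_counts: dict[str, int]
    seed: int
    n_self_pair_redraws: int
    convergence_ks: float = field(default=float("nan"))
    convergence_ks_p: float = field(default=float("nan"))


def pairwise_similarity_matrix(
    expr: ExpressionSet, genes: list[str]
) -> np.ndarray:
    """Dense S matrix over a gene list (diagonal 1, NaN where undefined)."""
    vectors = _gene_vectors(expr, genes, None)
    V = np.vstack([vectors[g] for g in genes])
    n = V.shape[0]
    if not np.isnan(V).any():
        npos = V.shape[1]
        phi = np.sqrt(np.sum(V * V, axis=1) / npos)
        with np.errstate(divide="ignore", invalid="ignore"):
            Z = V / phi[:, None]
            S = (Z @ Z.T) / npos
        S[phi == 0, :] = np.nan
        S[:, phi == 0] = np.nan
        return np.clip(S, -1.0, 1.0, out=S)  # NaN passes through clip
    S = np.full((n, n), np.nan)
    for i in range(n):
        S[i, i] = 1.0
        for k in range(i + 1, n):
            S[i, k] = S[k, i] = similarity(V[i], V[k])
    return S


def bootstrap_null(
    family: GeneFamily,
    expr: ExpressionSet,
    group_size: int,
    n_iterations: int = 10_000,
    seed: int = 0,
    observed_score: float = float("nan"),
) -> BootstrapNull:
    """Bootstrap-with-replacement null of the mean within-pair similarity.

    Each iteration draws ``group_size`` genes with replacement from the whole
    family (clustered and singleton members alike), pairs them consecutively,
    and records the mean pairwise S.  A draw that pairs a gene with itself
    would trivially score 1, so such pairs are redrawn (the event is
    counted).  The empirical percentile of ``observed_score`` uses the
    (r+1)/(n+1) estimator; both one-sided percentiles are reported, along
    with a first-half/second-half Kolmogorov-Smirnov convergence check.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if group_size < 2 or group_size % 2:
        raise ValueError(f"group_size must be even and >= 2, got {group_size}")
    genes = sorted(g for g in family.members if g in expr.gene_universe)
    if len(genes) < 2:
        raise ValueError(f"family {family.family_id}: fewer than 2 genes with expression")
    S = pairwise_similarity_matrix(expr, genes)
    ngenes = len(genes)
    n_pairs = group_size // 2
    rng = np.random.default_rng(seed)
    null_scores = np.empty(n_iterations)
    counts = np.zeros(ngenes, dtype=np.int64)
    redraws = 0
    for it in range(n_iterations):
        a = rng.integers(0, ngenes, size=n_pairs)
        b = rng.integers(0, ngenes, size=n_pairs)
        bad = a == b
        while bad.any():
            redraws += int(bad.sum())
            a[bad] = rng.integers(0, ngenes, size=int(bad.sum()))
            b[bad] = rng.integers(0, ngenes, size=int(bad.sum()))
            bad = a == b
        vals = S[a, b]
        null_scores[it] = np.nanmean(vals)
        np.add.at(counts, a, 1)
        np.add.at(counts, b, 1)
    r_low = int(np.sum(null_scores <= observed_score))
    r_high = int(np.sum(null_scores >= observed_score))
    half = n_iterations // 2
    if half >= 1 and n_iterations - half >= 1:
        ks = stats.ks_2samp(null_scores[:half], null_scores[half:])
        ks_stat, ks_p = float(ks.statistic), float(ks.pvalue)
    else:
        ks_stat = ks_p = float("nan")
    return BootstrapNull(
        n_iterations=n_iterations,
        null_scores=null_scores,
        observed_score=observed_score,
        empirical_percentile=(r_low + 1) / (n_iterations + 1),
        upper_percentile=(r_high + 1) / (n_iterations + 1),
        selection_counts={g: int(c) for g, c in zip(genes, counts)},
        seed=seed,
        n_self_pair_redraws=redraws,
        convergence_ks=ks_stat,
        convergence_ks_p=ks_p,
    )


# ---------------------------------------------------------------------------
# diagnostics

def bin_for_histogram(
    scores: np.ndarray, floor: float = -0.1, bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of similarity scores with every value below ``floor``
    clamped to the floor bin.  Returns (bin_edges, counts); counts sum to the
    input length."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return np.array([floor]), np.array([], dtype=int)
    clamped = np.maximum(scores, floor)
    hi = max(1.0, float(np.max(clamped)))
    n_bins = int(np.ceil((hi - floor) / bin_width)) or 1
    edges = floor + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(clamped, bins=edges)
    return edges, counts


@dataclass(frozen=True)
class SelectionDiagnostics:
    n_genes: int
    min_count: int
    max_count: int
    mean_count: float
    cv: float
    chisq: float
    chisq_p: float
    bias_warning: bool


def selection_uniformity(counts: dict[str, int]) -> SelectionDiagnostics:
    """Uniformity diagnostics of per-gene bootstrap selection frequencies.

    A gene never selected despite an expected count >= 10 raises the bias
    flag, as does chi-square goodness-of-fit p < 0.001.
    """
    if not counts:
        raise ValueError("counts must be non-empty")
    c = np.array(list(counts.values()), dtype=float)
    mean = float(c.mean())
    cv = float(c.std() / mean) if mean > 0 else float("nan")
    if mean > 0:
        chi = stats.chisquare(c)
        chisq, chisq_p = float(chi.statistic), float(chi.pvalue)
    else:
        chisq = chisq_p = float("nan")
    bias = bool((mean >= 10 and (c == 0).any()) or (chisq_p == chisq_p and chisq_p < 1e-3))
    return SelectionDiagnostics(
        n_genes=c.size,
        min_count=int(c.min()),
        max_count=int(c.max()),
        mean_count=mean,
        cv=cv,
        chisq=chisq,
        chisq_p=chisq_p,
        bias_warning=bias,
    )


# ---------------------------------------------------------------------------
# report writers

def write_coherence_tsv(
    results: list[CoherenceResult],
    path,
    condition_ids: list[str] | None = None,
    header_comments: list[str] | None = None,
) -> None:
    """Family-per-row singleton/cluster score table; per-condition columns
    are emitted when available."""
    conds = condition_ids or []
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        cols = ["family_id", "n_singletons", "n_clustered",
                "singleton_composite", "cluster_composite", "difference", "flag"]
        for c in conds:
            cols += [f"singleton_{c}", f"cluster_{c}"]
        fh.write("\t".join(cols) + "\n")
        for r in results:
            row = [
                r.family_id, str(r.n_singletons), str(r.n_clustered),
                _fmt(r.singleton_score), _fmt(r.cluster_score),
                _fmt(r.difference), r.flag(),
            ]
            for c in conds:
                if r.per_condition and c in r.per_condition:
                    ps, pc = r.per_condition[c]
                    row += [_fmt(ps), _fmt(pc)]
                else:
                    row += ["NA", "NA"]
            fh.write("\t".join(row) + "\n")


def write_histogram_tsv(
    edges: np.ndarray,
    counts: np.ndarray,
    path,
    observed_score: float = float("nan"),
    header_comments: list[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write("bin_left\tbin_right\tcount\tcontains_observed\n")
        for i in range(len(counts)):
            left, right = edges[i], edges[i + 1]
            inside = left <= observed_score < right or (
                i == len(counts) - 1 and observed_score == right
            )
            fh.write(f"{left:.6g}\t{right:.6g}\t{int(counts[i])}\t{int(bool(inside))}\n")


def _fmt(v: float) -> str:
    return "NA" if np.isnan(v) else f"{v:.6f}"
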