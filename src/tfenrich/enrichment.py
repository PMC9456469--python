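"""Score-based Kolmogorov-Smirnov term enrichment ("classic" algorithm).

Every ontology term is tested independently of its DAG neighbours: the
scores (adjusted p-values from differential expression) of the genes
annotated to the term are compared with the scores of the remaining
universe genes by a one-sided two-sample KS test.  Small tests are exact
(complete enumeration of assignments, computed by a lattice DP with
integer arithmetic so ties cost nothing); larger ones fall back to the
one-sided asymptotic tail exp(-2 D+^2 mn/(m+n)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .ontology import GoAnnotation, GoDag

EXACT_ENUMERATION_LIMIT = 100_000
# the lattice DP is exact at any C(m+n, m); gate it by its own cost instead
DP_COST_LIMIT = 100_000


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    label: str
    size: int  # annotated genes in the universe
    ks_stat: float
    p: float
    order: int  # 1-based rank by ascending p, ties by term id


@dataclass
class MethodRun:
    """One GSEA pass: a method (1 or 2), a stream (up/down), its universe."""

    method: int
    stream: str
    universe: frozenset[str]
    results: list[EnrichmentResult] = field(default_factory=list)
    significant: list[EnrichmentResult] = field(default_factory=list)
    untestable: list[str] = field(default_factory=list)
    tf_degs_associated: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.results


def _tie_groups(term_scores, comp_scores):
    """Pooled sorted unique values with per-group (term, complement) counts."""
    term = np.sort(np.asarray(term_scores, dtype=float))
    comp = np.sort(np.asarray(comp_scores, dtype=float))
    values = np.unique(np.concatenate([term, comp]))
    ct = np.searchsorted(term, values, side="right")
    cc = np.searchsorted(comp, values, side="right")
    term_counts = np.diff(np.concatenate([[0], ct]))
    comp_counts = np.diff(np.concatenate([[0], cc]))
    return term_counts.astype(int), comp_counts.astype(int)


def _d_plus_int(term_counts, comp_counts, m: int, n: int) -> int:
    """max over pooled unique values of (ECDF_term - ECDF_comp), scaled by m*n."""
    a = np.cumsum(term_counts)  # term genes <= value
    b = np.cumsum(comp_counts)
    return int(np.max(a * n - b * m))


def _exact_p(term_counts, comp_counts, m: int, n: int, d_int: int) -> float:
    """P(D+ >= d_int/(m n)) over all C(m+n, m) equally likely assignments.

    Lattice DP over tie groups: state = number of term genes seen so far.
    A path is 'bad' once some prefix satisfies a*n - (k-a)*m >= d_int; bad
    states are pruned (the running maximum can never recover), so the
    surviving mass counts assignments with D+ strictly below the observed
    value.  Exact integer arithmetic throughout.
    """
    if d_int <= 0:
        return 1.0
    total = math.comb(m + n, m)
    sizes = [int(t + c) for t, c in zip(term_counts, comp_counts)]
    # ways[a] = number of prefix assignments with `a` term genes placed,
    # none of which has hit the threshold
    ways = [0] * (m + 1)
    ways[0] = 1
    seen = 0
    for g_size in sizes:
        seen += g_size
        new = [0] * (m + 1)
        for a, w in enumerate(ways):
            if w == 0:
                continue
            for j in range(0, min(g_size, m - a) + 1):
                new[a + j] += w * math.comb(g_size, j)
        # prune states whose prefix statistic reaches the observed value
        for a in range(m + 1):
            if new[a] and a * n - (seen - a) * m >= d_int:
                new[a] = 0
        ways = new
    good = ways[m]
    return (total - good) / total


def ks_term_test(
    term_scores,
    comp_scores,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
    alternative: str = "enriched",
) -> tuple[float, float]:
    """One-sided two-sample KS test that term genes have smaller scores.

    Returns (D+, p).  D+ = max over pooled unique score values of
    ECDF_term - ECDF_complement.  The p-value is exact — equal to the
    frequency of D+ >= observed over all C(m+n, m) equally likely
    assignments — whenever that count is at most ``exact_limit`` or the
    lattice DP that computes it stays cheap (:data:`DP_COST_LIMIT`);
    otherwise the asymptotic one-sided tail exp(-2 D+^2 mn/(m+n)) is
    used.  ``alternative="two-sided"`` uses max |ECDF difference|.
    """
    m = len(term_scores)
    n = len(comp_scores)
    if m == 0 or n == 0:
        raise ValueError("both score lists must be nonempty")
    if alternative not in ("enriched", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    term_counts, comp_counts = _tie_groups(term_scores, comp_scores)
    if alternative == "two-sided":
        a = np.cumsum(term_counts)
        b = np.cumsum(comp_counts)
        d_int = int(np.max(np.abs(a * n - b * m)))
    else:
        d_int = _d_plus_int(term_counts, comp_counts, m, n)
    d = max(d_int, 0) / (m * n)
    if d_int <= 0:
        return 0.0, 1.0
    # DP inner work is ~(m+1)*(m+n+K) big-int operations
    dp_cost = (m + 1) * (m + n + len(term_counts))
    if math.comb(m + n, m) <= exact_limit or dp_cost <= DP_COST_LIMIT:
        if alternative == "two-sided":
            p = _exact_p_two_sided(term_counts, comp_counts, m, n, d_int)
        else:
            p = _exact_p(term_counts, comp_counts, m, n, d_int)
    else:
        p = float(np.exp(-2.0 * d * d * m * n / (m + n)))
        if alternative == "two-sided":
            p = min(1.0, 2.0 * p)
    return d, min(p, 1.0)


def _exact_p_two_sided(term_counts, comp_counts, m, n, d_int) -> float:
    if d_int <= 0:
        return 1.0
    total = math.comb(m + n, m)
    sizes = [int(t + c) for t, c in zip(term_counts, comp_counts)]
    ways = [0] * (m + 1)
    ways[0] = 1
    seen = 0
    for g_size in sizes:
        seen += g_size
        new = [0] * (m + 1)
        for a, w in enumerate(ways):
            if w == 0:
                continue
            for j in range(0, min(g_size, m - a) + 1):
                new[a + j] += w * math.comb(g_size, j)
        for a in range(m + 1):
            if new[a] and abs(a * n - (seen - a) * m) >= d_int:
                new[a] = 0
        ways = new
    return (total - ways[m]) / total


def run_classic_gsea(
    scores: dict[str, float],
    dag: GoDag,
    ann: GoAnnotation,
    min_size: int = 1,
    alternative: str = "enriched",
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> tuple[list[EnrichmentResult], list[str]]:
    """Test every annotated term against the score universe independently.

    ``scores`` maps every universe gene to its score (smaller = more
    significant).  The annotation must already be restricted to the score
    universe.  Returns the ranked result list (ascending p, ties broken by
    ascending term id) and the ids of untestable terms (empty complement).
    """
    universe = set(scores)
    if len(universe) < 2:
        raise ValueError("gene universe must contain at least 2 genes")
    results = []
    untestable = []
    score_arr = {g: float(s) for g, s in scores.items()}
    for term in sorted(ann.propagated):
        genes = ann.propagated[term] & universe
        if len(genes) < min_size or not genes:
            continue
        complement = universe - genes
        if not complement:
            untestable.append(term)
            continue
        t_scores = [score_arr[g] for g in genes]
        c_scores = [score_arr[g] for g in complement]
        ks, p = ks_term_test(
            t_scores, c_scores, exact_limit=exact_limit, alternative=alternative
        )
        label = dag.label(term) if term in dag.terms else term
        results.append(
            EnrichmentResult(term=term, label=label, size=len(genes), ks_stat=ks, p=p, order=0)
        )
    results.sort(key=lambda r: (r.p, r.term))
    ranked = [
        EnrichmentResult(r.term, r.label, r.size, r.ks_stat, r.p, order=i + 1)
        for i, r in enumerate(results)
    ]
    return ranked, untestable


def run_method(
    method: int,
    stats_df,
    catalog,
    dag: GoDag,
    ann: GoAnnotation,
    min_size: int = 1,
    alpha_term: float = 0.05,
    alternative: str = "enriched",
) -> dict[str, MethodRun]:
    """Run one method over both streams.

    Method 1: universe = all DEGs of the stream, scored by adj_p; TF-DEGs
    are intersected with each term afterwards.  Method 2: universe = the
    stream's TF-DEGs only, annotation restricted before testing.
    """
    if method not in (1, 2):
        raise ValueError("method must be 1 or 2")
    catalog = set(catalog)
    runs: dict[str, MethodRun] = {}
    for stream in ("up", "down"):
        stream_degs = stats_df.index[stats_df["status"] == stream]
        tf_degs = frozenset(g for g in stream_degs if g in catalog)
        universe = frozenset(stream_degs) if method == 1 else tf_degs
        run = MethodRun(method=method, stream=stream, universe=universe)
        if len(universe) < 2:
            warnings.warn(
                f"method {method} {stream} stream: universe of size "
                f"{len(universe)} is too small; returning an empty run",
                stacklevel=2,
            )
            runs[stream] = run
            continue
        restricted = _restrict(ann, universe, min_size)
        scores = stats_df.loc[list(universe), "adj_p"].to_dict()
        results, untestable = run_classic_gsea(
            scores, dag, restricted, min_size=min_size, alternative=alternative
        )
        run.results = results
        run.untestable = untestable
        run.significant = [r for r in results if r.p < alpha_term]
        run.tf_degs_associated = {
            r.term: frozenset(restricted.propagated[r.term] & tf_degs)
            for r in results
        }
        runs[stream] = run
    return runs


def _restrict(ann: GoAnnotation, universe, min_size):
    from .ontology import restrict_to_universe

    return restrict_to_universe(ann, universe, min_size=min_size)


def run_both_methods(stats_df, catalog, dag, ann, **kwargs) -> dict[tuple[int, str], MethodRun]:
    """All four runs (2 methods x 2 streams) keyed by (method, stream)."""
    runs: dict[tuple[int, str], MethodRun] = {}
    for method in (1, 2):
        for stream, run in run_method(method, stats_df, catalog, dag, ann, **kwargs).items():
            runs[(method, stream)] = run
    return runs
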