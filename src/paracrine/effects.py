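"""IDA causal-effect estimation with subsampling stability selection.

Given the stromal CPDAG, the total causal effect of a secreted stromal gene
``x`` on a tumor gene ``y`` is identified only up to the Markov equivalence
class: each DAG in the class has its own parent set of ``x`` and hence its
own adjusted regression effect.  The local IDA enumeration walks the valid
parent configurations directly from the CPDAG - the certain parents of
``x`` plus every subset of its undirected neighbors whose orientation
toward ``x`` creates no new collider - and computes, for each, the
coefficient of ``x`` in the least-squares regression of ``y`` on ``x`` and
the adjustment set.  On standardized data this coefficient is the expected
change of ``y`` per one-standard-unit (virtual) intervention on ``x``.  The
effect with minimum absolute value (sign preserved) is kept as a
conservative lower bound over the equivalence class.

:func:`global_ida_oracle` enumerates every consistent DAG extension of the
CPDAG explicitly; by the local/global equivalence of the IDA method its
distinct effect values coincide with the local enumeration, which the test
suite exploits as an exact oracle.

Because a CPDAG estimated from 15 samples is volatile, the whole procedure
is wrapped in stability selection: many subsamples are drawn (paired
stromal/tumor samples move together), each subsample is re-standardized and
re-analyzed, all (x, y) lower bounds are ranked jointly by magnitude, and
the relative frequency with which a pair lands in the top fraction ``q`` of
effects is recorded.  Pairs at or above the frequency threshold ``pi`` are
retained, and the median lower bound across all runs is their effect
summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import (
    ConsistencyError,
    PairingError,
    ParameterError,
    RankDeficiencyError,
    SizeError,
)
from .matrix import ExpressionMatrix
from .network import Cpdag, pc
from .preprocess import standardize


# ----------------------------------------------------------- adjustment sets

def local_adjustment_sets(cpdag: Cpdag, x: str) -> List[Tuple[str, ...]]:
    """All locally valid adjustment sets for x in the CPDAG.

    Valid sets are pa(x) u S for subsets S of the undirected neighbors of x
    such that orienting S -> x (and x -> the remaining neighbors) creates no
    new collider at x: every pair of new parents - two members of S, or a
    member of S with a certain parent - must be adjacent in the CPDAG.
    Equivalently, S must be a clique among the siblings that are each
    adjacent to every certain parent, so only clique subsets are
    enumerated.  Sets are returned sorted (by size, then lexicographically)
    and deduplicated.
    """
    pa = cpdag.parents(x)
    sib = cpdag.undirected_neighbors(x)
    # a sibling that is non-adjacent to some certain parent can never join
    eligible = [s for s in sib if all(cpdag.adjacent(s, p) for p in pa)]
    adj = {
        (a, b): cpdag.adjacent(a, b) for a, b in combinations(eligible, 2)
    }

    cliques: List[Tuple[str, ...]] = [()]

    def extend(current: Tuple[str, ...], rest: List[str]) -> None:
        for i, cand in enumerate(rest):
            if all(adj[tuple(sorted((cand, c)))] for c in current):
                nxt = current + (cand,)
                cliques.append(nxt)
                extend(nxt, rest[i + 1:])

    extend((), eligible)
    out = sorted({tuple(sorted(set(pa) | set(s))) for s in cliques},
                 key=lambda t: (len(t), t))
    return out


# --------------------------------------------------------- adjusted effects

def adjusted_effect(
    stromal: ExpressionMatrix,
    tumor: ExpressionMatrix,
    x: str,
    y: str,
    adjust: Sequence[str] = (),
) -> float:
    """Coefficient of x in the regression of y on {x} u adjust (+ intercept).

    With per-gene standardized data and an empty adjustment set this equals
    the Pearson correlation of x and y across the paired samples.
    """
    if x in adjust:
        raise ParameterError("x must not be part of its own adjustment set")
    if stromal.n_samples != tumor.n_samples:
        raise PairingError("stromal and tumor matrices have unequal sample counts")
    xv = stromal.values.loc[x].to_numpy()
    zv = stromal.values.loc[list(adjust)].to_numpy() if adjust else np.empty((0, xv.size))
    yv = tumor.values.loc[y].to_numpy()
    design = np.column_stack([np.ones_like(xv), xv] + list(zv))
    coef, _, rank, _ = np.linalg.lstsq(design, yv, rcond=None)
    if rank < design.shape[1]:
        raise RankDeficiencyError(
            f"collinear design for effect of {x!r} on {y!r} adjusting for {list(adjust)}"
        )
    return float(coef[1])


def _effects_for_sets(
    x_idx: int,
    adj_sets: List[Tuple[int, ...]],
    stromal_vals: np.ndarray,
    tumor_vals: np.ndarray,
) -> np.ndarray:
    """Effects of stromal gene x on every tumor gene, one row per adjustment set."""
    n = stromal_vals.shape[1]
    ones = np.ones(n)
    out = np.empty((len(adj_sets), tumor_vals.shape[0]))
    for k, s in enumerate(adj_sets):
        design = np.column_stack([ones, stromal_vals[x_idx]] + [stromal_vals[j] for j in s])
        coef, _, rank, _ = np.linalg.lstsq(design, tumor_vals.T, rcond=None)
        if rank < design.shape[1]:
            raise RankDeficiencyError(
                f"collinear design for stromal gene index {x_idx} with set {s}"
            )
        out[k] = coef[1]
    return out


@dataclass
class EffectRecord:
    """IDA effect multiset for one (secreted gene, tumor gene) pair."""

    x: str
    y: str
    effects: List[float]

    @property
    def lower_bound(self) -> float:
        if not self.effects:
            raise ConsistencyError("effects multiset is empty")
        return min(self.effects, key=abs)

    @property
    def signed_minimum(self) -> float:
        return min(self.effects)


def ida_lower_bounds(
    stromal: ExpressionMatrix,
    tumor: ExpressionMatrix,
    cpdag: Cpdag,
    secreted: Sequence[str],
    targets: Sequence[str],
    mode: str = "absolute",
) -> pd.DataFrame:
    """Minimum-effect lower bounds for every (secreted, target) pair.

    ``mode='absolute'`` (default) keeps the effect of minimum absolute value
    with its sign; ``mode='signed'`` keeps the signed minimum.
    """
    lb, n_sets = _ida_matrix(stromal, tumor, cpdag, secreted, targets, mode)
    rows = []
    for i, x in enumerate(secreted):
        for j, y in enumerate(targets):
            rows.append((x, y, lb[i, j], n_sets[i]))
    return pd.DataFrame(rows, columns=["x", "y", "lower_bound", "n_adjustment_sets"])


def _ida_matrix(
    stromal: ExpressionMatrix,
    tumor: ExpressionMatrix,
    cpdag: Cpdag,
    secreted: Sequence[str],
    targets: Sequence[str],
    mode: str = "absolute",
) -> Tuple[np.ndarray, List[int]]:
    if mode not in ("absolute", "signed"):
        raise ParameterError("mode must be 'absolute' or 'signed'")
    missing = [g for g in secreted if not cpdag.has_node(g)]
    if missing:
        raise ConsistencyError(f"secreted genes missing from CPDAG: {missing[:5]}")
    forbidden = [g for g in targets if cpdag.has_node(g)]
    if forbidden:
        raise ConsistencyError(
            f"tumor genes must not appear in the stromal CPDAG: {forbidden[:5]}"
        )
    stromal = stromal.subset_genes(cpdag.nodes)
    tumor_t = tumor.subset_genes(list(targets))
    svals = stromal.array()
    tvals = tumor_t.array()
    gidx = {g: i for i, g in enumerate(cpdag.nodes)}
    lb = np.empty((len(secreted), len(targets)))
    set_counts: List[int] = []
    for i, x in enumerate(secreted):
        sets = local_adjustment_sets(cpdag, x)
        idx_sets = [tuple(gidx[g] for g in s) for s in sets]
        eff = _effects_for_sets(gidx[x], idx_sets, svals, tvals)
        if mode == "absolute":
            pick = np.argmin(np.abs(eff), axis=0)
            lb[i] = eff[pick, np.arange(eff.shape[1])]
        else:
            lb[i] = eff.min(axis=0)
        set_counts.append(len(sets))
    return lb, set_counts


# ------------------------------------------------------------ global oracle

def _consistent_extensions(cpdag: Cpdag, max_undirected: int = 12):
    """Yield directed adjacency matrices of every consistent DAG extension."""
    from .network import _is_acyclic, _v_structures

    und = sorted(tuple(sorted(e)) for e in cpdag.undirected_edges)
    if len(und) > max_undirected:
        raise SizeError(
            f"{len(und)} undirected edges exceed the enumeration cap {max_undirected}"
        )
    base = cpdag.amat.copy()
    base_v = _v_structures(base)
    idx = {g: i for i, g in enumerate(cpdag.nodes)}
    for bits in range(2 ** len(und)):
        amat = base.copy()
        for k, (a, b) in enumerate(und):
            i, j = idx[a], idx[b]
            if (bits >> k) & 1:
                amat[j, i] = 0  # a -> b
            else:
                amat[i, j] = 0  # b -> a
        directed = (amat == 1) & (amat.T == 0)
        if not _is_acyclic(directed):
            continue
        if _v_structures(amat) != base_v:
            continue
        yield directed


def global_ida_oracle(
    cpdag: Cpdag,
    stromal: ExpressionMatrix,
    tumor: ExpressionMatrix,
    x: str,
    y: str,
    max_undirected: int = 12,
) -> List[float]:
    """Effects of x on y across every DAG in the equivalence class.

    Exhaustive counterpart of the local enumeration: orient the undirected
    edges in all consistent ways, and for each DAG regress y on x plus that
    DAG's parents of x.
    """
    i_x = cpdag.index(x)
    effects = []
    for directed in _consistent_extensions(cpdag, max_undirected):
        pa = [cpdag.nodes[i] for i in np.where(directed[:, i_x])[0]]
        effects.append(adjusted_effect(stromal, tumor, x, y, pa))
    if not effects:
        raise ConsistencyError("CPDAG admits no consistent extension")
    return effects


# ------------------------------------------------------- stability selection

@dataclass
class StabilityConfig:
    """Parameters of the subsampling stability selection."""

    n_runs: int = 100
    subsample_size: Optional[int] = None  # default: 12-of-15 ratio (80%)
    alpha: float = 0.2
    top_fraction: float = 0.30
    freq_threshold: float = 0.7
    max_cond_size: Optional[int] = None
    effect_mode: str = "absolute"
    standardize_per_subsample: bool = True
    seed: int = 0

    def resolved_subsample(self, n: int) -> int:
        size = self.subsample_size
        if size is None:
            size = int(round(0.8 * n))
        if size > n or size < 4:
            raise ParameterError(
                f"subsample_size must be between 4 and the sample count {n}; got {size}"
            )
        return size

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ParameterError("n_runs must be >= 1")
        if not (0 < self.top_fraction <= 1):
            raise ParameterError("top_fraction must lie in (0, 1]")
        if not (0 <= self.freq_threshold <= 1):
            raise ParameterError("freq_threshold must lie in [0, 1]")


@dataclass
class StableEffectTable:
    """Per-pair selection frequencies and median effects, plus raw run data.

    ``table`` has one row per (x, y) pair with columns ``x``, ``y``,
    ``frequency`` (fraction of runs in which the pair ranked in the top
    fraction of absolute effects) and ``median_effect`` (median lower bound
    across all runs).  ``lower_bounds`` keeps the full pairs x runs matrix
    so retention can be re-evaluated for any (q, pi) without re-running.
    """

    table: pd.DataFrame
    params: Dict = field(default_factory=dict)
    lower_bounds: Optional[np.ndarray] = None  # shape (n_pairs, n_runs)

    def retained(self, freq_threshold: Optional[float] = None) -> pd.DataFrame:
        pi = self.params.get("freq_threshold", 0.7) if freq_threshold is None else freq_threshold
        return self.table[self.table["frequency"] >= pi].reset_index(drop=True)

    def frequencies_for(self, top_fraction: float) -> np.ndarray:
        """Recompute per-pair top-``q`` frequencies from the stored run matrix."""
        if self.lower_bounds is None:
            raise ConsistencyError("run-level lower bounds were not stored")
        return _top_frequencies(self.lower_bounds, top_fraction)


def _top_frequencies(lb: np.ndarray, top_fraction: float) -> np.ndarray:
    """Fraction of runs in which each pair's |effect| reaches the top fraction.

    The cutoff is the ceil(q * N)-th largest absolute effect in the run;
    ties at the cutoff are all included.
    """
    if not (0 < top_fraction <= 1):
        raise ParameterError("top_fraction must lie in (0, 1]")
    n_pairs, n_runs = lb.shape
    k = int(np.ceil(top_fraction * n_pairs))
    k = min(max(k, 1), n_pairs)
    hits = np.zeros((n_pairs, n_runs), dtype=bool)
    a = np.abs(lb)
    for r in range(n_runs):
        thresh = np.partition(a[:, r], n_pairs - k)[n_pairs - k]
        hits[:, r] = a[:, r] >= thresh
    return hits.mean(axis=1)


def stability_selection(
    stromal: ExpressionMatrix,
    tumor: ExpressionMatrix,
    secreted: Sequence[str],
    targets: Sequence[str],
    cfg: StabilityConfig = StabilityConfig(),
) -> StableEffectTable:
    """Subsampled PC + IDA with top-fraction frequency retention.

    ``stromal`` holds the network genes (secreted candidates included);
    ``tumor`` holds at least the target genes; columns of the two matrices
    are paired by position and are drawn jointly, since a stromal sample
    and the tumor sample its conditioned medium stimulated are inseparable.
    """
    cfg.validate()
    if stromal.n_samples != tumor.n_samples:
        raise PairingError("stromal and tumor matrices have unequal sample counts")
    overlap = set(stromal.genes) & set(targets)
    if overlap:
        raise ConsistencyError(
            f"tumor target genes must not be stromal network genes: {sorted(overlap)[:5]}"
        )
    n = stromal.n_samples
    size = cfg.resolved_subsample(n)
    secreted = list(secreted)
    targets = list(targets)
    rng = np.random.default_rng(cfg.seed)
    n_pairs = len(secreted) * len(targets)
    lb_runs = np.empty((n_pairs, cfg.n_runs))
    stromal_sub = stromal.subset_genes(stromal.genes)
    for r in range(cfg.n_runs):
        idx = np.sort(rng.choice(n, size=size, replace=False))
        s_sub = stromal_sub.take_samples(idx)
        t_sub = tumor.take_samples(idx)
        if cfg.standardize_per_subsample:
            s_sub = standardize(s_sub)
            t_sub = standardize(t_sub)
        cpdag = pc(s_sub, alpha=cfg.alpha, max_cond_size=cfg.max_cond_size)
        lb, _ = _ida_matrix(s_sub, t_sub, cpdag, secreted, targets, cfg.effect_mode)
        lb_runs[:, r] = lb.ravel()
    freq = _top_frequencies(lb_runs, cfg.top_fraction)
    med = np.median(lb_runs, axis=1)
    pairs = [(x, y) for x in secreted for y in targets]
    table = pd.DataFrame(
        {
            "x": [p[0] for p in pairs],
            "y": [p[1] for p in pairs],
            "frequency": freq,
            "median_effect": med,
        }
    )
    params = {
        "n_runs": cfg.n_runs,
        "subsample_size": size,
        "n_samples": n,
        "alpha": cfg.alpha,
        "top_fraction": cfg.top_fraction,
        "freq_threshold": cfg.freq_threshold,
        "effect_mode": cfg.effect_mode,
        "standardize_per_subsample": cfg.standardize_per_subsample,
        "seed": cfg.seed,
    }
    return StableEffectTable(table=table, params=params, lower_bounds=lb_runs)
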