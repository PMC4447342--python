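"""Sparse regulator selection by a Bayesian set-activation model.

The stable-effect table is reorganized into target sets - for each secreted
regulator, the set of tumor genes it stably affects.  A model-based gene
set analysis (MGSA-style) then explains the observed list of responsive
tumor genes with as few active sets as possible: each set is active with
prior probability ``p``; a tumor gene is hidden-on when it belongs to at
least one active set; an observed "on" flag arises from a hidden-off gene
with false-positive rate ``alpha`` and an observed "off" flag from a
hidden-on gene with false-negative rate ``beta``.  Because any active set
must pay the prior price ``p`` while overlapping sets explain the same
genes, the posterior exhibits explaining-away: redundant regulators
suppress each other, which is precisely what a frequency count of targets
cannot do.

Two inference routes are implemented: exact enumeration over all 2^m
activation states (feasible for the small collections this analysis
produces, and the oracle for testing) and a Metropolis-within-Gibbs MCMC
over the activation bit vector with grid moves for the nuisance rates,
averaged over independent restarts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import (
    CalibrationError,
    ConsistencyError,
    DomainError,
    ParameterError,
    SizeError,
)


# ----------------------------------------------------------------- containers

@dataclass
class TargetSetCollection:
    """Map regulator -> nonempty set of tumor genes, over a fixed universe."""

    sets: Dict[str, FrozenSet[str]]
    universe: Tuple[str, ...]

    def __post_init__(self):
        self.universe = tuple(self.universe)
        uni = set(self.universe)
        if len(uni) != len(self.universe):
            raise ConsistencyError("universe contains duplicate genes")
        for reg, s in self.sets.items():
            if not s:
                raise ConsistencyError(f"regulator {reg!r} has an empty target set")
            extra = set(s) - uni
            if extra:
                raise ConsistencyError(
                    f"targets of {reg!r} outside the universe: {sorted(extra)[:5]}"
                )
            self.sets[reg] = frozenset(s)

    @property
    def regulators(self) -> List[str]:
        return sorted(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


def build_target_sets(
    stable: pd.DataFrame, universe: Sequence[str]
) -> TargetSetCollection:
    """Reorganize retained (x, y) rows into per-regulator target sets.

    ``stable`` must contain only retained rows (columns ``x`` and ``y``);
    regulators without retained targets are simply absent.
    """
    sets: Dict[str, set] = {}
    uni = set(universe)
    for _, row in stable.iterrows():
        if row["y"] in uni:
            sets.setdefault(row["x"], set()).add(row["y"])
    sets = {x: frozenset(s) for x, s in sets.items() if s}
    if not sets:
        warnings.warn("no retained effects; target set collection is empty", stacklevel=2)
    return TargetSetCollection(sets=sets, universe=tuple(universe))


@dataclass
class MgsaParams:
    """Grids and MCMC settings for the set-activation model.

    The defaults place ten grid points over conservative ranges of the
    false-positive rate alpha in (0.01, 0.3), the false-negative rate beta
    in (0.05, 0.8) and the activation prior p in (1/m, 0.5); singleton
    grids fix a parameter.
    """

    alpha_grid: Sequence[float] = field(default_factory=lambda: np.linspace(0.01, 0.3, 10))
    beta_grid: Sequence[float] = field(default_factory=lambda: np.linspace(0.05, 0.8, 10))
    p_grid: Optional[Sequence[float]] = None  # default depends on the set count
    n_iter: int = 200_000
    burnin: int = 50_000
    n_restarts: int = 5
    seed: int = 0

    def resolved_p_grid(self, n_sets: int) -> np.ndarray:
        if self.p_grid is not None:
            return _check_grid(np.asarray(self.p_grid, dtype=float), "p")
        lo = min(1.0 / max(n_sets, 2), 0.5)
        return np.linspace(lo, 0.5, 10)

    def validate(self) -> None:
        _check_grid(np.asarray(self.alpha_grid, dtype=float), "alpha")
        _check_grid(np.asarray(self.beta_grid, dtype=float), "beta")
        if self.n_iter <= self.burnin:
            raise ParameterError("n_iter must exceed burnin")
        if self.n_restarts < 1:
            raise ParameterError("n_restarts must be >= 1")


def _check_grid(grid: np.ndarray, name: str) -> np.ndarray:
    if grid.size == 0:
        raise ParameterError(f"{name} grid is empty")
    if np.any(grid <= 0) or np.any(grid >= 1):
        raise DomainError(f"{name} grid values must lie strictly inside (0, 1)")
    return grid


@dataclass
class MgsaResult:
    """Marginal activation posteriors per regulator."""

    table: pd.DataFrame  # index regulator; columns set_size, posterior[, restart_spread]
    params: Dict = field(default_factory=dict)
    method: str = "exhaustive"

    @property
    def posteriors(self) -> pd.Series:
        return self.table["posterior"]


# ------------------------------------------------------------- log likelihood

def mgsa_log_likelihood(
    active: Iterable[str],
    coll: TargetSetCollection,
    observed: Iterable[str],
    alpha_fp: float,
    beta_fn: float,
) -> float:
    """Log P(observed flags | active sets) under the noisy set-cover model.

    Hidden state of gene i is "on" iff i belongs to at least one active
    set; P(observed on | hidden off) = alpha_fp, P(observed off | hidden
    on) = beta_fn.
    """
    if not (0 < alpha_fp < 1) or not (0 < beta_fn < 1):
        raise DomainError("rates must lie strictly inside (0, 1)")
    obs = set(observed)
    extra = obs - set(coll.universe)
    if extra:
        raise ConsistencyError(f"observed genes outside universe: {sorted(extra)[:5]}")
    active = list(active)
    unknown = [a for a in active if a not in coll.sets]
    if unknown:
        raise ConsistencyError(f"unknown regulators: {unknown[:5]}")
    covered = set().union(*(coll.sets[a] for a in active)) if active else set()
    ll = 0.0
    for gene in coll.universe:
        on = gene in obs
        hid = gene in covered
        if hid:
            ll += math.log(1.0 - beta_fn) if on else math.log(beta_fn)
        else:
            ll += math.log(alpha_fp) if on else math.log(1.0 - alpha_fp)
    return ll


def _category_counts(coll: TargetSetCollection, observed: set) -> Tuple[np.ndarray, np.ndarray]:
    """Per-gene membership arrays used by both inference routes."""
    genes = list(coll.universe)
    obs = np.array([g in observed for g in genes], dtype=bool)
    regs = coll.regulators
    member = np.zeros((len(regs), len(genes)), dtype=bool)
    for i, r in enumerate(regs):
        s = coll.sets[r]
        member[i] = [g in s for g in genes]
    return member, obs


# ------------------------------------------------------------------ exhaustive

def mgsa_exhaustive(
    coll: TargetSetCollection,
    observed: Iterable[str],
    params: MgsaParams = MgsaParams(),
    max_sets: int = 20,
) -> MgsaResult:
    """Exact marginal activation posteriors by full state enumeration.

    Sums prior x likelihood over all 2^m activation states, marginalizing
    over the (possibly singleton) parameter grids with uniform grid priors.
    """
    params.validate()
    m = len(coll)
    if m == 0:
        raise ConsistencyError("empty set collection")
    if m > max_sets:
        raise SizeError(f"{m} sets exceed the exhaustive cap {max_sets}")
    member, obs = _category_counts(coll, set(observed))
    alpha = np.asarray(params.alpha_grid, dtype=float)
    beta = np.asarray(params.beta_grid, dtype=float)
    p = params.resolved_p_grid(m)
    # grid combinations and their per-category log terms
    ga, gb = np.meshgrid(alpha, beta, indexing="ij")
    ga, gb = ga.ravel(), gb.ravel()
    # categories: on&covered, on&uncovered, off&covered, off&uncovered
    log_terms = np.stack(
        [np.log(1 - gb), np.log(ga), np.log(gb), np.log(1 - ga)], axis=1
    )  # (n_ab, 4)
    states = np.arange(2**m, dtype=np.int64)
    bits = ((states[:, None] >> np.arange(m)) & 1).astype(bool)  # (2^m, m)
    cover = bits @ member.astype(np.int64) > 0  # (2^m, n_genes)
    counts = np.stack(
        [
            (cover & obs).sum(axis=1),
            (~cover & obs).sum(axis=1),
            (cover & ~obs).sum(axis=1),
            (~cover & ~obs).sum(axis=1),
        ],
        axis=1,
    ).astype(float)  # (2^m, 4)
    loglik_ab = counts @ log_terms.T  # (2^m, n_ab)
    k = bits.sum(axis=1).astype(float)
    logprior_p = k[:, None] * np.log(p)[None, :] + (m - k)[:, None] * np.log(1 - p)[None, :]
    # joint over (state, alpha-beta, p) with uniform grid priors
    log_state = logsumexp(loglik_ab, axis=1) + logsumexp(logprior_p, axis=1)
    total = logsumexp(log_state)
    post = np.empty(m)
    for i in range(m):
        post[i] = np.exp(logsumexp(log_state[bits[:, i]]) - total)
    regs = coll.regulators
    table = pd.DataFrame(
        {"set_size": [len(coll.sets[r]) for r in regs], "posterior": post},
        index=pd.Index(regs, name="regulator"),
    )
    return MgsaResult(table=table, params={"grids": (len(alpha), len(beta), len(p))},
                      method="exhaustive")


# ------------------------------------------------------------------------ MCMC

class _MgsaState:
    """Mutable MCMC state with incremental category counters."""

    def __init__(self, member: np.ndarray, obs: np.ndarray):
        self.member_lists = [np.where(row)[0] for row in member]
        self.obs = obs
        self.m = member.shape[0]
        self.n = obs.size
        self.active = np.zeros(self.m, dtype=bool)
        self.cover = np.zeros(self.n, dtype=np.int32)
        self.n_on = int(obs.sum())
        self.n_on_cov = 0
        self.n_off_cov = 0

    def loglik(self, alpha: float, beta: float) -> float:
        n_on_unc = self.n_on - self.n_on_cov
        n_off_unc = (self.n - self.n_on) - self.n_off_cov
        return (
            self.n_on_cov * math.log(1 - beta)
            + n_on_unc * math.log(alpha)
            + self.n_off_cov * math.log(beta)
            + n_off_unc * math.log(1 - alpha)
        )

    def toggle(self, j: int) -> None:
        items = self.member_lists[j]
        if self.active[j]:
            self.active[j] = False
            for g in items:
                self.cover[g] -= 1
                if self.cover[g] == 0:
                    if self.obs[g]:
                        self.n_on_cov -= 1
                    else:
                        self.n_off_cov -= 1
        else:
            self.active[j] = True
            for g in items:
                if self.cover[g] == 0:
                    if self.obs[g]:
                        self.n_on_cov += 1
                    else:
                        self.n_off_cov += 1
                self.cover[g] += 1


def mgsa_mcmc(
    coll: TargetSetCollection,
    observed: Iterable[str],
    params: MgsaParams = MgsaParams(),
) -> MgsaResult:
    """Metropolis-within-Gibbs sampler for the set-activation posterior.

    Proposals: single-bit toggles, active/inactive swaps, and grid moves of
    the nuisance parameters (alpha, beta, p).  The marginal posterior of a
    set is its post-burnin activation frequency averaged over
    ``n_restarts`` independent chains; the restart-to-restart spread is
    reported alongside.
    """
    params.validate()
    m = len(coll)
    if m == 0:
        raise ConsistencyError("empty set collection")
    member, obs = _category_counts(coll, set(observed))
    alpha = np.asarray(params.alpha_grid, dtype=float)
    beta = np.asarray(params.beta_grid, dtype=float)
    p = params.resolved_p_grid(m)
    ss = np.random.SeedSequence(params.seed)
    marginals = np.zeros((params.n_restarts, m))
    for restart, child in enumerate(ss.spawn(params.n_restarts)):
        rng = np.random.default_rng(child)
        marginals[restart] = _run_chain(member, obs, alpha, beta, p, params, rng)
    post = marginals.mean(axis=0)
    spread = marginals.max(axis=0) - marginals.min(axis=0)
    regs = coll.regulators
    table = pd.DataFrame(
        {
            "set_size": [len(coll.sets[r]) for r in regs],
            "posterior": post,
            "restart_spread": spread,
        },
        index=pd.Index(regs, name="regulator"),
    )
    return MgsaResult(
        table=table,
        params={
            "n_iter": params.n_iter,
            "burnin": params.burnin,
            "n_restarts": params.n_restarts,
            "seed": params.seed,
        },
        method="mcmc",
    )


def _run_chain(member, obs, alpha, beta, p, params, rng) -> np.ndarray:
    state = _MgsaState(member, obs)
    m = state.m
    ia = rng.integers(alpha.size)
    ib = rng.integers(beta.size)
    ip = rng.integers(p.size)
    # random initial activation at the prior's expected sparsity
    for j in range(m):
        if rng.random() < p[ip]:
            state.toggle(j)
    log_p = np.log(p)
    log_1mp = np.log(1 - p)
    cur_ll = state.loglik(alpha[ia], beta[ib])
    k = int(state.active.sum())
    counts = np.zeros(m)
    kept = 0
    n_iter, burnin = params.n_iter, params.burnin
    u_all = rng.random(n_iter)
    acc_all = rng.random(n_iter)
    for it in range(n_iter):
        u = u_all[it]
        if u < 0.5:  # toggle
            j = int(rng.integers(m))
            was_active = state.active[j]
            state.toggle(j)
            new_ll = state.loglik(alpha[ia], beta[ib])
            d_prior = (log_1mp[ip] - log_p[ip]) if was_active else (log_p[ip] - log_1mp[ip])
            if math.log(acc_all[it]) < (new_ll - cur_ll) + d_prior:
                cur_ll = new_ll
                k += -1 if was_active else 1
            else:
                state.toggle(j)
        elif u < 0.75:  # swap an active with an inactive set
            if 0 < k < m:
                act = np.where(state.active)[0]
                inact = np.where(~state.active)[0]
                j_off = int(act[rng.integers(act.size)])
                j_on = int(inact[rng.integers(inact.size)])
                state.toggle(j_off)
                state.toggle(j_on)
                new_ll = state.loglik(alpha[ia], beta[ib])
                if math.log(acc_all[it]) < new_ll - cur_ll:
                    cur_ll = new_ll
                else:
                    state.toggle(j_on)
                    state.toggle(j_off)
        else:  # grid move of one nuisance parameter
            which = int(rng.integers(3))
            if which == 0 and alpha.size > 1:
                prop = int(rng.integers(alpha.size))
                new_ll = state.loglik(alpha[prop], beta[ib])
                if math.log(acc_all[it]) < new_ll - cur_ll:
                    ia, cur_ll = prop, new_ll
            elif which == 1 and beta.size > 1:
                prop = int(rng.integers(beta.size))
                new_ll = state.loglik(alpha[ia], beta[prop])
                if math.log(acc_all[it]) < new_ll - cur_ll:
                    ib, cur_ll = prop, new_ll
            elif which == 2 and p.size > 1:
                prop = int(rng.integers(p.size))
                d = k * (log_p[prop] - log_p[ip]) + (m - k) * (log_1mp[prop] - log_1mp[ip])
                if math.log(acc_all[it]) < d:
                    ip = prop
        if it >= burnin:
            counts += state.active
            kept += 1
    return counts / max(kept, 1)


# ------------------------------------------------------------------ selection

def select_regulators(result: MgsaResult, b: float = 0.5) -> List[str]:
    """Regulators with posterior strictly above b, ranked by posterior descending."""
    if not (0 <= b <= 1):
        raise ParameterError("b must lie in [0, 1]")
    tab = result.table
    keep = tab[tab["posterior"] > b]
    order = sorted(keep.index, key=lambda r: (-keep.loc[r, "posterior"], r))
    return order


# ----------------------------------------------------------------- calibration

@dataclass
class CalibrationResult:
    """Grid scan anchored on a known positive regulator."""

    median_rank: pd.DataFrame  # regulator, median_rank + per-pi posteriors
    selected_settings: List[float]  # pi values whose list contains the known positive
    known_positive: str
    params: Dict = field(default_factory=dict)


def calibrate(
    stable,
    universe: Sequence[str],
    known_positive: str,
    secreted: Sequence[str],
    pi_grid: Sequence[float] = (0.80, 0.85, 0.90),
    q_grid: Optional[Sequence[float]] = None,
    mgsa_params: Optional[MgsaParams] = None,
    b: float = 0.5,
) -> CalibrationResult:
    """Scan retention parameters and aggregate regulator rankings.

    For each frequency threshold ``pi``, per-pair selection frequencies are
    integrated over the whole grid of top fractions ``q`` (median frequency
    across q), pairs at or above ``pi`` are retained, and the set-activation
    model is run on the resulting collection.  Regulators are then ordered
    by their median rank across the pi-specific posteriors; the settings
    whose selected list contains the known positive are reported.

    ``stable`` is a :class:`~paracrine.effects.StableEffectTable` holding
    the run-level effect matrix; the stability runs are therefore reused
    rather than repeated per grid point.
    """
    if known_positive not in set(secreted):
        raise CalibrationError(
            f"known positive {known_positive!r} is not among the secreted candidates"
        )
    if q_grid is None:
        q_grid = np.arange(0.02, 1.0001, 0.02)
    q_grid = [float(q) for q in q_grid]
    pi_grid = [float(v) for v in pi_grid]
    mgsa_params = mgsa_params or MgsaParams()
    freqs = np.stack([stable.frequencies_for(q) for q in q_grid], axis=1)
    med_freq = np.median(freqs, axis=1)
    pairs = stable.table[["x", "y"]]
    rankings: Dict[float, pd.Series] = {}
    selected_settings: List[float] = []
    ss = np.random.SeedSequence(mgsa_params.seed)
    children = ss.spawn(len(pi_grid))
    for pi, child in zip(pi_grid, children):
        retained = pairs[med_freq >= pi]
        coll = build_target_sets(retained, universe) if len(retained) else None
        if coll is None or len(coll) == 0:
            rankings[pi] = pd.Series(dtype=float)
            continue
        pp = MgsaParams(
            alpha_grid=mgsa_params.alpha_grid,
            beta_grid=mgsa_params.beta_grid,
            p_grid=mgsa_params.p_grid,
            n_iter=mgsa_params.n_iter,
            burnin=mgsa_params.burnin,
            n_restarts=mgsa_params.n_restarts,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        result = mgsa_mcmc(coll, list(universe), pp)
        rankings[pi] = result.posteriors
        if known_positive in select_regulators(result, b):
            selected_settings.append(pi)
    all_regs = sorted(set().union(*(set(r.index) for r in rankings.values())) or set())
    rank_rows = {}
    for pi, posts in rankings.items():
        order = sorted(posts.index, key=lambda r: (-posts[r], r))
        rank = {reg: i + 1 for i, reg in enumerate(order)}
        worst = len(all_regs) + 1
        rank_rows[pi] = {reg: rank.get(reg, worst) for reg in all_regs}
    med_rank = pd.DataFrame(
        {
            "median_rank": [
                float(np.median([rank_rows[pi][reg] for pi in rankings])) if rankings else np.nan
                for reg in all_regs
            ]
        },
        index=pd.Index(all_regs, name="regulator"),
    )
    for pi, posts in rankings.items():
        med_rank[f"posterior_pi_{pi:g}"] = [posts.get(reg, np.nan) for reg in all_regs]
    med_rank = med_rank.sort_values(["median_rank", "regulator"] if "regulator" in med_rank else "median_rank",
                                    kind="mergesort")
    return CalibrationResult(
        median_rank=med_rank,
        selected_settings=selected_settings,
        known_positive=known_positive,
        params={"pi_grid": pi_grid, "n_q": len(q_grid), "b": b},
    )


def median_rank_aggregate(rankings: Sequence[Sequence[str]]) -> pd.Series:
    """Median rank per item across several rankings (1-based; absent items
    get one past the longest list)."""
    items = sorted(set().union(*[set(r) for r in rankings]))
    worst = max(len(r) for r in rankings) + 1
    out = {}
    for item in items:
        ranks = [list(r).index(item) + 1 if item in r else worst for r in rankings]
        out[item] = float(np.median(ranks))
    return pd.Series(out).sort_values(kind="mergesort")
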