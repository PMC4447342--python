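"""Constraint-based CPDAG estimation over stromal genes.

Implements the order-independent (stable) variant of the PC algorithm with
Gaussian conditional-independence tests, collider orientation and Meek's
closure rules, yielding the completed partially directed acyclic graph
(CPDAG) that represents the Markov equivalence class of the stromal
regulatory network.  Tumor genes never enter: by design of the conditioned-
medium experiment they cannot influence stromal genes, and structurally
excluding them is what licenses the downstream adjustment-based effect
estimation.

Two conditional-independence backends are provided:

* the Fisher-z test on sample partial correlations, the standard test for
  multivariate Gaussian data; and
* a population oracle that thresholds exact partial correlations computed
  from a known covariance matrix, used to verify that the algorithm
  recovers the true CPDAG when the tests are infallible.

Determinism: nodes are processed in lexicographic gene-label order, the
stable variant freezes adjacency sets at the start of every level, and
conflicting collider orientations leave the contested edge undirected.
Consequently the estimated CPDAG is invariant under permutation of the
input gene order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConsistencyError,
    DomainError,
    InsufficientSampleError,
    NumericalRankError,
    ParameterError,
)
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

_SINGULAR_TOL = 1e-10


@dataclass
class CiTestConfig:
    """Significance level and optional conditioning-size cap for PC."""

    alpha: float = 0.2
    max_cond_size: Optional[int] = None

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ParameterError("alpha must lie strictly between 0 and 1")
        if self.max_cond_size is not None and self.max_cond_size < 0:
            raise ParameterError("max_cond_size must be >= 0 or None")


class Cpdag:
    """A completed partially directed acyclic graph over gene labels.

    Internally an n x n mark matrix ``amat`` with ``amat[i, j] == 1`` when
    there is an edge mark from i to j: a directed edge i -> j has
    ``amat[i, j] == 1, amat[j, i] == 0``; an undirected edge has both marks.
    """

    def __init__(self, nodes: Sequence[str], amat: Optional[np.ndarray] = None,
                 sepsets: Optional[Dict[FrozenSet[str], Tuple[str, ...]]] = None):
        self.nodes = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ConsistencyError("duplicate node labels")
        n = len(self.nodes)
        if amat is None:
            amat = np.zeros((n, n), dtype=np.int8)
        amat = np.asarray(amat, dtype=np.int8)
        if amat.shape != (n, n):
            raise ConsistencyError("amat shape does not match node count")
        if np.any(np.diag(amat)):
            raise ConsistencyError("self-loops are not allowed")
        self.amat = amat
        self._index = {g: i for i, g in enumerate(self.nodes)}
        self.sepsets = dict(sepsets or {})
        for pair in self.sepsets:
            i, j = (self._index[g] for g in pair)
            if amat[i, j] or amat[j, i]:
                raise ConsistencyError(
                    f"pair {sorted(pair)} has both an edge and a separation set"
                )

    # ------------------------------------------------------------- queries
    def index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise ConsistencyError(f"node {node!r} not in CPDAG") from None

    def has_node(self, node: str) -> bool:
        return node in self._index

    def adjacent(self, a: str, b: str) -> bool:
        i, j = self.index(a), self.index(b)
        return bool(self.amat[i, j] or self.amat[j, i])

    @property
    def directed_edges(self) -> Set[Tuple[str, str]]:
        out = set()
        n = len(self.nodes)
        for i in range(n):
            for j in range(n):
                if self.amat[i, j] and not self.amat[j, i]:
                    out.add((self.nodes[i], self.nodes[j]))
        return out

    @property
    def undirected_edges(self) -> Set[FrozenSet[str]]:
        out = set()
        n = len(self.nodes)
        for i in range(n):
            for j in range(i + 1, n):
                if self.amat[i, j] and self.amat[j, i]:
                    out.add(frozenset((self.nodes[i], self.nodes[j])))
        return out

    def parents(self, node: str) -> List[str]:
        """Certain parents: sources of directed edges into ``node``."""
        j = self.index(node)
        return sorted(
            self.nodes[i]
            for i in range(len(self.nodes))
            if self.amat[i, j] and not self.amat[j, i]
        )

    def undirected_neighbors(self, node: str) -> List[str]:
        i = self.index(node)
        return sorted(
            self.nodes[j]
            for j in range(len(self.nodes))
            if self.amat[i, j] and self.amat[j, i]
        )

    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)

    # ---------------------------------------------------------------- I/O
    def to_edgelist(self) -> pd.DataFrame:
        rows = [(u, v, "directed") for (u, v) in sorted(self.directed_edges)]
        rows += [
            (a, b, "undirected") for a, b in sorted(tuple(sorted(e)) for e in self.undirected_edges)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "type"])

    @classmethod
    def from_edgelist(cls, nodes: Sequence[str], edges: pd.DataFrame) -> "Cpdag":
        g = cls(nodes)
        for _, row in edges.iterrows():
            i, j = g.index(row["source"]), g.index(row["target"])
            g.amat[i, j] = 1
            if row["type"] == "undirected":
                g.amat[j, i] = 1
            elif row["type"] != "directed":
                raise ConsistencyError(f"unknown edge type {row['type']!r}")
        return g

    def copy(self) -> "Cpdag":
        return Cpdag(self.nodes, self.amat.copy(), dict(self.sepsets))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cpdag):
            return NotImplemented
        if self.nodes == other.nodes:
            return bool(np.array_equal(self.amat, other.amat))
        if set(self.nodes) != set(other.nodes):
            return False
        perm = [other._index[g] for g in self.nodes]
        return bool(np.array_equal(self.amat, other.amat[np.ix_(perm, perm)]))


# ------------------------------------------------------ primitive statistics

def partial_correlation(corr: np.ndarray, x: int, y: int, s: Sequence[int]) -> float:
    """Partial correlation of x and y given S from a correlation matrix.

    Computed by inverting the sub-correlation matrix on {x, y} u S:
    rho = -P_xy / sqrt(P_xx P_yy) with P the precision of the submatrix.
    Near-singular submatrices fall back to a pseudo-inverse; submatrices
    whose pseudo-inverse is degenerate on the (x, y) block raise
    :class:`NumericalRankError`.
    """
    corr = np.asarray(corr, dtype=float)
    if x == y or x in s or y in s:
        raise DomainError("x and y must be distinct and disjoint from S")
    if not s:
        return float(corr[x, y])
    idx = [x, y] + list(s)
    sub = corr[np.ix_(idx, idx)]
    try:
        prec = np.linalg.inv(sub)
        if np.linalg.cond(sub) > 1.0 / _SINGULAR_TOL:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(sub, rcond=_SINGULAR_TOL)
    denom = prec[0, 0] * prec[1, 1]
    if denom <= 0 or not np.isfinite(denom):
        raise NumericalRankError(
            f"sub-correlation matrix for ({x}, {y} | {list(s)}) is numerically singular"
        )
    r = -prec[0, 1] / np.sqrt(denom)
    return float(np.clip(r, -1.0, 1.0))


def fisher_z_dependent(r: float, n: int, s: int, alpha: float) -> bool:
    """Fisher-z decision: True when x and y are declared dependent.

    z = atanh(r); dependent iff sqrt(n - s - 3) * |z| exceeds the two-sided
    normal quantile at level alpha.
    """
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie strictly between 0 and 1")
    if n - s - 3 <= 0:
        raise InsufficientSampleError(
            f"need n - |S| - 3 > 0 (n={n}, |S|={s}); edge must be kept"
        )
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return True
    z = np.arctanh(r)
    crit = stats.norm.ppf(1.0 - alpha / 2.0)
    return bool(np.sqrt(n - s - 3) * abs(z) > crit)


# Decision callables map |partial r| arrays to boolean "dependent" arrays.

def _fisher_decision(n: int, alpha: float) -> Callable[[np.ndarray, int], np.ndarray]:
    crit = stats.norm.ppf(1.0 - alpha / 2.0)

    def decide(r_abs: np.ndarray, cond_size: int) -> np.ndarray:
        dof = n - cond_size - 3
        if dof <= 0:
            logger.warning(
                "insufficient samples for conditioning size %d (n=%d); keeping edges",
                cond_size, n,
            )
            return np.ones_like(np.asarray(r_abs, dtype=float), dtype=bool)
        z = np.arctanh(np.clip(np.asarray(r_abs, dtype=float), 0.0, 1.0 - 1e-16))
        return np.sqrt(dof) * z > crit

    return decide


def _oracle_decision(tol: float = 1e-8) -> Callable[[np.ndarray, int], np.ndarray]:
    def decide(r_abs: np.ndarray, cond_size: int) -> np.ndarray:
        return np.asarray(r_abs, dtype=float) > tol

    return decide


# --------------------------------------------------------------- PC skeleton

def _skeleton(
    corr: np.ndarray,
    decide: Callable[[np.ndarray, int], np.ndarray],
    max_cond_size: Optional[int] = None,
) -> Tuple[np.ndarray, Dict[FrozenSet[int], Tuple[int, ...]]]:
    """Stable-PC skeleton on a correlation matrix.

    Returns (boolean adjacency, sepsets keyed by index pairs).  Adjacency
    snapshots are frozen at the start of each level and candidate
    conditioning sets are enumerated in sorted index order, which makes the
    result independent of edge-processing order.
    """
    n = corr.shape[0]
    adj = np.ones((n, n), dtype=bool)
    np.fill_diagonal(adj, False)
    sepsets: Dict[FrozenSet[int], Tuple[int, ...]] = {}

    # level 0: marginal correlations, fully vectorized
    dep = decide(np.abs(corr), 0)
    removed = adj & ~dep & ~dep.T  # decision is symmetric, but be safe
    for i, j in zip(*np.where(np.triu(removed, 1))):
        sepsets[frozenset((int(i), int(j)))] = ()
    adj &= dep | dep.T

    level = 1
    while True:
        if max_cond_size is not None and level > max_cond_size:
            break
        snapshot = [np.where(adj[i])[0] for i in range(n)]
        pairs = [(i, j) for i, j in zip(*np.where(np.triu(adj, 1)))]
        any_candidates = False
        for i, j in pairs:
            if not adj[i, j]:
                continue
            cand_i = [k for k in snapshot[i] if k != j]
            cand_j = [k for k in snapshot[j] if k != i]
            if len(cand_i) < level and len(cand_j) < level:
                continue
            any_candidates = True
            if level == 1:
                if _try_remove_level1(corr, decide, adj, sepsets, i, j, cand_i, cand_j):
                    continue
            else:
                if _try_remove_highlevel(
                    corr, decide, adj, sepsets, i, j, cand_i, cand_j, level
                ):
                    continue
        if not any_candidates:
            break
        level += 1
    return adj, sepsets


def _try_remove_level1(corr, decide, adj, sepsets, i, j, cand_i, cand_j) -> bool:
    seen: Set[int] = set()
    cands: List[int] = []
    for k in list(cand_i) + list(cand_j):
        if k not in seen:
            seen.add(k)
            cands.append(int(k))
    if not cands:
        return False
    ks = np.array(cands)
    r_ij = corr[i, j]
    r_ik = corr[i, ks]
    r_jk = corr[j, ks]
    denom = (1.0 - r_ik**2) * (1.0 - r_jk**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pr = (r_ij - r_ik * r_jk) / np.sqrt(denom)
    pr = np.where(denom <= _SINGULAR_TOL, 1.0, pr)  # collinear: keep dependent
    pr = np.clip(np.nan_to_num(pr, nan=1.0), -1.0, 1.0)
    dep = decide(np.abs(pr), 1)
    indep = np.where(~dep)[0]
    if indep.size:
        k = int(ks[indep[0]])
        adj[i, j] = adj[j, i] = False
        sepsets[frozenset((int(i), int(j)))] = (k,)
        return True
    return False


def _try_remove_highlevel(corr, decide, adj, sepsets, i, j, cand_i, cand_j, level) -> bool:
    tried: Set[Tuple[int, ...]] = set()
    for cands in (cand_i, cand_j):
        if len(cands) < level:
            continue
        for s in combinations(sorted(int(k) for k in cands), level):
            if s in tried:
                continue
            tried.add(s)
            try:
                pr = partial_correlation(corr, int(i), int(j), list(s))
            except NumericalRankError:
                continue  # keep the edge for this subset
            if not decide(np.array([abs(pr)]), level)[0]:
                adj[i, j] = adj[j, i] = False
                sepsets[frozenset((int(i), int(j)))] = s
                return True
    return False


# -------------------------------------------------------------- orientation

def _v_structures(amat: np.ndarray) -> Set[Tuple[int, int, int]]:
    """Colliders (a, c, b) with a -> c <- b and a, b non-adjacent."""
    n = amat.shape[0]
    out = set()
    directed = (amat == 1) & (amat.T == 0)
    for c in range(n):
        ps = np.where(directed[:, c])[0]
        for a, b in combinations(ps, 2):
            if not (amat[a, b] or amat[b, a]):
                out.add((min(a, b), c, max(a, b)))
    return out


def _meek_closure(amat: np.ndarray, frozen=frozenset()) -> np.ndarray:
    """Apply Meek rules R1-R4 until fixpoint.  Conservative: a rule that
    would reverse an existing directed edge is skipped (and logged), and
    edges in ``frozen`` (contested v-structure orientations) stay
    undirected."""
    n = amat.shape[0]

    def directed(i, j):
        return amat[i, j] == 1 and amat[j, i] == 0

    def undirected(i, j):
        return amat[i, j] == 1 and amat[j, i] == 1

    def adjacent(i, j):
        return amat[i, j] == 1 or amat[j, i] == 1

    def orient(a, b) -> bool:
        if frozenset((a, b)) in frozen:
            return False
        if undirected(a, b):
            amat[b, a] = 0
            return True
        if directed(b, a):
            logger.info("Meek rule conflict on edge (%d, %d); leaving as is", a, b)
        return False

    changed = True
    while changed:
        changed = False
        und = [(a, b) for a in range(n) for b in range(n) if a != b and undirected(a, b)]
        for a, b in und:
            if not undirected(a, b):
                continue
            # R1: c -> a, a - b, c and b non-adjacent  =>  a -> b
            done = False
            for c in range(n):
                if c not in (a, b) and directed(c, a) and not adjacent(c, b):
                    changed |= orient(a, b)
                    done = True
                    break
            if done:
                continue
            # R2: a -> c -> b and a - b  =>  a -> b
            for c in range(n):
                if c not in (a, b) and directed(a, c) and directed(c, b):
                    changed |= orient(a, b)
                    done = True
                    break
            if done:
                continue
            # R3: a - c -> b, a - d -> b, c and d non-adjacent  =>  a -> b
            cs = [
                c
                for c in range(n)
                if c not in (a, b) and undirected(a, c) and directed(c, b)
            ]
            for c, d in combinations(cs, 2):
                if not adjacent(c, d):
                    changed |= orient(a, b)
                    done = True
                    break
            if done:
                continue
            # R4: a - c -> d -> b with a adjacent to d, c and b non-adjacent
            for c in range(n):
                if c in (a, b) or not undirected(a, c) or adjacent(c, b):
                    continue
                for d in range(n):
                    if d in (a, b, c):
                        continue
                    if directed(c, d) and directed(d, b) and adjacent(a, d):
                        changed |= orient(a, b)
                        done = True
                        break
                if done:
                    break
    return amat


def orient_cpdag(
    skeleton: np.ndarray,
    sepsets: Dict[FrozenSet[int], Tuple[int, ...]],
    labels: Sequence[str],
) -> Cpdag:
    """Orient v-structures from separation sets, then close under Meek rules.

    For every unshielded triple a - c - b with a, b non-adjacent, orient
    a -> c <- b iff c is not in sepset(a, b).  When two triples demand
    opposite orientations of the same edge, the edge is left undirected
    (logged) - the conservative resolution that keeps the output a valid
    partially directed graph.
    """
    n = skeleton.shape[0]
    amat = skeleton.astype(np.int8)
    votes: Dict[Tuple[int, int], int] = {}
    for c in range(n):
        nbrs = np.where(skeleton[c])[0]
        for a, b in combinations(nbrs, 2):
            if skeleton[a, b]:
                continue
            sep = sepsets.get(frozenset((int(a), int(b))))
            if sep is None:
                continue  # pair never separated (test failure); no evidence
            if c not in sep:
                votes[(int(a), int(c))] = votes.get((int(a), int(c)), 0) + 1
                votes[(int(b), int(c))] = votes.get((int(b), int(c)), 0) + 1
    contested = set()
    for (a, c) in votes:
        if (c, a) in votes:
            contested.add(frozenset((a, c)))
            logger.info(
                "conflicting v-structure orientations on edge (%s, %s); left undirected",
                labels[a], labels[c],
            )
    for (a, c) in votes:
        if frozenset((a, c)) in contested:
            continue
        if amat[a, c] and amat[c, a]:
            amat[c, a] = 0
    amat = _meek_closure(amat, frozenset(contested))
    named_sepsets = {
        frozenset(labels[i] for i in pair): tuple(labels[k] for k in sep)
        for pair, sep in sepsets.items()
    }
    return Cpdag(list(labels), amat, named_sepsets)


# ------------------------------------------------------------- entry points

def estimate_skeleton(
    data: ExpressionMatrix, cfg: CiTestConfig = CiTestConfig()
) -> Tuple[np.ndarray, Dict[FrozenSet[int], Tuple[int, ...]], List[str]]:
    """PC-stable skeleton from standardized expression data.

    Returns (adjacency, sepsets over node indices, lexicographically sorted
    gene labels defining the index order).
    """
    if data.n_samples < 4:
        raise ParameterError("need at least 4 samples for skeleton estimation")
    labels = sorted(data.genes)
    vals = data.subset_genes(labels).array()
    corr = np.corrcoef(vals)
    decide = _fisher_decision(data.n_samples, cfg.alpha)
    adj, seps = _skeleton(corr, decide, cfg.max_cond_size)
    return adj, seps, labels


def pc(
    data: ExpressionMatrix,
    alpha: float = 0.2,
    max_cond_size: Optional[int] = None,
) -> Cpdag:
    """PC-stable CPDAG estimate from (standardized) expression data."""
    cfg = CiTestConfig(alpha=alpha, max_cond_size=max_cond_size)
    adj, seps, labels = estimate_skeleton(data, cfg)
    return orient_cpdag(adj, seps, labels)


def pc_from_corr(
    corr: np.ndarray,
    n: int,
    labels: Sequence[str],
    alpha: float = 0.2,
    max_cond_size: Optional[int] = None,
) -> Cpdag:
    """PC-stable CPDAG from a precomputed correlation matrix (labels define order)."""
    cfg = CiTestConfig(alpha=alpha, max_cond_size=max_cond_size)
    decide = _fisher_decision(n, cfg.alpha)
    adj, seps = _skeleton(np.asarray(corr, dtype=float), decide, cfg.max_cond_size)
    return orient_cpdag(adj, seps, list(labels))


def pc_oracle(cov: pd.DataFrame, tol: float = 1e-8) -> Cpdag:
    """PC with infallible population tests: thresholds exact partial
    correlations derived from the supplied covariance matrix."""
    labels = sorted(cov.index)
    c = cov.loc[labels, labels].to_numpy()
    d = np.sqrt(np.diag(c))
    corr = c / np.outer(d, d)
    adj, seps = _skeleton(corr, _oracle_decision(tol), None)
    return orient_cpdag(adj, seps, labels)


def dag_to_cpdag(edges: Sequence[Tuple[str, str]], nodes: Sequence[str]) -> Cpdag:
    """The CPDAG of a DAG: skeleton plus v-structures, closed under Meek rules."""
    labels = sorted(nodes)
    idx = {g: i for i, g in enumerate(labels)}
    n = len(labels)
    directed = np.zeros((n, n), dtype=bool)
    for (u, v) in edges:
        directed[idx[u], idx[v]] = True
    if not _is_acyclic(directed):
        raise ConsistencyError("input edges contain a directed cycle")
    skeleton = directed | directed.T
    amat = skeleton.astype(np.int8)
    for c in range(n):
        ps = np.where(directed[:, c])[0]
        for a, b in combinations(ps, 2):
            if not skeleton[a, b]:
                amat[c, a] = 0
                amat[c, b] = 0
    amat = _meek_closure(amat)
    return Cpdag(labels, amat)


def _is_acyclic(directed: np.ndarray) -> bool:
    n = directed.shape[0]
    indeg = directed.sum(axis=0).astype(int)
    stack = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    work = directed.copy()
    while stack:
        i = stack.pop()
        seen += 1
        for j in np.where(work[i])[0]:
            work[i, j] = False
            indeg[j] -= 1
            if indeg[j] == 0:
                stack.append(int(j))
    return seen == n


def shd(a: Cpdag, b: Cpdag) -> int:
    """Structural Hamming distance between two CPDAGs on the same nodes.

    For every unordered node pair the edge state (none, undirected, either
    direction) is compared; each mismatch counts one.
    """
    if set(a.nodes) != set(b.nodes):
        raise ConsistencyError("CPDAGs have different node sets")
    labels = sorted(a.nodes)
    pa = [a.index(g) for g in labels]
    pb = [b.index(g) for g in labels]
    am = a.amat[np.ix_(pa, pa)]
    bm = b.amat[np.ix_(pb, pb)]
    dist = 0
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if (am[i, j], am[j, i]) != (bm[i, j], bm[j, i]):
                dist += 1
    return dist
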