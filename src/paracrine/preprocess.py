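"""Differential expression and the gene-selection cascade.

This module provides the empirical-Bayes moderated two-sample t test used to
contrast stimulated and unstimulated tumor cultures, Benjamini-Hochberg FDR
control, and the filters that turn an annotated stromal expression matrix
into (a) the candidate secreted regulators, (b) the stromal network gene
set for causal discovery, and (c) the tumor target genes.

The moderated t statistic shrinks gene-wise sample variances toward a
pooled prior fitted by moment matching on the log variances (a scaled
inverse-chi-square prior, Smyth-style):

    s_tilde_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)
    t_g = (mean_case - mean_control) / (s_tilde_g * sqrt(1/n1 + 1/n2))

with ``d = n1 + n2 - 2`` residual and ``d0`` prior degrees of freedom; the
null distribution is t with ``d + d0`` degrees of freedom.  With ``d0 = 0``
this is the ordinary pooled-variance two-sample t; with ``d0 = inf`` every
gene shares the pooled prior variance.

All selection thresholds are strict inequalities (q < q_max,
|log2FC| > lfc_min, |r| > cutoff) and ties at ranking cutoffs are broken by
lexicographic gene id, so the selected sets are invariant to input order.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import (
    ConsistencyError,
    DegenerateGeneError,
    DomainError,
    InsufficientReplicationError,
    PairingError,
    ParameterError,
)
from .matrix import ExpressionMatrix

FLAG_COLUMNS = ["secreted_annotation", "receptor", "growth_factor", "detected_in_cm"]


# ------------------------------------------------------------------ moderated t

def _trigamma_inverse(y: np.ndarray) -> np.ndarray:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    y = np.asarray(y, dtype=float)
    x = 0.5 + 1.0 / y
    small = y < 1e-6
    large = y > 1e7
    x = np.where(small, 1.0 / y, x)
    x = np.where(large, 1.0 / np.sqrt(y), x)
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.all(np.abs(dif) < 1e-10 * x):
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> Tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to gene variances.

    Returns ``(d0, s0_sq)``; ``d0`` may be ``inf`` when the observed spread
    of log variances is no larger than expected from sampling alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if not ok.any():
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(emean))
    evar = float(np.sum((e - emean) ** 2) / (n - 1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = float(2.0 * _trigamma_inverse(np.array([evar]))[0])
    s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def moderated_t_test(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    prior_df: Optional[float] = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated t test of case vs control, per gene.

    Parameters
    ----------
    case, control:
        Matrices over identical gene sets with >= 2 samples each.
    prior_df:
        Override the estimated prior degrees of freedom; ``0`` gives the
        ordinary pooled two-sample t, ``inf`` full pooling across genes.

    Returns
    -------
    DataFrame indexed by gene with columns ``log2_fold_change``,
    ``moderated_t``, ``p_value`` and BH-adjusted ``q_value``.
    """
    if case.n_samples < 2 or control.n_samples < 2:
        raise InsufficientReplicationError("need >= 2 samples in each group")
    if list(case.genes) != list(control.genes):
        if set(case.genes) != set(control.genes):
            raise ConsistencyError("case and control gene sets differ")
        control = control.subset_genes(case.genes)
    a = case.array()
    b = control.array()
    n1, n2 = a.shape[1], b.shape[1]
    df_resid = n1 + n2 - 2
    m1 = a.mean(axis=1)
    m2 = b.mean(axis=1)
    lfc = m1 - m2
    ss = ((a - m1[:, None]) ** 2).sum(axis=1) + ((b - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    if prior_df is None:
        d0, s0_sq = fit_variance_prior(s2, df_resid)
    else:
        if prior_df < 0:
            raise ParameterError("prior_df must be >= 0")
        d0 = float(prior_df)
        _, s0_sq = fit_variance_prior(s2, df_resid)
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        post = s2
        df_total = df_resid
    else:
        post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, 0.0)
    t = np.where(lfc == 0, 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "moderated_t": t,
            "p_value": p,
            "q_value": q,
        },
        index=pd.Index(case.genes, name="gene_id"),
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    out.attrs["residual_df"] = df_resid
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DomainError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ------------------------------------------------------------- gene selection

def select_target_genes(
    de: pd.DataFrame, q_max: float = 0.001, lfc_min: float = 1.0
) -> List[str]:
    """Tumor genes with q < q_max and |log2FC| > lfc_min (both strict)."""
    keep = (de["q_value"] < q_max) & (de["log2_fold_change"].abs() > lfc_min)
    return list(de.index[keep])


def _check_flags(flags: pd.DataFrame, genes: Sequence[str]) -> pd.DataFrame:
    missing_cols = [c for c in FLAG_COLUMNS if c not in flags.columns]
    if missing_cols:
        raise ConsistencyError(f"flags table lacks columns {missing_cols}")
    missing = [g for g in genes if g not in flags.index]
    if missing:
        raise ConsistencyError(f"genes without flag rows: {missing[:5]}")
    return flags.loc[list(genes), FLAG_COLUMNS].astype(bool)


def _iqr(values: np.ndarray) -> np.ndarray:
    q75 = np.percentile(values, 75, axis=1)
    q25 = np.percentile(values, 25, axis=1)
    return q75 - q25


def select_secreted_candidates(
    stromal: ExpressionMatrix,
    flags: pd.DataFrame,
    expression_percentile: float = 40.0,
    iqr_drop_fraction: float = 0.20,
    with_audit: bool = False,
):
    """The ordered secreted-candidate filter cascade.

    1. keep genes annotated secreted/extracellular;
    2. remove annotated receptors;
    3. keep genes whose maximum expression over stromal samples exceeds the
       global 40th percentile of all (gene, sample) entries of the matrix;
    4. among the survivors, drop the lowest 20% by inter-quartile range
       across samples (ties broken by gene id);
    5. keep genes detected in conditioned medium or annotated growth factor.

    Returns the candidate list (and a per-filter survivor audit when
    ``with_audit`` is true).  An empty survivor set is a warning, not an
    error.
    """
    fl = _check_flags(flags, stromal.genes)
    audit = {"input": stromal.n_genes}
    g1 = [g for g in stromal.genes if fl.loc[g, "secreted_annotation"]]
    audit["secreted_annotation"] = len(g1)
    g2 = [g for g in g1 if not fl.loc[g, "receptor"]]
    audit["not_receptor"] = len(g2)
    threshold = float(np.percentile(stromal.array(), expression_percentile))
    audit["expression_threshold"] = threshold
    vals = stromal.values
    g3 = [g for g in g2 if vals.loc[g].max() > threshold]
    audit["expressed"] = len(g3)
    if g3:
        iqr = pd.Series(_iqr(vals.loc[g3].to_numpy()), index=g3)
        n_drop = int(np.floor(iqr_drop_fraction * len(g3)))
        dropped = set(iqr.sort_values(kind="mergesort").index[:n_drop])
        g4 = [g for g in g3 if g not in dropped]
    else:
        g4 = []
    audit["iqr_filter"] = len(g4)
    g5 = [g for g in g4 if fl.loc[g, "detected_in_cm"] or fl.loc[g, "growth_factor"]]
    audit["detected_or_growth_factor"] = len(g5)
    if not g5:
        warnings.warn("secreted-candidate cascade left no genes", stacklevel=2)
    if with_audit:
        return g5, audit
    return g5


def select_network_genes(
    stromal: ExpressionMatrix,
    secreted: Sequence[str],
    total: int = 2000,
    expression_percentile: float = 40.0,
    min_samples_above: int = 3,
) -> List[str]:
    """Secreted candidates plus the most expressed/variable remaining genes.

    Non-secreted genes qualify when at least ``min_samples_above`` samples
    exceed the global expression percentile; qualifiers are ranked by
    inter-quartile range descending (ties by gene id ascending) and the top
    ``total - len(secreted)`` are added.  When fewer qualify, all qualifiers
    are returned with a shortfall warning.
    """
    secreted = list(secreted)
    if total < len(secreted):
        raise ParameterError("total network size is below the secreted candidate count")
    missing = [g for g in secreted if g not in stromal.values.index]
    if missing:
        raise ConsistencyError(f"secreted genes absent from stromal matrix: {missing[:5]}")
    threshold = float(np.percentile(stromal.array(), expression_percentile))
    others = [g for g in stromal.genes if g not in set(secreted)]
    vals = stromal.values
    qual = [g for g in others if int((vals.loc[g] > threshold).sum()) >= min_samples_above]
    if qual:
        iqr = pd.Series(_iqr(vals.loc[qual].to_numpy()), index=qual)
        ranked = sorted(qual, key=lambda g: (-iqr[g], g))
    else:
        ranked = []
    want = total - len(secreted)
    if len(ranked) < want:
        warnings.warn(
            f"network gene shortfall: wanted {want} non-secreted qualifiers, got {len(ranked)}",
            stacklevel=2,
        )
    return secreted + ranked[:want]


def standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Center every gene to mean 0 and scale to sample SD 1 (denominator n-1)."""
    vals = matrix.array()
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    bad = ~(sd > 0) | ~np.isfinite(sd)
    if bad.any():
        gene = matrix.genes[int(np.argmax(bad))]
        raise DegenerateGeneError(f"gene {gene!r} has zero variance; cannot standardize")
    out = (vals - mean[:, None]) / sd[:, None]
    return ExpressionMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.sample_role,
    )


def correlation_baseline(
    secreted_data: ExpressionMatrix,
    target_data: ExpressionMatrix,
    cutoff: float = 0.7,
) -> pd.Series:
    """Per secreted gene: how many target genes it correlates with (|r| > cutoff).

    The naive association analysis the causal pipeline improves on: with
    paired samples, count target genes whose absolute Pearson correlation
    with the secreted gene exceeds the cutoff.  Returned ranked descending.
    """
    if secreted_data.n_samples != target_data.n_samples:
        raise PairingError(
            f"unpaired samples: {secreted_data.n_samples} stromal vs "
            f"{target_data.n_samples} tumor"
        )
    xs = secreted_data.array()
    ys = target_data.array()
    xs_c = xs - xs.mean(axis=1, keepdims=True)
    ys_c = ys - ys.mean(axis=1, keepdims=True)
    xn = np.sqrt((xs_c**2).sum(axis=1))
    yn = np.sqrt((ys_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xs_c @ ys_c.T) / np.outer(xn, yn)
    r = np.nan_to_num(r, nan=0.0)
    counts = (np.abs(r) > cutoff).sum(axis=1)
    out = pd.Series(counts, index=secreted_data.genes, name="n_correlated")
    return out.sort_values(ascending=False, kind="mergesort")


def high_variance_subset(matrix: ExpressionMatrix, top_n: int = 200) -> List[str]:
    """The top_n genes by sample variance, ties broken lexicographically."""
    if top_n > matrix.n_genes:
        raise ParameterError("top_n exceeds the gene count")
    var = pd.Series(matrix.array().var(axis=1, ddof=1), index=matrix.genes)
    ranked = sorted(matrix.genes, key=lambda g: (-var[g], g))
    return ranked[:top_n]
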