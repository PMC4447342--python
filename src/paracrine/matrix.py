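"""Gene-by-sample expression container.

The pipeline works on log2-scale, normalized expression matrices with genes
in rows and samples in columns.  :class:`ExpressionMatrix` wraps a pandas
DataFrame, enforces unique gene identifiers and complete numeric values, and
carries an optional per-sample role annotation (``stromal``,
``tumor_stimulated`` or ``tumor_control``).  Paired stromal and stimulated
tumor samples are aligned by column position: column *i* of the stromal
matrix is the donor whose conditioned medium stimulated column *i* of the
stimulated tumor matrix.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, ParseError

SAMPLE_ROLES = ("stromal", "tumor_stimulated", "tumor_control")


class ExpressionMatrix:
    """A validated genes x samples matrix of log2 expression values."""

    def __init__(self, values: pd.DataFrame, sample_role: Optional[pd.Series] = None):
        if not isinstance(values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame (genes x samples)")
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ConsistencyError(f"duplicate gene id: {dup!r}")
        if values.columns.duplicated().any():
            dup = values.columns[values.columns.duplicated()][0]
            raise ConsistencyError(f"duplicate sample id: {dup!r}")
        try:
            values = values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric expression values: {exc}") from exc
        if values.isna().any().any():
            gene = values.index[values.isna().any(axis=1)][0]
            raise ConsistencyError(f"missing value in gene {gene!r}")
        self.values = values
        if sample_role is not None:
            sample_role = pd.Series(sample_role)
            missing = [s for s in values.columns if s not in sample_role.index]
            if missing:
                raise ConsistencyError(f"samples without role annotation: {missing[:5]}")
            bad = set(sample_role.loc[values.columns]) - set(SAMPLE_ROLES)
            if bad:
                raise ConsistencyError(f"unknown sample roles: {sorted(bad)}")
            sample_role = sample_role.loc[values.columns]
        self.sample_role = sample_role

    # ------------------------------------------------------------------ views
    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ConsistencyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.sample_role)

    def subset_samples(self, samples: Sequence) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise ConsistencyError(f"samples absent from matrix: {missing[:5]}")
        role = self.sample_role.loc[list(samples)] if self.sample_role is not None else None
        return ExpressionMatrix(self.values[list(samples)], role)

    def take_samples(self, positions: Iterable[int]) -> "ExpressionMatrix":
        """Positional column subset (used for paired subsampling)."""
        cols = [self.values.columns[i] for i in positions]
        return self.subset_samples(cols)

    def by_role(self, role: str) -> "ExpressionMatrix":
        if self.sample_role is None:
            raise ConsistencyError("matrix has no sample role annotation")
        if role not in SAMPLE_ROLES:
            raise ConsistencyError(f"unknown role {role!r}")
        cols = [s for s in self.values.columns if self.sample_role[s] == role]
        return self.subset_samples(cols)

    def array(self) -> np.ndarray:
        return self.values.to_numpy()

    # ------------------------------------------------------------------- I/O
    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def read_tsv(cls, path, sample_role: Optional[pd.Series] = None) -> "ExpressionMatrix":
        try:
            raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ParseError(f"cannot parse {path}: {exc}") from exc
        if raw.index.duplicated().any():
            dup = raw.index[raw.index.duplicated()][0]
            raise ParseError(f"{path}: duplicate gene id {dup!r}")
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        if coerced.isna().any().any():
            bad = np.argwhere(coerced.isna().to_numpy())
            r, c = bad[0]
            raise ParseError(
                f"{path}: non-numeric value {raw.iat[r, c]!r} at gene "
                f"{raw.index[r]!r}, sample {raw.columns[c]!r}"
            )
        # exact (correctly rounded) parse; pd.to_numeric's fast path is lossy
        values = raw.astype(float)
        return cls(values, sample_role)

    def __eq__(self, other) -> bool:  # value equality, used in round-trip tests
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"
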