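"""Readers and writers for the pipeline's tab-delimited artifacts.

Every artifact the pipeline emits can be re-read by the functions here:
expression matrices (genes in rows, first column gene id), sample role
tables, gene-flag tables, CPDAG edge lists plus separation sets, stable
effect tables and run reports.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .effects import StableEffectTable
from .exceptions import ParseError
from .matrix import ExpressionMatrix
from .network import Cpdag
from .preprocess import FLAG_COLUMNS


def load_expression(path, sample_role: Optional[pd.Series] = None) -> ExpressionMatrix:
    """Read a gene x sample TSV matrix (validates ids and numeric cells)."""
    return ExpressionMatrix.read_tsv(path, sample_role)


def save_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_tsv(path)


def load_sample_roles(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns or "role" not in df.columns:
        raise ParseError(f"{path}: expected columns sample_id and role")
    return pd.Series(df["role"].to_numpy(), index=df["sample_id"].to_numpy())


def load_flags(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in FLAG_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: flags table lacks columns {missing}")
    return df[FLAG_COLUMNS].astype(bool)


def save_flags(flags: pd.DataFrame, path) -> None:
    out = flags[FLAG_COLUMNS].astype(int).copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def save_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def load_gene_list(path) -> list:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def save_cpdag(cpdag: Cpdag, edge_path, sepset_path=None) -> None:
    cpdag.to_edgelist().to_csv(edge_path, sep="\t", index=False)
    if sepset_path is not None:
        payload = {
            "nodes": cpdag.nodes,
            "sepsets": [
                {"pair": sorted(pair), "sepset": list(sep)}
                for pair, sep in sorted(cpdag.sepsets.items(), key=lambda kv: sorted(kv[0]))
            ],
        }
        Path(sepset_path).write_text(json.dumps(payload, indent=1))


def load_cpdag(edge_path, sepset_path=None) -> Cpdag:
    edges = pd.read_csv(edge_path, sep="\t")
    if sepset_path is not None:
        payload = json.loads(Path(sepset_path).read_text())
        nodes = payload["nodes"]
        seps = {
            frozenset(entry["pair"]): tuple(entry["sepset"])
            for entry in payload["sepsets"]
        }
    else:
        nodes = sorted(set(edges["source"]) | set(edges["target"]))
        seps = None
    g = Cpdag.from_edgelist(nodes, edges)
    if seps:
        g.sepsets = seps
    return g


def save_stable_effects(stable: StableEffectTable, table_path, params_path=None) -> None:
    stable.table.to_csv(table_path, sep="\t", index=False, float_format="%.17g")
    if params_path is not None:
        Path(params_path).write_text(json.dumps(stable.params, indent=1))


def load_stable_effects(table_path, params_path=None) -> StableEffectTable:
    table = pd.read_csv(table_path, sep="\t")
    params = json.loads(Path(params_path).read_text()) if params_path else {}
    return StableEffectTable(table=table, params=params, lower_bounds=None)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def split_tumor(tumor: ExpressionMatrix) -> Tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split a combined tumor matrix into (stimulated, controls) by role."""
    return tumor.by_role("tumor_stimulated"), tumor.by_role("tumor_control")


def derive_seed(master: int, stage: str) -> int:
    """Stage seed derived from the master seed.

    Deterministic key-derivation: the stage name is hashed to a 32-bit
    salt, and ``SeedSequence([master, salt])`` yields the stage seed (kept
    below 2^31), so any stage can be rerun in isolation reproducibly.
    """
    salt = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    ss = np.random.SeedSequence([int(master), salt])
    return int(ss.generate_state(1)[0] % (2**31))
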