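"""Seeded end-to-end orchestration of the stroma->tumor analysis.

``run_pipeline`` wires the stages together: differential expression of
stimulated vs control tumor samples, the gene-selection cascade, PC + IDA
under subsampling stability selection, target-set construction and the
Bayesian set-activation condensation.  Every intermediate artifact is
written to the output directory; the JSON run report records per-filter
survivor counts, parameters, the seed, wall time and content hashes of the
inputs, so identical configurations produce identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from . import io as pio
from .effects import StabilityConfig, stability_selection
from .exceptions import ConsistencyError, ParacrineError, PipelineStageError
from .matrix import ExpressionMatrix
from .mgsa import MgsaParams, build_target_sets, mgsa_mcmc, select_regulators
from .preprocess import (
    moderated_t_test,
    select_network_genes,
    select_secreted_candidates,
    select_target_genes,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All file paths and stage parameters of one pipeline run."""

    stromal_path: str = "stromal.tsv"
    tumor_path: str = "tumor.tsv"
    samples_path: str = "samples.tsv"
    flags_path: str = "flags.tsv"
    outdir: str = "out"
    q_max: float = 0.001
    lfc_min: float = 1.0
    network_total: int = 2000
    alpha: float = 0.2
    n_runs: int = 100
    subsample_size: Optional[int] = None
    top_fraction: float = 0.30
    freq_threshold: float = 0.7
    max_cond_size: Optional[int] = None
    effect_mode: str = "absolute"
    mgsa_n_iter: int = 200_000
    mgsa_burnin: int = 50_000
    mgsa_restarts: int = 5
    b: float = 0.5
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclass
class PipelineReport:
    report: Dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.report[key]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ParacrineError as exc:
                if isinstance(exc, PipelineStageError):
                    raise
                raise PipelineStageError(name, str(exc)) from exc
            except FileNotFoundError as exc:
                raise PipelineStageError(name, f"missing input file: {exc}") from exc
        return inner
    return wrap


@_stage("load")
def _load_inputs(config: PipelineConfig):
    roles = pio.load_sample_roles(config.samples_path)
    stromal = pio.load_expression(config.stromal_path, roles)
    tumor = pio.load_expression(config.tumor_path, roles)
    flags = pio.load_flags(config.flags_path)
    stim, ctrl = pio.split_tumor(tumor)
    if stim.n_samples != stromal.n_samples:
        raise ConsistencyError(
            f"{stromal.n_samples} stromal vs {stim.n_samples} stimulated samples"
        )
    return stromal, stim, ctrl, flags


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages; returns (and writes) the machine-readable report."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict = {
        "parameters": asdict(config),
        "seed": config.seed,
        "input_hashes": {},
    }
    for key in ("stromal_path", "tumor_path", "samples_path", "flags_path"):
        path = getattr(config, key)
        if Path(path).exists():
            report["input_hashes"][key] = pio.sha256_of(path)

    stromal, stim, ctrl, flags = _load_inputs(config)
    logger.info("loaded %s stromal / %s stimulated / %s control samples",
                stromal.n_samples, stim.n_samples, ctrl.n_samples)

    de = _stage("differential_expression")(moderated_t_test)(stim, ctrl)
    de.to_csv(outdir / "de.tsv", sep="\t", float_format="%.17g")
    targets = _stage("differential_expression")(select_target_genes)(
        de, config.q_max, config.lfc_min
    )
    pio.save_gene_list(targets, outdir / "target_genes.txt")

    secreted, audit = _stage("gene_selection")(select_secreted_candidates)(
        stromal, flags, with_audit=True
    )
    pio.save_gene_list(secreted, outdir / "secreted_candidates.txt")
    network = _stage("gene_selection")(select_network_genes)(
        stromal, secreted, total=config.network_total
    )
    pio.save_gene_list(network, outdir / "network_genes.txt")
    overlap = set(network) & set(targets)
    if overlap:
        raise PipelineStageError(
            "gene_selection", f"network and target gene sets overlap: {sorted(overlap)[:5]}"
        )
    report["selection"] = {
        "secreted_audit": audit,
        "n_secreted_candidates": len(secreted),
        "n_network_genes": len(network),
        "n_target_genes": len(targets),
    }

    stab_cfg = StabilityConfig(
        n_runs=config.n_runs,
        subsample_size=config.subsample_size,
        alpha=config.alpha,
        top_fraction=config.top_fraction,
        freq_threshold=config.freq_threshold,
        max_cond_size=config.max_cond_size,
        effect_mode=config.effect_mode,
        seed=pio.derive_seed(config.seed, "stability"),
    )
    stable = _stage("stability_selection")(stability_selection)(
        stromal.subset_genes(network), stim.subset_genes(targets), secreted, targets, stab_cfg
    )
    pio.save_stable_effects(stable, outdir / "stable_effects.tsv", outdir / "stability_params.json")
    retained = stable.retained()
    report["stability"] = {
        "n_pairs": int(len(stable.table)),
        "n_retained_pairs": int(len(retained)),
    }

    coll = _stage("regulator_selection")(build_target_sets)(retained, targets)
    (outdir / "target_sets.json").write_text(
        json.dumps({r: sorted(s) for r, s in coll.sets.items()}, indent=1)
    )
    if len(coll):
        params = MgsaParams(
            n_iter=config.mgsa_n_iter,
            burnin=config.mgsa_burnin,
            n_restarts=config.mgsa_restarts,
            seed=pio.derive_seed(config.seed, "mgsa"),
        )
        result = _stage("regulator_selection")(mgsa_mcmc)(coll, targets, params)
        result.table.to_csv(outdir / "regulators.tsv", sep="\t", float_format="%.6g")
        selected = select_regulators(result, config.b)
        regtab = result.table.loc[selected].reset_index().to_dict(orient="records")
    else:
        selected, regtab = [], []
    pio.save_gene_list(selected, outdir / "selected_regulators.txt")
    report["regulators"] = {
        "n_nonempty_sets": int(len(coll)),
        "selected": selected,
        "table": regtab,
    }
    report["wall_time_s"] = round(time.time() - t0, 3)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
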