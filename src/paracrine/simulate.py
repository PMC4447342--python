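"""Synthetic paired stromal/tumor expression data with planted regulators.

The generator emulates the study design the pipeline targets: stromal cells
from ``n`` donors condition medium that stimulates matched tumor cell
cultures, so communication is strictly one-way (stroma -> tumor, no
feedback).  Stromal genes follow a sparse linear-Gaussian structural
equation model (SEM) over a random DAG; a designated subset of genes is
"secreted", and a small planted subset of the secreted genes drives a block
of tumor response genes linearly.  Unstimulated tumor controls receive the
same baseline and noise but no stromal contribution.

The linear-Gaussian SEM matches the identifiability assumptions of the
intervention-calculus (IDA) stage exactly, which makes parameter recovery a
fair end-to-end check: every planted regulator->target effect is knowable in
closed form.

Gene-level baselines (typical log2 expression, drawn once per gene) are
added on top of the zero-mean SEM fluctuations.  Baselines do not change any
covariance, but they are what make the expression-level filters and the
stimulated-vs-control differential contrast meaningful: without them every
gene would sit at log2 expression 0 and the mean response to stimulation
would vanish.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, ParameterError
from .matrix import ExpressionMatrix


@dataclass
class GroundTruthModel:
    """A known structural model: stromal DAG plus planted tumor responses.

    Attributes
    ----------
    nodes:
        Stromal gene labels in a topological order of the DAG.
    edges:
        Map ``(parent, child) -> weight`` of the stromal SEM.
    noise_sd:
        Per-node innovation standard deviation (> 0).
    baseline:
        Per-node mean log2 expression added after the SEM recursion.
    secreted:
        Stromal genes flagged as secreted/extracellular.
    regulator_effects:
        Map ``(secreted stromal gene, tumor gene) -> effect`` of the planted
        linear stroma->tumor couplings.
    tumor_genes:
        All tumor gene labels (responsive first, then null).
    null_targets:
        Tumor genes with no stromal driver (baseline + noise only).
    control_shift:
        Per-tumor-gene baseline, shared by stimulated and control samples.
    """

    nodes: List[str]
    edges: Dict[Tuple[str, str], float]
    noise_sd: Dict[str, float]
    baseline: Dict[str, float] = field(default_factory=dict)
    secreted: FrozenSet[str] = frozenset()
    regulator_effects: Dict[Tuple[str, str], float] = field(default_factory=dict)
    tumor_genes: List[str] = field(default_factory=list)
    null_targets: List[str] = field(default_factory=list)
    control_shift: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        g = self.dag()
        if not nx.is_directed_acyclic_graph(g):
            raise ConsistencyError("stromal graph has a directed cycle")
        for node in self.nodes:
            if self.noise_sd.get(node, 0.0) <= 0:
                raise ConsistencyError(f"noise_sd must be > 0 for node {node!r}")
        for (x, _y) in self.regulator_effects:
            if x not in self.secreted:
                raise ConsistencyError(f"regulator {x!r} is not in the secreted set")
        tumor = set(self.tumor_genes)
        for (_x, y) in self.regulator_effects:
            if y not in tumor:
                raise ConsistencyError(f"target {y!r} is not a tumor gene")

    def dag(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges.keys())
        return g

    @property
    def regulators(self) -> List[str]:
        return sorted({x for (x, _y) in self.regulator_effects})

    def weight_matrix(self) -> pd.DataFrame:
        """W with W[i, j] = weight of edge i -> j (zero where absent)."""
        idx = {g: i for i, g in enumerate(self.nodes)}
        w = np.zeros((len(self.nodes), len(self.nodes)))
        for (u, v), wt in self.edges.items():
            w[idx[u], idx[v]] = wt
        return pd.DataFrame(w, index=self.nodes, columns=self.nodes)

    def covariance(self) -> pd.DataFrame:
        """Closed-form SEM covariance (I - W)^-T D (I - W)^-1."""
        w = self.weight_matrix().to_numpy()
        d = np.diag([self.noise_sd[g] ** 2 for g in self.nodes])
        inv = np.linalg.inv(np.eye(len(self.nodes)) - w)
        cov = inv.T @ d @ inv
        return pd.DataFrame(cov, index=self.nodes, columns=self.nodes)

    def tumor_sd(self, y: str, target_noise_sd: float) -> float:
        """Population standard deviation of tumor gene y under stimulation."""
        cov = self.covariance()
        drivers = [(x, b) for (x, yy), b in self.regulator_effects.items() if yy == y]
        var = target_noise_sd**2
        for (x1, b1) in drivers:
            for (x2, b2) in drivers:
                var += b1 * b2 * cov.loc[x1, x2]
        return float(np.sqrt(var))


def make_random_dag(
    n_nodes: int,
    expected_degree: float,
    weight_range: Tuple[float, float] = (0.5, 1.5),
    seed: int = 0,
    prefix: str = "SG",
) -> GroundTruthModel:
    """Draw a random sparse DAG with signed uniform edge weights.

    Nodes are placed in a fixed order and each forward edge is included
    independently with probability ``expected_degree / (n_nodes - 1)``, which
    yields ``n_nodes * expected_degree / 2`` edges in expectation and is
    acyclic by construction.  Weight magnitudes are uniform on
    ``weight_range`` with a random sign.
    """
    if n_nodes < 2:
        raise ParameterError("n_nodes must be >= 2")
    if not (0 < expected_degree < n_nodes - 1):
        raise ParameterError("expected_degree must be in (0, n_nodes - 1)")
    lo, hi = weight_range
    if not (0 < lo < hi):
        raise ParameterError("weight_range must satisfy 0 < low < high")
    rng = np.random.default_rng(seed)
    width = len(str(n_nodes))
    nodes = [f"{prefix}{i + 1:0{width}d}" for i in range(n_nodes)]
    p = expected_degree / (n_nodes - 1)
    edges: Dict[Tuple[str, str], float] = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p:
                mag = rng.uniform(lo, hi)
                sign = 1.0 if rng.random() < 0.5 else -1.0
                edges[(nodes[i], nodes[j])] = sign * mag
    noise = {g: 1.0 for g in nodes}
    base = {g: 0.0 for g in nodes}
    return GroundTruthModel(nodes=nodes, edges=edges, noise_sd=noise, baseline=base)


def sample_stromal_expression(
    model: GroundTruthModel, n_samples: int, seed: int = 0
) -> ExpressionMatrix:
    """Draw stromal samples by topological recursion of the linear SEM."""
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    order = list(nx.topological_sort(model.dag()))
    idx = {g: i for i, g in enumerate(model.nodes)}
    parents: Dict[str, List[Tuple[str, float]]] = {g: [] for g in model.nodes}
    for (u, v), w in model.edges.items():
        parents[v].append((u, w))
    x = np.zeros((len(model.nodes), n_samples))
    for g in order:
        eps = rng.normal(0.0, model.noise_sd[g], size=n_samples)
        val = eps
        for (u, w) in parents[g]:
            val = val + w * x[idx[u]]
        x[idx[g]] = val
    base = np.array([model.baseline.get(g, 0.0) for g in model.nodes])
    x = x + base[:, None]
    cols = [f"S{i + 1:03d}" for i in range(n_samples)]
    df = pd.DataFrame(x, index=model.nodes, columns=cols)
    role = pd.Series("stromal", index=cols)
    return ExpressionMatrix(df, role)


def sample_tumor_response(
    model: GroundTruthModel,
    stromal: ExpressionMatrix,
    n_controls: int = 4,
    target_noise_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Tumor genes driven linearly by planted secreted regulators.

    Stimulated sample *i* of tumor gene y is
    ``control_shift[y] + sum_x effect(x, y) * stromal[x, i] + noise``;
    control samples replace the stromal contribution by zero.  Returns one
    matrix holding stimulated samples (paired with the stromal columns by
    position) followed by controls, distinguished via ``sample_role``.
    """
    if n_controls < 0:
        raise ParameterError("n_controls must be >= 0")
    if target_noise_sd <= 0:
        raise ParameterError("target_noise_sd must be > 0")
    needed = {x for (x, _y) in model.regulator_effects}
    missing = sorted(needed - set(stromal.genes))
    if missing:
        raise ConsistencyError(f"secreted genes absent from stromal matrix: {missing}")
    rng = np.random.default_rng(seed)
    n_stim = stromal.n_samples
    genes = model.tumor_genes
    shift = np.array([model.control_shift.get(y, 0.0) for y in genes])
    out = np.zeros((len(genes), n_stim + n_controls))
    out += shift[:, None]
    out += rng.normal(0.0, target_noise_sd, size=out.shape)
    gidx = {y: i for i, y in enumerate(genes)}
    for (x, y), beta in model.regulator_effects.items():
        out[gidx[y], :n_stim] += beta * stromal.values.loc[x].to_numpy()
    stim_cols = [f"T{i + 1:03d}" for i in range(n_stim)]
    ctrl_cols = [f"C{i + 1:03d}" for i in range(n_controls)]
    df = pd.DataFrame(out, index=genes, columns=stim_cols + ctrl_cols)
    role = pd.Series(
        ["tumor_stimulated"] * n_stim + ["tumor_control"] * n_controls,
        index=stim_cols + ctrl_cols,
    )
    return ExpressionMatrix(df, role)


def default_flags(model: GroundTruthModel, seed: int = 0,
                  detection_prob: float = 0.75,
                  n_receptor_decoys: int = 3,
                  n_growth_factors: int = 4) -> pd.DataFrame:
    """Boolean annotation flags for every stromal and tumor gene.

    Secreted genes carry the secreted/extracellular annotation.  A few
    secreted genes are marked as receptors (always removed by the candidate
    filter), most secreted genes are "detected in conditioned medium" (the
    planted regulators always are, being the abundantly secreted factors the
    fixture plants), and a few are annotated growth factors, some undetected
    - exercising the growth-factor rescue of the filter cascade.
    """
    rng = np.random.default_rng(seed)
    genes = list(model.nodes) + list(model.tumor_genes)
    flags = pd.DataFrame(
        False,
        index=genes,
        columns=["secreted_annotation", "receptor", "growth_factor", "detected_in_cm"],
    )
    secreted = sorted(model.secreted)
    regulators = set(model.regulators)
    flags.loc[secreted, "secreted_annotation"] = True
    non_planted = [g for g in secreted if g not in regulators]
    rng.shuffle(non_planted)
    receptors = non_planted[:n_receptor_decoys]
    flags.loc[receptors, "receptor"] = True
    for g in secreted:
        if g in regulators:
            flags.loc[g, "detected_in_cm"] = True
        elif g not in receptors:
            flags.loc[g, "detected_in_cm"] = rng.random() < detection_prob
    gf_pool = [g for g in non_planted if g not in receptors]
    flags.loc[gf_pool[:n_growth_factors], "growth_factor"] = True
    return flags


def make_benchmark(
    n_network: int = 150,
    n_secreted: int = 40,
    n_regulators: int = 5,
    n_responsive: int = 60,
    n_null: int = 40,
    n_samples: int = 15,
    n_controls: int = 4,
    expected_degree: float = 2.0,
    weight_range: Tuple[float, float] = (0.5, 1.5),
    effect_range: Tuple[float, float] = (1.0, 2.0),
    noise_sd: float = 1.0,
    regulator_noise_sd: float = 2.0,
    baseline_range: Tuple[float, float] = (4.0, 12.0),
    regulator_baseline_range: Tuple[float, float] = (7.0, 10.0),
    shift_range: Tuple[float, float] = (4.0, 12.0),
    target_noise_sd: float = 1.0,
    seed: int = 0,
):
    """The default planted-truth benchmark.

    150 stromal network genes, 40 secreted, 5 planted regulators, 60
    responsive plus 40 null tumor genes, 15 paired samples and 4 controls -
    a desk-scale mirror of the motivating 15-donor design.  Each responsive
    tumor gene is driven by exactly one planted regulator with effect
    magnitude uniform on ``effect_range`` and random sign.  Planted
    regulators receive a larger innovation SD and a high expression
    baseline: detectable paracrine factors are precisely the secreted genes
    that are abundant and variable across donors, and this is also what the
    candidate filter cascade selects for.

    Returns ``(model, stromal, tumor, flags)``.
    """
    if n_regulators > n_secreted or n_secreted > n_network:
        raise ParameterError("need n_regulators <= n_secreted <= n_network")
    ss = np.random.SeedSequence(seed)
    s_graph, s_assign, s_strom, s_tumor, s_flags = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    model = make_random_dag(n_network, expected_degree, weight_range, seed=s_graph)
    rng = np.random.default_rng(s_assign)

    secreted = sorted(rng.choice(model.nodes, size=n_secreted, replace=False))
    regulators = sorted(rng.choice(secreted, size=n_regulators, replace=False))
    responsive = [f"TG{i + 1:03d}" for i in range(n_responsive)]
    nulls = [f"TN{i + 1:03d}" for i in range(n_null)]

    effects: Dict[Tuple[str, str], float] = {}
    for i, y in enumerate(responsive):
        x = regulators[i % n_regulators]
        mag = rng.uniform(*effect_range)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        effects[(x, y)] = sign * mag

    baseline = {g: float(rng.uniform(*baseline_range)) for g in model.nodes}
    for g in regulators:
        baseline[g] = float(rng.uniform(*regulator_baseline_range))
    noise = {g: noise_sd for g in model.nodes}
    for g in regulators:
        noise[g] = regulator_noise_sd
    shift = {y: float(rng.uniform(*shift_range)) for y in responsive + nulls}

    model = GroundTruthModel(
        nodes=model.nodes,
        edges=model.edges,
        noise_sd=noise,
        baseline=baseline,
        secreted=frozenset(secreted),
        regulator_effects=effects,
        tumor_genes=responsive + nulls,
        null_targets=nulls,
        control_shift=shift,
    )
    stromal = sample_stromal_expression(model, n_samples, seed=s_strom)
    tumor = sample_tumor_response(
        model, stromal, n_controls=n_controls, target_noise_sd=target_noise_sd, seed=s_tumor
    )
    flags = default_flags(model, seed=s_flags)
    return model, stromal, tumor, flags


# --------------------------------------------------------------------- I/O

def write_fixture(outdir, model: GroundTruthModel, stromal: ExpressionMatrix,
                  tumor: ExpressionMatrix, flags: pd.DataFrame) -> None:
    """Write matrices, sample roles, flags and the ground truth to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stromal.to_tsv(outdir / "stromal.tsv")
    tumor.to_tsv(outdir / "tumor.tsv")
    roles = []
    for m in (stromal, tumor):
        for i, s in enumerate(m.samples):
            role = m.sample_role[s]
            pair = i + 1 if role in ("stromal", "tumor_stimulated") else ""
            roles.append((s, role, pair))
    pd.DataFrame(roles, columns=["sample_id", "role", "pair_id"]).to_csv(
        outdir / "samples.tsv", sep="\t", index=False
    )
    out_flags = flags.astype(int).copy()
    out_flags.index.name = "gene_id"
    out_flags.to_csv(outdir / "flags.tsv", sep="\t")
    truth = {
        "nodes": model.nodes,
        "edges": [[u, v, w] for (u, v), w in sorted(model.edges.items())],
        "noise_sd": model.noise_sd,
        "baseline": model.baseline,
        "secreted": sorted(model.secreted),
        "regulator_effects": [[x, y, b] for (x, y), b in sorted(model.regulator_effects.items())],
        "tumor_genes": model.tumor_genes,
        "null_targets": model.null_targets,
        "control_shift": model.control_shift,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


def load_truth(path) -> GroundTruthModel:
    raw = json.loads(Path(path).read_text())
    return GroundTruthModel(
        nodes=raw["nodes"],
        edges={(u, v): w for u, v, w in raw["edges"]},
        noise_sd=raw["noise_sd"],
        baseline=raw.get("baseline", {}),
        secreted=frozenset(raw.get("secreted", [])),
        regulator_effects={(x, y): b for x, y, b in raw.get("regulator_effects", [])},
        tumor_genes=raw.get("tumor_genes", []),
        null_targets=raw.get("null_targets", []),
        control_shift=raw.get("control_shift", {}),
    )
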