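"""Synthetic networks and case-control expression data with known ground truth.

The generator emulates the study design the pipeline is built for: a
scale-free-ish directed regulatory network whose nodes carry molecular class
labels, and a small two-group microarray-style experiment (3 cases vs 3
controls by default) with Gaussian noise on the log2 scale. A handful of
"planted" regulators have a fraction of their targets shifted up or down in
case samples, so over-connectivity of those hubs to the DE set is true by
construction and every pipeline stage can be validated against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityRecord
from .diffexpr import ExpressionStudy
from .network import CLASS_TOKENS, InteractionNetwork, build_network, save_network

EFFECT_PROPORTIONS = {"activation": 0.5, "inhibition": 0.3, "unspecified": 0.2}

# Default class mix: regulatory classes are a minority of the universe, as in
# curated pathway databases.
DEFAULT_CLASS_FRACTIONS = {
    "transcription_factor": 0.15,
    "kinase": 0.15,
    "protease": 0.10,
    "other": 0.60,
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe the reference condition used throughout: a 200-node
    network with 20 hubs of mean out-degree 8, three planted regulators whose
    targets shift by 1.5 log2 units against noise sd 0.5, measured 3 vs 3.
    """

    n_nodes: int = 200
    n_hubs: int = 20
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    mean_out_degree: float = 8.0
    n_planted: int = 3
    planted_target_fraction: float = 0.8
    effect_log2: float = 1.5
    noise_sd: float = 0.5
    n_case: int = 3
    n_control: int = 3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_hubs <= self.n_nodes):
            raise ValueError("need 0 < n_hubs <= n_nodes")
        if self.n_planted > self.n_hubs:
            raise ValueError("n_planted must not exceed n_hubs")
        if self.n_planted < 0:
            raise ValueError("n_planted must be >= 0")
        if not 0 < self.planted_target_fraction <= 1:
            raise ValueError("planted_target_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.mean_out_degree >= self.n_nodes:
            raise ValueError("mean_out_degree must be < n_nodes")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        unknown = set(self.class_fractions) - set(CLASS_TOKENS)
        if unknown:
            raise ValueError(f"unknown class tokens in fractions: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class GroundTruth:
    """Planted regulators and the genes whose expression was truly shifted."""

    planted_regulators: set[str]
    planted_de_genes: dict[str, str]  # gene -> true direction (up/down)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # Independent, reproducible streams per generation stage.
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(cfg: SimulationConfig) -> InteractionNetwork:
    """Directed network with designated hubs and heavy-tailed out-degrees.

    Hub out-degrees are lognormal (sigma 0.75) with the configured mean,
    clipped to [1, n_nodes - 1]; targets are sampled uniformly without
    replacement excluding the hub itself. Non-hub nodes have no outgoing
    edges. Classes follow ``class_fractions``; edge effects are drawn
    activation/inhibition/unspecified at 0.5/0.3/0.2.
    """
    rng = _rng(cfg, 0)
    genes = _gene_ids(cfg.n_nodes)
    gene_arr = np.array(genes)
    hubs = sorted(rng.choice(gene_arr, size=cfg.n_hubs, replace=False).tolist())

    classes = dict(zip(genes, rng.choice(
        list(cfg.class_fractions), size=cfg.n_nodes,
        p=list(cfg.class_fractions.values()),
    ).tolist()))

    sigma = 0.75
    mu = math.log(cfg.mean_out_degree) - sigma ** 2 / 2.0
    edges: list[tuple[str, str, str]] = []
    if cfg.n_nodes > 1:
        effects = np.array(list(EFFECT_PROPORTIONS))
        effect_p = np.array(list(EFFECT_PROPORTIONS.values()))
        for hub in hubs:
            deg = int(np.clip(round(rng.lognormal(mu, sigma)), 1,
                              cfg.n_nodes - 1))
            others = gene_arr[gene_arr != hub]
            targets = rng.choice(others, size=deg, replace=False)
            for tgt, eff in zip(targets,
                                rng.choice(effects, size=deg, p=effect_p)):
                edges.append((hub, str(tgt), str(eff)))
    return build_network(edges, classes, extra_nodes=set(genes))


def generate_expression(net: InteractionNetwork, cfg: SimulationConfig
                        ) -> tuple[ExpressionStudy, GroundTruth]:
    """Two-group log2 expression matrix over the network's genes.

    Every sample is baseline + Normal(0, noise_sd). For each planted
    regulator (drawn among the nodes with outgoing edges), a
    ``planted_target_fraction`` share of its targets gets a +/- effect_log2
    shift in case samples, one fixed sign per gene.
    """
    rng = _rng(cfg, 1)
    genes = sorted(net.nodes)
    idx_of = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    n_samples = cfg.n_case + cfg.n_control
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_genes)
    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd,
                                            (n_genes, n_samples))
    sample_ids = ([f"case_{i + 1}" for i in range(cfg.n_case)]
                  + [f"ctrl_{i + 1}" for i in range(cfg.n_control)])
    group_of = {s: ("case" if s.startswith("case") else "control")
                for s in sample_ids}

    hub_pool = sorted(n for n in net.nodes if net.out_targets(n))
    if cfg.n_planted > len(hub_pool):
        raise ValueError(
            f"cannot plant {cfg.n_planted} regulators: only "
            f"{len(hub_pool)} nodes have outgoing edges"
        )
    planted = sorted(rng.choice(np.array(hub_pool), size=cfg.n_planted,
                                replace=False).tolist()) if cfg.n_planted else []
    case_cols = np.arange(cfg.n_case)
    planted_de: dict[str, str] = {}
    for hub in planted:
        targets = sorted(net.out_targets(hub))
        k = max(1, int(round(cfg.planted_target_fraction * len(targets))))
        chosen = rng.choice(np.array(targets), size=k, replace=False)
        for gene in sorted(map(str, chosen)):
            if gene in planted_de:   # shared target of two planted hubs
                continue
            sign = 1.0 if rng.random() < 0.5 else -1.0
            values[idx_of[gene]][case_cols] += sign * cfg.effect_log2
            planted_de[gene] = "up" if sign > 0 else "down"

    study = ExpressionStudy(genes, values, sample_ids, group_of)
    return study, GroundTruth(set(planted), planted_de)


def simulate_study(cfg: SimulationConfig
                   ) -> tuple[InteractionNetwork, ExpressionStudy, GroundTruth]:
    """Convenience: network + expression + truth for one configuration."""
    net = generate_network(cfg)
    study, truth = generate_expression(net, cfg)
    return net, study, truth


def evaluate_recovery(records: list[ConnectivityRecord], truth: GroundTruth,
                      k: int) -> tuple[float | None, float | None, float | None]:
    """(top-k hit rate, median planted z, median null z) for one analysis.

    The hit rate is the fraction of planted regulators among the k hubs with
    the highest z (ties broken by p then name); it is None when nothing was
    planted. Records with undefined z are excluded.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted((r for r in records if r.z is not None),
                    key=lambda r: (-r.z, r.p, r.hub))
    top_hubs = {r.hub for r in ranked[:k]}
    planted_z = [r.z for r in ranked if r.hub in truth.planted_regulators]
    null_z = [r.z for r in ranked if r.hub not in truth.planted_regulators]
    if truth.planted_regulators:
        hit_rate = (len(truth.planted_regulators & top_hubs)
                    / len(truth.planted_regulators))
    else:
        hit_rate = None
    med = lambda xs: float(np.median(xs)) if xs else None
    return hit_rate, med(planted_z), med(null_z)


def null_calibration(n_seeds: int = 100, base_cfg: SimulationConfig | None = None,
                     seed_offset: int = 0) -> dict[str, float]:
    """Calibration of the pipeline on data with no planted effects.

    For each seed a study is generated with ``n_planted = 0`` and the full
    DE + over-connectivity analysis is run. Because the expression noise is
    independent of the network, genes selected at ``p_raw <= 0.05`` form a
    uniform random node subset, so the hypergeometric null holds exactly for
    the connectivity stage; the raw-p selection (rather than the FDR/FC
    gate, which correctly yields an empty DE set on null data) keeps the DE
    set non-empty so that null is actually exercised.

    Returns the mean fraction of hubs with connectivity p <= 0.05, the mean
    connectivity z, and the pooled DE false-positive rate at p_raw <= 0.05.
    """
    import dataclasses

    from .diffexpr import run_de

    base = base_cfg or SimulationConfig()
    fracs: list[float] = []
    zs: list[float] = []
    fp = 0
    n_tests = 0
    for seed in range(seed_offset, seed_offset + n_seeds):
        cfg = dataclasses.replace(base, seed=seed, n_planted=0)
        net, study, _ = simulate_study(cfg)
        de, _ = run_de(study)
        fp += int((de["p_raw"] <= 0.05).sum())
        n_tests += len(de)
        raw = de[de["p_raw"] <= 0.05]
        from .connectivity import DESet, analyze_interactome
        de_set = DESet(
            set(raw["gene_id"]),
            {g: ("up" if l > 0 else "down")
             for g, l in zip(raw["gene_id"], raw["log2fc"])},
        )
        records = analyze_interactome(net, de_set, de)
        if records:
            fracs.append(float(np.mean([r.p <= 0.05 for r in records])))
        zs.extend(r.z for r in records if r.z is not None)
    return {
        "mean_frac_p05": float(np.mean(fracs)),
        "mean_z": float(np.mean(zs)),
        "de_fpr_raw": fp / n_tests,
        "n_tests": n_tests,
    }


def write_simulation(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialize one simulated study as the pipeline's input TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, study, truth = simulate_study(cfg)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "samples": outdir / "samples.tsv",
        "edges": outdir / "edges.tsv",
        "classes": outdir / "classes.tsv",
        "truth": outdir / "truth.tsv",
    }
    mat = pd.DataFrame(study.values, columns=study.sample_ids)
    mat.insert(0, "gene_id", study.gene_ids)
    mat.to_csv(paths["matrix"], sep="\t", index=False, float_format="%.6f")
    pd.DataFrame({
        "sample": study.sample_ids,
        "group": [study.group_of[s] for s in study.sample_ids],
    }).to_csv(paths["samples"], sep="\t", index=False)
    save_network(net, paths["edges"], paths["classes"])
    truth_rows = [("regulator", hub, "") for hub in sorted(truth.planted_regulators)]
    truth_rows += [("de_gene", g, d) for g, d in sorted(truth.planted_de_genes.items())]
    pd.DataFrame(truth_rows, columns=["kind", "gene", "direction"]).to_csv(
        paths["truth"], sep="\t", index=False)
    return paths
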