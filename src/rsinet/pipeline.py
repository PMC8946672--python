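"""Orchestration of the full network analysis from a single configuration.

One run produces, for each of three networks (whole cohort, returned,
not-returned): the edge list and weight matrix, centrality tables, edge
bootstrap intervals and the Strength CS-coefficient; plus one permutation
comparison between the two subgroups and a machine-readable summary naming
the strongest edge and the top-Strength node per network. Every stochastic
stage draws its seed deterministically from one master seed and the stage
name, so toggling a stage never shifts another stage's random draws.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import centrality, comparison, resampling
from .cohort import CohortTable, concat, read_cohort, summarize
from .network import NetworkModel, fit_network
from .synthetic import make_spec_from_study_defaults, generate

logger = logging.getLogger(__name__)

NETWORK_IDS = ("whole", "returned", "not_returned")


@dataclass
class RunConfig:
    """Configuration for a full analysis run.

    ``input_csv`` takes precedence; when absent, a synthetic default cohort
    is generated from ``synthetic_seed``. Stage toggles allow partial runs
    without disturbing other stages' seeds.
    """

    input_csv: str | None = None
    synthetic_seed: int = 0
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    B_edges: int = 1000
    drop_grid: tuple[float, ...] = resampling.DEFAULT_DROP_GRID
    B_per_proportion: int = 1000
    n_permutations: int = 1000
    alpha: float = 0.05
    master_seed: int = 0
    output_dir: str = "results"
    stages: dict = field(
        default_factory=lambda: {
            "descriptives": True,
            "networks": True,
            "centrality": True,
            "edge_bootstrap": True,
            "stability": True,
            "nct": True,
            "figures": False,
        }
    )

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["drop_grid"] = list(self.drop_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "drop_grid" in d:
            d["drop_grid"] = tuple(d["drop_grid"])
        return cls(**d)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed combined with a stage-name
    hash, reduced below 2^31 so it fits any consumer."""
    ss = np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _pipeline_kwargs(config: RunConfig) -> dict:
    return {
        "gamma": config.gamma,
        "n_lambda": config.n_lambda,
        "lambda_min_ratio": config.lambda_min_ratio,
    }


def load_input(config: RunConfig) -> CohortTable:
    """Resolve the whole-cohort table from the config (CSV or synthetic)."""
    if config.input_csv is not None:
        return read_cohort(config.input_csv)
    spec = make_spec_from_study_defaults(seed=config.synthetic_seed)
    a, b = generate(spec)
    return concat([a, b])


def network_summary(models: dict[str, NetworkModel]) -> dict:
    """Strongest edge and top-Strength node per network."""
    out = {}
    for net_id, m in models.items():
        iu = np.triu_indices(m.p, k=1)
        k = int(np.argmax(np.abs(m.W[iu])))
        i, j = iu[0][k], iu[1][k]
        s = centrality.strength(m.W)
        out[net_id] = {
            "max_weight_edge": [m.node_labels[i], m.node_labels[j]],
            "max_weight": float(m.W[i, j]),
            "top_strength_node": m.node_labels[int(np.argmax(s))],
            "top_strength": float(s.max()),
            "lambda": m.lam,
            "ebic": m.ebic,
            "edge_count": m.edge_count,
        }
    return out


def write_model(model: NetworkModel, outdir: Path, net_id: str) -> None:
    model.edge_list().to_csv(outdir / f"edges_{net_id}.csv", index=False)
    import pandas as pd

    pd.DataFrame(
        model.W, index=list(model.node_labels), columns=list(model.node_labels)
    ).to_csv(outdir / f"weights_{net_id}.csv")
    meta = {
        "lambda": model.lam, "gamma": model.gamma, "ebic": model.ebic,
        "edge_count": model.edge_count,
    }
    (outdir / f"model_{net_id}.json").write_text(json.dumps(meta, indent=2))


def plot_network(model: NetworkModel, path, seed: int = 0) -> None:
    """Force-directed network figure: blue positive / red negative edges,
    thickness proportional to |weight|. Layout is a presentation choice and
    not reproducible across platforms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(model.node_labels)
    p = model.p
    for i in range(p):
        for j in range(i + 1, p):
            w = model.W[i, j]
            if w != 0:
                G.add_edge(model.node_labels[i], model.node_labels[j], weight=w)
    pos = nx.spring_layout(G, seed=seed)
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx_nodes(G, pos, node_color="#dddddd", edgecolors="black",
                           node_size=700, ax=ax)
    nx.draw_networkx_labels(G, pos, font_size=9, ax=ax)
    for (u, v, d) in G.edges(data=True):
        nx.draw_networkx_edges(
            G, pos, edgelist=[(u, v)],
            width=abs(d["weight"]) * 8,
            edge_color="tab:blue" if d["weight"] > 0 else "tab:red",
            ax=ax,
        )
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the configured stages; write artifacts; return them in memory.

    Consistency is checked up front: the whole-cohort table must equal the
    row-concatenation of the two subgroup tables. Stage failures propagate
    with the stage name; artifacts written before the failure persist.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"config": config}
    kw = _pipeline_kwargs(config)

    whole = load_input(config)
    returned, not_returned = whole.split_by_return()
    rebuilt = concat([returned, not_returned])
    order = np.argsort(
        np.concatenate([np.where(whole.returned)[0], np.where(~whole.returned)[0]])
    )
    if not np.array_equal(rebuilt.items[order], whole.items):
        raise AssertionError("whole cohort != concatenation of subgroups")
    groups = {"whole": whole, "returned": returned, "not_returned": not_returned}
    artifacts["cohorts"] = groups

    def _stage(name: str) -> bool:
        return bool(config.stages.get(name, False))

    def _log(name: str, t0: float) -> None:
        logger.info("stage=%s seed=%s elapsed=%.1fs", name,
                    stage_seed(config.master_seed, name), time.time() - t0)

    if _stage("descriptives"):
        t0 = time.time()
        summary = summarize(whole)
        summary.to_csv(outdir / "item_summary.csv", index=False)
        artifacts["summary"] = summary
        _log("descriptives", t0)

    models: dict[str, NetworkModel] = {}
    if _stage("networks"):
        t0 = time.time()
        for net_id, cohort in groups.items():
            m = fit_network(cohort.items, node_labels=cohort.item_labels, **kw)
            models[net_id] = m
            write_model(m, outdir, net_id)
        artifacts["models"] = models
        summary_json = network_summary(models)
        (outdir / "network_summary.json").write_text(
            json.dumps(summary_json, indent=2)
        )
        artifacts["network_summary"] = summary_json
        _log("networks", t0)

    if _stage("centrality") and models:
        t0 = time.time()
        import pandas as pd

        tables = [
            centrality.centrality_table(m.W, m.node_labels, net_id)
            for net_id, m in models.items()
        ]
        cent = pd.concat(tables, ignore_index=True)
        cent.to_csv(outdir / "centrality.csv", index=False)
        artifacts["centrality"] = cent
        _log("centrality", t0)

    if _stage("edge_bootstrap"):
        t0 = time.time()
        boots = {}
        for net_id, cohort in groups.items():
            res = resampling.bootstrap_edges(
                cohort, B=config.B_edges,
                seed=stage_seed(config.master_seed, f"edge_bootstrap/{net_id}"),
                **kw,
            )
            res.to_frame().to_csv(outdir / f"edge_bootstrap_{net_id}.csv",
                                  index=False)
            boots[net_id] = res
        artifacts["edge_bootstrap"] = boots
        _log("edge_bootstrap", t0)

    if _stage("stability"):
        t0 = time.time()
        cs = {}
        drops = {}
        for net_id, cohort in groups.items():
            res = resampling.case_drop_bootstrap(
                cohort, proportions=config.drop_grid,
                B_per_proportion=config.B_per_proportion,
                seed=stage_seed(config.master_seed, f"stability/{net_id}"),
                **kw,
            )
            res.to_frame().to_csv(outdir / f"case_drop_{net_id}.csv", index=False)
            cs[net_id] = resampling.cs_coefficient(res)
            drops[net_id] = res
        (outdir / "cs_coefficients.json").write_text(json.dumps(cs, indent=2))
        artifacts["cs"] = cs
        artifacts["case_drop"] = drops
        _log("stability", t0)

    if _stage("nct"):
        t0 = time.time()
        res = comparison.nct(
            returned, not_returned,
            n_permutations=config.n_permutations,
            seed=stage_seed(config.master_seed, "nct"),
            alpha=config.alpha, **kw,
        )
        res.edge_frame().to_csv(outdir / "nct_edges.csv", index=False)
        res.strength_frame().to_csv(outdir / "nct_strength.csv", index=False)
        meta = {
            "n_A": returned.n, "n_B": not_returned.n,
            "n_permutations": res.n_permutations, "seed": res.seed,
            "alpha": res.alpha, "adjusted": res.adjusted,
        }
        (outdir / "nct_meta.json").write_text(json.dumps(meta, indent=2))
        artifacts["nct"] = res
        _log("nct", t0)

    if _stage("figures") and models:
        t0 = time.time()
        for net_id, m in models.items():
            plot_network(m, outdir / f"network_{net_id}.svg",
                         seed=stage_seed(config.master_seed, "figures"))
        _log("figures", t0)

    return artifacts
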