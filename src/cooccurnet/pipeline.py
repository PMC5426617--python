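"""Configuration-driven orchestration of the full analysis workflow.

The pipeline runs, in order: filtering → tie-break Monte-Carlo ensemble →
permutation sweep and threshold resolution → per-replicate networks and
statistics → Erdős–Rényi and Chung-Lu null ensembles parameterized from the
derived ensemble → empirical significance per statistic → consensus network
→ phylum mixing table and fixed-partition modularity when taxonomy is
supplied. Every artifact is listed in a manifest together with the seed
that produced it, and two runs with the same config and seed are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from ._rng import child_seed
from .abundance import (
    AbundanceMatrix,
    classify_otus,
    filter_min_total,
    read_abundance_matrix,
    read_taxonomy,
    sparsity,
    write_abundance_matrix,
)
from .netstats import (
    compute_statistics,
    diameter,
    global_clustering,
    max_modularity,
    mean_path_length,
    mixing_table,
    partition_modularity,
    summarize_ensemble,
)
from .networks import (
    component_sweep,
    consensus_network,
    default_grid,
    monte_carlo_ensemble,
    noise_transition_threshold,
    threshold_network,
)
from .nullmodels import (
    empirical_significance,
    er_probability,
    null_distribution,
    sample_chung_lu,
    sample_erdos_renyi,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "statistics_sweep"]

logger = logging.getLogger("cooccurnet")

#: statistics compared against the graph-level null models
NULL_STATISTICS = {
    "mean_path_length": mean_path_length,
    "diameter": diameter,
    "clustering": global_clustering,
    "max_modularity": lambda g: max_modularity(g)[0],
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (YAML-serializable)."""

    input: str
    outdir: str
    taxonomy: Optional[str] = None
    orientation: str = "otus_in_rows"
    delimiter: Optional[str] = None
    min_total: float = 5
    threshold: Union[str, float] = "auto"
    margin: float = 0.05
    cutoff: float = 0.01
    grid_step: float = 0.01
    noise_replicates: int = 2000
    er_replicates: int = 2000
    cl_replicates: int = 2000
    support: float = 0.9
    er_recipe: str = "matrix_cells"
    include_modularity: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_replicates", "er_replicates", "cl_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.threshold != "auto" and not (0.0 <= float(self.threshold) <= 1.0):
            raise ValueError("threshold must be 'auto' or in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write_json(obj, path: str) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)


def write_edge_list(g: nx.Graph, path: str) -> None:
    """TSV edge list: source, target, |ρ| weight, sign, support (if any)."""
    rows = []
    for u, v, d in sorted(g.edges(data=True)):
        rows.append(
            {
                "source": u,
                "target": v,
                "weight": d.get("weight", float("nan")),
                "sign": d.get("sign", 1),
                "support": d.get("support", float("nan")),
            }
        )
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign", "support"]).to_csv(
        path, sep="\t", index=False
    )


def _representative_replicate(graphs) -> Optional[int]:
    """Index of the replicate whose edge count is the ensemble median."""
    m_counts = np.array([g.number_of_edges() for g in graphs])
    if m_counts.max() == 0:
        return None
    med = np.median(m_counts)
    return int(np.argmin(np.abs(m_counts - med)))


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the full workflow; returns the key results in memory.

    Artifacts and a ``manifest.json`` (stage status, outputs, seeds) are
    written under ``config.outdir``. A stage failure aborts the run with a
    :class:`PipelineError` naming the stage; completed artifacts are kept
    and the manifest records the FAILED stage.
    """
    os.makedirs(config.outdir, exist_ok=True)
    manifest: Dict[str, object] = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    results: Dict[str, object] = {}

    def _out(name: str) -> str:
        return os.path.join(config.outdir, name)

    def _finish(stage: str, t0: float, outputs, **extra) -> None:
        manifest["stages"][stage] = {
            "status": "OK",
            "elapsed_s": round(time.time() - t0, 3),
            "outputs": outputs,
            **extra,
        }
        logger.info("stage %s done (%.2fs)", stage, time.time() - t0)

    def _fail(stage: str, err: BaseException) -> None:
        manifest["stages"][stage] = {"status": "FAILED", "error": str(err)}
        _write_json(manifest, _out("manifest.json"))

    stage = "load"
    t0 = time.time()
    try:
        phylum = read_taxonomy(config.taxonomy) if config.taxonomy else None
        matrix = read_abundance_matrix(
            config.input,
            orientation=config.orientation,
            delimiter=config.delimiter,
            phylum=phylum,
        )
        _finish(stage, t0, [], n_otus=matrix.n_otus, n_locations=matrix.n_locations)
    except Exception as err:
        _fail(stage, err)
        raise PipelineError(stage, err) from err

    stage = "filter"
    t0 = time.time()
    try:
        filtered = filter_min_total(matrix, config.min_total)
        write_abundance_matrix(filtered, _out("filtered_matrix.tsv"))
        results["n_otus"] = filtered.n_otus
        results["sparsity"] = sparsity(filtered) if filtered.counts.size else float("nan")
        _finish(
            stage, t0, ["filtered_matrix.tsv"],
            n_otus=filtered.n_otus, sparsity=results["sparsity"],
        )
    except Exception as err:
        _fail(stage, err)
        raise PipelineError(stage, err) from err

    stage = "sweep"
    t0 = time.time()
    sweep_seed = child_seed(config.seed, 1)
    try:
        sweep = component_sweep(
            filtered, grid=default_grid(config.grid_step), seed=sweep_seed
        )
        sweep.to_frame().to_csv(_out("sweep.tsv"), sep="\t", index=False)
        results["sweep"] = sweep
        _finish(stage, t0, ["sweep.tsv"], seed=sweep_seed)
    except Exception as err:
        _fail(stage, err)
        raise PipelineError(stage, err) from err

    stage = "threshold"
    t0 = time.time()
    try:
        transition = noise_transition_threshold(sweep, cutoff=config.cutoff)
        if config.threshold == "auto":
            if transition is None:
                raise ValueError("no noise transition on the grid; cannot auto-threshold")
            tau = min(1.0, transition + config.margin)
        else:
            tau = float(config.threshold)
        results["transition"] = transition
        results["threshold"] = tau
        _write_json(
            {
                "threshold": tau,
                "transition": transition,
                "margin": config.margin,
                "cutoff": config.cutoff,
                "mode": "auto" if config.threshold == "auto" else "fixed",
            },
            _out("threshold.json"),
        )
        _finish(stage, t0, ["threshold.json"], threshold=tau)
    except Exception as err:
        _fail(stage, err)
        raise PipelineError(stage, err) from err

    stage = "derive"
    t0 = time.time()
    ensemble_seed = child_seed(config.seed, 2)
    try:
        ensemble = monte_carlo_ensemble(
            filtered, tau=tau, replicates=config.noise_replicates,
            master_seed=ensemble_seed,
        )
        frame, summary = summarize_ensemble(
            ensemble, include_modularity=config.include_modularity
        )
        frame.to_csv(_out("replicate_statistics.tsv"), sep="\t", index=False)
        _write_json(summary, _out("observed_statistics.json"))
        results["ensemble"] = ensemble
        results["observed_summary"] = summary
        _finish(
            stage, t0, ["replicate_statistics.tsv", "observed_statistics.json"],
            seed=ensemble_seed,
        )
    except Exception as err:
        _fail(stage, err)
        raise PipelineError(stage, err) from err

    stage = "nulls"
    t0 = time.time()
    er_seed, cl_seed = child_seed(config.seed, 3), child_seed(config.seed, 4)
    try:
        null_stats = dict(NULL_STATISTICS)
        if not config.include_modularity:
            null_stats.pop("max_modularity")
        mean_n = results["observed_summary"]["n"]["mean"]
        mean_k = results["observed_summary"]["average_degree"]["mean"]
        rep_idx = _representative_replicate(ensemble)
        nulls: Dict[str, object] = {}
        if rep_idx is None or not np.isfinite(mean_n) or mean_n < 3:
            manifest_extra = {"skipped": "derived ensemble too small for null models"}
        else:
            n_er = int(round(mean_n))
            p = er_probability(n_er, mean_k, recipe=config.er_recipe)
            nulls["erdos_renyi"] = null_distribution(
                lambda rng: sample_erdos_renyi(n_er, p, rng),
                null_stats,
                replicates=config.er_replicates,
                seed=er_seed,
                model="erdos_renyi",
                parameters={"n": n_er, "p": p, "mean_degree": mean_k},
                allow_empty=True,
            )
            rep = ensemble[rep_idx]
            degrees = [d for _, d in sorted(rep.degree())]
            nulls["chung_lu"] = null_distribution(
                lambda rng: sample_chung_lu(degrees, rng),
                null_stats,
                replicates=config.cl_replicates,
                seed=cl_seed,
                model="chung_lu",
                parameters={"n": len(degrees), "m": rep.number_of_edges(),
                            "source_replicate": rep_idx},
                allow_empty=True,
            )
            manifest_extra = {"er_seed": er_seed, "cl_seed": cl_seed,
                              "representative_replicate": rep_idx}
        results["nulls"] = nulls
        _write_json(
            {name: {"parameters": s.parameters, "summary": s.summary(),
                    "skipped_draws": s.skipped}
             for name, s in nulls.items()},
            _out("null_statistics.json"),
        )
        _finish(stage, t0, ["null_statistics.json"], **manifest_extra)
    except Exception as err:
        _fail(stage, err)
        raise PipelineError(stage, err) from err

    stage = "significance"
    t0 = time.time()
    try:
        significance: Dict[str, Dict[str, Dict[str, float]]] = {}
        for model_name, summary_obj in results["nulls"].items():
            per_stat = {}
            for stat_name in summary_obj.samples:
                obs = results["observed_summary"].get(
                    stat_name if stat_name != "clustering" else "clustering",
                    {"mean": float("nan")},
                )["mean"]
                if not np.isfinite(obs):
                    continue
                res = empirical_significance(obs, summary_obj, stat=stat_name)
                per_stat[stat_name] = {
                    "observed": obs,
                    "null_mean": summary_obj.mean(stat_name),
                    "null_sd": summary_obj.sd(stat_name),
                    "p_value": res.p_value,
                    "z_score": res.z_score,
                }
            significance[model_name] = per_stat
        results["significance"] = significance
        _write_json(significance, _out("significance.json"))
        _finish(stage, t0, ["significance.json"])
    except Exception as err:
        _fail(stage, err)
        raise PipelineError(stage, err) from err

    stage = "consensus"
    t0 = time.time()
    try:
        cons = consensus_network(ensemble, support=config.support)
        write_edge_list(cons, _out("consensus_edges.tsv"))
        nx.write_graphml(cons, _out("consensus.graphml"))
        results["consensus"] = cons
        _finish(
            stage, t0, ["consensus_edges.tsv", "consensus.graphml"],
            n_nodes=cons.number_of_nodes(), n_edges=cons.number_of_edges(),
        )
    except Exception as err:
        _fail(stage, err)
        raise PipelineError(stage, err) from err

    if phylum is not None:
        stage = "taxonomy"
        t0 = time.time()
        try:
            outputs = []
            if cons.number_of_edges() > 0:
                table = mixing_table(cons, phylum)
                table.to_csv(_out("mixing_table.tsv"), sep="\t", index_label="phylum")
                q_phy = partition_modularity(cons, phylum)
                outputs = ["mixing_table.tsv", "taxonomy.json"]
                _write_json(
                    {"partition_modularity": q_phy,
                     "otu_classes": classify_otus(filtered)},
                    _out("taxonomy.json"),
                )
                results["partition_modularity"] = q_phy
                results["mixing_table"] = table
            _finish(stage, t0, outputs)
        except Exception as err:
            _fail(stage, err)
            raise PipelineError(stage, err) from err

    _write_json(manifest, _out("manifest.json"))
    results["manifest"] = manifest
    return results


def statistics_sweep(
    m: AbundanceMatrix,
    grid: Optional[Sequence[float]] = None,
    seed: int = 0,
    treatments: Sequence[str] = ("original", "noise_added"),
    include_modularity: bool = True,
) -> pd.DataFrame:
    """Network statistics as a function of threshold (robustness analysis).

    For each treatment, one correlation matrix is computed (raw ties for
    ``original``, one tie-break draw for ``noise_added``) and thresholded at
    every grid value; all summary statistics of the resulting network are
    tabulated. Conclusions that depend on a statistic should not depend
    sensitively on the threshold within the admissible range.
    """
    from .correlation import NoiseSpec, add_tiebreak_noise, pairwise_correlations

    if grid is None:
        grid = default_grid()
    rows = []
    for treatment in treatments:
        if treatment == "original":
            c = pairwise_correlations(m, on_ties="average")
        elif treatment == "noise_added":
            s = child_seed(seed, 0)
            c = pairwise_correlations(
                add_tiebreak_noise(m, NoiseSpec.for_matrix(m, seed=s)), seed=s
            )
        else:
            raise ValueError(f"unknown treatment {treatment!r}")
        for tau in grid:
            g = threshold_network(c, float(tau), provenance=treatment)
            st = compute_statistics(g, include_modularity=include_modularity)
            row = {"treatment": treatment, "threshold": float(tau)}
            row.update(st.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
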