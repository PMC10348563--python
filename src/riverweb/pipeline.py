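"""End-to-end study pipeline: sections -> master -> aggregation ->
metrics -> REGE -> flow tables -> two-web comparison.

Everything in the report bundle is regenerable from the inputs and the
config; no hidden state.  Outputs are plain CSV/JSON/Newick.
"""

from __future__ import annotations

import csv
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .aggregation import AggregationScheme, apply_scheme, merge_webs, read_scheme
from .comparison import compare_tables, read_synonyms
from .core import (
    CentralityTable,
    FoodWeb,
    ValidationError,
    read_centrality_table,
    read_edge_list,
    symmetrize,
    write_centrality_table,
)
from .metrics import local_metrics, metrics_trajectory
from .rege import cluster_similarity, rege_similarity

log = logging.getLogger("riverweb")

__all__ = ["RunConfig", "run_study", "sankey_flows", "write_metrics_csv"]


@dataclass
class RunConfig:
    """Inputs and options for one full pipeline run."""

    section_edge_lists: dict[str, str]  # section name -> edge-list CSV path
    scheme_path: str
    out_dir: str
    centrality_a: str | None = None  # two-web comparison inputs
    centrality_b: str | None = None
    synonyms_path: str | None = None
    rege_iterations: int = 3
    linkage: str = "average"
    rege_symmetrized: bool = False
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, path in self.section_edge_lists.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"section {name!r}: {path}")
        if not Path(self.scheme_path).exists():
            raise FileNotFoundError(self.scheme_path)
        if self.rege_iterations < 1:
            raise ValueError("rege_iterations must be >= 1")


def write_metrics_csv(reports, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["web", "step", "N", "L", "D", "CL", "d", "SW", "mutual_pairs"])
        for rep in reports:
            writer.writerow(
                [
                    rep.name,
                    rep.level,
                    rep.N,
                    rep.L,
                    f"{rep.D:.6f}",
                    f"{rep.CL:.6f}",
                    f"{rep.d:.6f}",
                    f"{rep.SW:.6f}",
                    rep.mutual_pairs,
                ]
            )


def sankey_flows(
    raw: FoodWeb, schemed: list[FoodWeb], scheme: AggregationScheme
) -> list[dict]:
    """Flow table behind a Sankey view of the aggregation.

    One row per (step, aggregate label): how many nodes of the
    previous level merged into the aggregate, and whether the
    aggregate carries a self-loop (within-group feeding, e.g.
    cannibalism) in that step's web.
    """
    if len(schemed) != len(scheme.steps):
        raise ValidationError("schemed webs do not match scheme steps")
    rows: list[dict] = []
    prev = raw
    for (step, mapping), web in zip(scheme.steps, schemed):
        merged: dict[str, int] = {}
        for node in prev.nodes:
            target = None
            for src, dst in mapping.items():
                if src == node or src.casefold() == node.casefold():
                    target = dst
                    break
            if target is not None:
                merged[target] = merged.get(target, 0) + 1
        loops = web.self_loops
        for target in sorted(merged):
            rows.append(
                {
                    "step": step,
                    "group": target,
                    "n_members": merged[target],
                    "self_loop": target in loops,
                }
            )
        prev = web
    return rows


def _section_outputs(
    name: str, web: FoodWeb, scheme: AggregationScheme, config: RunConfig, out: Path
) -> dict:
    schemed = apply_scheme(web, scheme)
    reports = metrics_trajectory([web] + schemed)
    write_metrics_csv(reports, out / f"metrics_{name.lower()}.csv")

    local = local_metrics(symmetrize(web))
    table = CentralityTable(name=name, rows=local)
    write_centrality_table(table, out / f"centrality_{name.lower()}.csv")

    t5 = schemed[-1]
    rege_input = t5
    if config.rege_symmetrized:
        sw = symmetrize(t5)
        rege_input = FoodWeb(
            name=t5.name,
            nodes=set(sw.nodes),
            edges={(u, v) for l in sw.links for u, v in (tuple(l), tuple(l)[::-1])},
            level=t5.level,
        )
    sim = rege_similarity(rege_input, iterations=config.rege_iterations)
    dend = cluster_similarity(sim, method=config.linkage)
    (out / f"rege_{name.lower()}.nwk").write_text(dend.to_newick() + "\n")
    sim.to_frame().to_csv(out / f"rege_{name.lower()}_similarity.csv")

    flows = sankey_flows(web, schemed, scheme)
    with (out / f"sankey_{name.lower()}.csv").open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["step", "group", "n_members", "self_loop"])
        writer.writeheader()
        writer.writerows(flows)

    final = reports[-1]
    return {
        "steps": [r.as_dict() for r in reports],
        "t5": {"N": final.N, "L": final.L, "D": final.D, "SW": final.SW},
    }


def run_study(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Stages: read each section web, merge into a master web, apply the
    aggregation scheme to every web, write metric trajectories and
    per-node centralities, REGE-cluster each T5 web, export flow
    tables, and (when two centrality tables are configured) run the
    shared-node comparison.  Any stage failure aborts with the stage
    named.  Returns a summary dict, also written to ``run_log.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "options": {
            "rege_iterations": config.rege_iterations,
            "linkage": config.linkage,
            "rege_symmetrized": config.rege_symmetrized,
        },
        "sections": {},
    }
    stage = "read inputs"
    try:
        webs = {
            name: read_edge_list(path, name=name)
            for name, path in config.section_edge_lists.items()
        }
        scheme = read_scheme(config.scheme_path)
        stage = "merge"
        if len(webs) > 1:
            webs["Master"] = merge_webs(list(webs.values()))
        for name, web in webs.items():
            stage = f"section {name}"
            summary["sections"][name] = _section_outputs(name, web, scheme, config, out)
        if config.centrality_a and config.centrality_b:
            stage = "comparison"
            table_a = read_centrality_table(config.centrality_a)
            table_b = read_centrality_table(config.centrality_b)
            synonyms = (
                read_synonyms(config.synonyms_path) if config.synonyms_path else None
            )
            result = compare_tables(table_a, table_b, synonyms)
            (out / "comparison.json").write_text(json.dumps(result.as_dict(), indent=2))
            summary["comparison"] = result.as_dict()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {stage}: {exc}") from exc
    (out / "run_log.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("report bundle written to %s", out)
    return summary
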