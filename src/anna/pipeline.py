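"""End-to-end orchestration of the three head analyses.

``run_analysis`` loads a network (user tables or the packaged head registry),
optionally restricts it to the skeletal ({bone, cartilage}) or muscular
({muscle}) subsystem, detects connectivity modules by the walktrap / max-Q
procedure, and writes the partition table, the modularity curve, and a summary
— plus an agreement report when a reference partition is supplied.  All
outputs are deterministic for a fixed configuration.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from . import community_detection as cd
from . import network_model as nm
from . import partition_metrics as pm

logger = logging.getLogger(__name__)

SUBSETS = {
    "all": None,
    "skeletal": nm.SKELETAL_CLASSES,
    "muscular": nm.MUSCULAR_CLASSES,
}


@dataclass(frozen=True)
class RunConfig:
    node_path: str = "packaged"
    edge_path: str | None = None
    subset: str = "all"
    walk_length: int = 3
    output_dir: str | Path = "."
    reference: str | None = None  # path, "table1", or None
    major_threshold: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.subset not in SUBSETS:
            raise cd.ParameterError(
                f"subset must be one of {sorted(SUBSETS)}, got {self.subset!r}"
            )
        if self.walk_length < 1:
            raise cd.ParameterError("walk_length must be >= 1")


@dataclass(frozen=True)
class SizeClassification:
    major: tuple[int, ...]     # module ids with size >= threshold
    blocks: tuple[int, ...]    # module ids with size 2..threshold-1
    isolates: tuple[int, ...]  # node ids in singleton/isolate modules


def classify_module_sizes(
    partition: cd.Partition, major_threshold: int = 5
) -> SizeClassification:
    """Split detected modules into major modules, small blocks, and isolates.

    "Major" means size >= ``major_threshold`` (default 5, so blocks span 2-4
    units); size-1 modules — flagged isolates and singleton communities alike —
    are reported as isolates.
    """
    if major_threshold < 2:
        raise cd.ParameterError("major_threshold must be >= 2")
    major, blocks, isolates = [], [], []
    for mod, members in sorted(partition.modules().items()):
        if len(members) >= major_threshold:
            major.append(mod)
        elif len(members) >= 2:
            blocks.append(mod)
        else:
            isolates.extend(members)
    return SizeClassification(tuple(major), tuple(blocks), tuple(sorted(isolates)))


def _load_inputs(config: RunConfig) -> nm.AnatomicalNetwork:
    if config.node_path == "packaged":
        nodes = nm.load_head_registry()
        edges = nm.load_head_edges(config.edge_path)
    else:
        nodes = nm.load_nodes(config.node_path)
        edges = nm.load_edges(config.edge_path) if config.edge_path else []
    return nm.build_network(nodes, edges)


def _load_reference(config: RunConfig):
    if config.reference is None:
        return None
    if config.reference == "table1":
        return nm.load_reference_partition()
    assignments: dict[int, int] = {}
    with open(config.reference, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    for row in rows[1:]:
        assignments[int(row[0])] = int(row[1])
    return nm.ReferencePartition(assignments)


def write_partition_table(partition: cd.Partition, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["node_id", "module_id", "is_isolate"])
        for node in sorted(partition.assignments):
            w.writerow(
                [node, partition.assignments[node], int(node in partition.isolates)]
            )


def read_partition_table(path: str | Path) -> dict[int, int]:
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    return {int(r[0]): int(r[1]) for r in rows[1:]}


def run_analysis(config: RunConfig) -> dict:
    """Run one full analysis; returns the summary dict and writes all reports."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    network = _load_inputs(config)
    logger.info("loaded network: %d nodes, %d edges", network.n_nodes, network.n_edges)
    classes = SUBSETS[config.subset]
    if classes is not None:
        network = nm.subset_by_tissue(network, classes)
        logger.info(
            "subset=%s: %d nodes, %d edges", config.subset, network.n_nodes,
            network.n_edges,
        )
    if network.n_edges == 0:
        raise nm.InputError(
            f"network is edgeless after subset={config.subset!r}; nothing to detect"
        )

    tree = cd.walktrap_merge_tree(network, config.walk_length)
    partition = cd.best_partition(network, tree)
    curve = cd.modularity_curve(network, tree)
    sizes = classify_module_sizes(partition, config.major_threshold)
    logger.info(
        "detected %d modules (Q=%.4f), %d isolates", partition.M, partition.Q,
        len(partition.isolates),
    )

    write_partition_table(partition, out / "partition.csv")
    with open(out / "modularity_curve.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["n_modules", "Q"])
        for k, q in curve:
            w.writerow([k, f"{q:.10f}"])

    summary = {
        "subset": config.subset,
        "walk_length": config.walk_length,
        "n_nodes": network.n_nodes,
        "n_edges": network.n_edges,
        "n_modules": partition.M,
        "n_isolates": len(partition.isolates),
        "Q": round(partition.Q, 6),
        "major_modules": len(sizes.major),
        "small_blocks": len(sizes.blocks),
        "module_fractions": {
            int(m): {"e_mm": round(e, 6), "a_m": round(a, 6)}
            for m, (e, a) in sorted(partition.module_fractions.items())
        },
    }

    reference = _load_reference(config)
    if reference is not None:
        exclude = set(reference.ambiguous_nodes) | set(partition.isolates)
        comparison = pm.compare_partitions(
            partition.assignments, reference.assignments, exclude
        )
        overlap = pm.module_overlap_report(partition, reference)
        summary["reference_comparison"] = {
            "ari": round(comparison.ari, 6),
            "nmi": round(comparison.nmi, 6),
            "n_compared": comparison.n_compared(),
            "excluded_nodes": sorted(comparison.excluded),
            "mean_best_jaccard": round(overlap.mean_jaccard(), 6),
            "best_matches": [
                {
                    "detected_module": m.detected_module,
                    "reference_module": m.best_reference_module,
                    "jaccard": round(m.jaccard, 6),
                }
                for m in overlap.matches
            ],
        }

    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    return summary
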