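"""Quantitative comparison of module partitions.

Detected module maps are compared against a reference (a published table or a
planted ground truth) with the adjusted Rand index (permutation-model chance
correction), normalized mutual information (arithmetic-mean normalization), a
contingency table, and a per-module best-Jaccard-match report.  Ambiguous
reference nodes and isolate singletons are excluded from the scalar scores and
listed explicitly, so the comparison stays well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .community_detection import Partition
from .network_model import InputError, ReferencePartition


@dataclass(frozen=True)
class PartitionComparison:
    ari: float
    nmi: float
    contingency: pd.DataFrame  # rows: modules of a, columns: modules of b
    excluded: frozenset[int]

    def n_compared(self) -> int:
        return int(self.contingency.to_numpy().sum())


def compare_partitions(
    a: Mapping[int, int],
    b: Mapping[int, int],
    exclude: Iterable[int] = (),
) -> PartitionComparison:
    """ARI/NMI agreement between two node -> module maps on their shared nodes."""
    excluded = frozenset(exclude)
    shared = sorted((set(a) & set(b)) - excluded)
    if len(shared) < 2:
        raise InputError(
            f"need at least 2 shared nodes after exclusions, got {len(shared)}"
        )
    la = [a[n] for n in shared]
    lb = [b[n] for n in shared]
    contingency = pd.crosstab(
        pd.Series(la, name="a"), pd.Series(lb, name="b")
    )
    return PartitionComparison(
        ari=float(adjusted_rand_score(la, lb)),
        nmi=float(normalized_mutual_info_score(la, lb, average_method="arithmetic")),
        contingency=contingency,
        excluded=excluded,
    )


@dataclass(frozen=True)
class ModuleMatch:
    detected_module: int
    best_reference_module: int
    jaccard: float
    detected_size: int
    reference_size: int


@dataclass(frozen=True)
class OverlapReport:
    matches: tuple[ModuleMatch, ...]
    excluded: frozenset[int]  # ambiguous reference nodes and detected isolates

    def mean_jaccard(self) -> float:
        return float(np.mean([m.jaccard for m in self.matches]))


def module_overlap_report(
    detected: Partition, reference: ReferencePartition | Mapping[int, int]
) -> OverlapReport:
    """Best-Jaccard reference match for every detected (non-isolate) module."""
    if isinstance(reference, ReferencePartition):
        ref_assign = reference.assignments
        ambiguous = set(reference.ambiguous_nodes)
    else:
        ref_assign = dict(reference)
        ambiguous = set()
    excluded = ambiguous | set(detected.isolates)

    det_modules = {
        m: members - excluded
        for m, members in detected.modules().items()
        if not (members <= detected.isolates)
    }
    ref_modules: dict[int, set[int]] = {}
    for node, mod in ref_assign.items():
        if node not in excluded:
            ref_modules.setdefault(mod, set()).add(node)
    if not set().union(*det_modules.values(), set()) & set(ref_assign):
        raise InputError("detected and reference partitions share no nodes")

    matches = []
    for m, members in sorted(det_modules.items()):
        best_mod, best_j, best_size = -1, -1.0, 0
        for r, ref_members in sorted(ref_modules.items()):
            union = members | ref_members
            j = len(members & ref_members) / len(union) if union else 0.0
            if j > best_j:
                best_mod, best_j, best_size = r, j, len(ref_members)
        matches.append(
            ModuleMatch(m, best_mod, best_j, len(members), best_size)
        )
    return OverlapReport(matches=tuple(matches), excluded=frozenset(excluded))
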