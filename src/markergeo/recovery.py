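"""Taxonomy assignment and per-taxon genome recovery rates.

A cluster's taxon is the per-rank strict-majority consensus of its
annotated members' lineages; clusters that stay unassigned can inherit a
label from the phylogeny when every annotated leaf in their smallest
annotated clade agrees.  The genome recovery rate of a taxon for a set
of recovery methods (MAGs, isolates, SAGs) is then simply

    rate = #clusters of the taxon containing a member from any of those
           sources / #clusters of the taxon,

with the denominator restricted to clusters detected in at least one
metagenome.  Assembly-only clusters are the complement: populations seen
in assemblies but recovered by no method.
"""
from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .cluster import SequenceCluster, is_assembly_only

#: sentinel taxon meaning "all clusters regardless of taxon"
ALL = "__ALL__"

UNASSIGNED = "Unassigned"


def _split_lineage(lineage: str) -> list[str]:
    if not isinstance(lineage, str) or not lineage.strip():
        raise ValueError(f"malformed lineage string: {lineage!r}")
    ranks = [r.strip() for r in lineage.split(";")]
    if any(not r for r in ranks):
        raise ValueError(f"malformed lineage string (empty rank): {lineage!r}")
    return ranks


def consensus_taxonomy(lineages: Iterable[str | None]) -> str | None:
    """Per-rank strict-majority consensus lineage of annotated members.

    Unannotated members (None) are ignored.  Walking from the highest
    rank down, a rank label is kept when more than half of the annotated
    members carry it; the lineage is truncated at the first rank without
    a strict majority.  Returns None when nothing can be assigned.
    """
    annotated = [_split_lineage(l) for l in lineages if l is not None]
    if not annotated:
        return None
    n = len(annotated)
    consensus: list[str] = []
    depth = max(len(l) for l in annotated)
    for rank in range(depth):
        counts: dict[str, int] = {}
        for lin in annotated:
            if rank < len(lin):
                counts[lin[rank]] = counts.get(lin[rank], 0) + 1
        winner = None
        for label in sorted(counts):
            if counts[label] * 2 > n:
                winner = label
                break
        if winner is None:
            break
        consensus.append(winner)
    return ";".join(consensus) if consensus else None


def _unanimous_lineage(lineages: Sequence[str]) -> str | None:
    """The shared lineage when every annotated leaf agrees completely."""
    for l in lineages:
        _split_lineage(l)  # validate
    return lineages[0] if len(set(lineages)) == 1 else None


def propagate_taxonomy_from_tree(
    tree: TreeNode,
    assignments: Mapping[str, str | None],
) -> dict[str, tuple[str | None, bool]]:
    """Label unassigned tree tips from their phylogenetic neighborhood.

    An unassigned leaf inherits a lineage only when its smallest enclosing
    clade that contains any annotated leaf holds at least two annotated
    leaves and ALL of them carry the same lineage — a conservative,
    automated stand-in for manual neighborhood curation.  A single pass
    over the original assignments: newly propagated labels never seed
    further propagation.  Returns gene -> (lineage or None, propagated).
    """
    tip_names = {t.name for t in tree.tips()}
    missing = set(assignments) - tip_names
    if missing:
        raise KeyError(f"assignments reference leaves absent from the tree: {sorted(missing)}")
    annotated_leaves = {
        name for name, lin in assignments.items() if lin is not None
    }
    out: dict[str, tuple[str | None, bool]] = {
        name: (lin, False) for name, lin in assignments.items()
    }
    if not annotated_leaves:
        return out
    for tip in tree.tips():
        name = tip.name
        if name not in assignments or assignments[name] is not None:
            continue
        node = tip.parent
        while node is not None:
            clade_annotated = [
                assignments[t.name]
                for t in node.tips()
                if t.name in annotated_leaves
            ]
            if clade_annotated:
                break
            node = node.parent
        if node is None or len(clade_annotated) < 2:
            continue
        lineage = _unanimous_lineage(clade_annotated)
        if lineage is not None:
            out[name] = (lineage, True)
    return out


def _detected(
    cluster: SequenceCluster,
    detections: Mapping[str, float] | None,
    floor: float,
) -> bool:
    if detections is None:
        return True
    return detections.get(cluster.cluster_id, 0.0) > floor


def recovery_rate(
    clusters: Sequence[SequenceCluster],
    taxon: str,
    sources: Iterable[str],
    detections: Mapping[str, float] | None = None,
    detection_floor: float = 0.0,
) -> tuple[Fraction, float] | None:
    """Recovery rate of one taxon (or ALL) for a set of recovery methods.

    ``detections`` maps cluster_id to the maximum detection over samples;
    clusters at or below ``detection_floor`` are excluded from the
    denominator.  Returns (exact fraction, percentage), or None when the
    taxon has no eligible clusters (an absent row, not a zero rate).
    """
    sources = frozenset(sources)
    pool = [
        c
        for c in clusters
        if _detected(c, detections, detection_floor)
        and (taxon == ALL or (c.taxon or UNASSIGNED) == taxon)
    ]
    if not pool:
        return None
    hits = sum(1 for c in pool if c.source_flags & sources)
    frac = Fraction(hits, len(pool))
    return frac, float(frac) * 100.0


def recovery_report(
    clusters: Sequence[SequenceCluster],
    detections: Mapping[str, float] | None = None,
    detection_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-taxon recovery table across the standard source combinations.

    One row per taxon (plus Unassigned when present, plus an ALL summary
    row) with cluster counts per source and recovery-rate percentages for
    MAGs alone, isolates alone, MAG+isolate, and all genome methods.
    """
    pool = [c for c in clusters if _detected(c, detections, detection_floor)]
    taxa = sorted({c.taxon or UNASSIGNED for c in pool})
    combos = {
        "rate_MAG": frozenset({"MAG"}),
        "rate_isolate": frozenset({"isolate"}),
        "rate_MAG_isolate": frozenset({"MAG", "isolate"}),
        "rate_any_genome": frozenset({"MAG", "isolate", "SAG"}),
    }
    rows = []
    for taxon in taxa + [ALL]:
        sub = [c for c in pool if taxon == ALL or (c.taxon or UNASSIGNED) == taxon]
        if not sub:
            continue
        row = {
            "taxon": "ALL" if taxon == ALL else taxon,
            "n_clusters": len(sub),
            "n_MAG": sum(1 for c in sub if "MAG" in c.source_flags),
            "n_isolate": sum(1 for c in sub if "isolate" in c.source_flags),
            "n_SAG": sum(1 for c in sub if "SAG" in c.source_flags),
            "n_assembly_only": sum(1 for c in sub if is_assembly_only(c)),
        }
        for col, srcs in combos.items():
            row[col] = round(100.0 * sum(1 for c in sub if c.source_flags & srcs) / len(sub), 1)
        rows.append(row)
    cols = ["taxon", "n_clusters", "n_MAG", "n_isolate", "n_SAG", "n_assembly_only"] + list(combos)
    return pd.DataFrame(rows, columns=cols)


def whole_genome_detected(depth: Sequence[int] | np.ndarray, genome_detection: float = 0.5) -> bool:
    """Whether a genome counts as detected in a metagenome.

    True when at least ``genome_detection`` (default 50%) of genome
    positions are covered by one or more reads.
    """
    d = np.asarray(depth)
    if d.size == 0:
        raise ValueError("empty genome depth vector")
    return float(np.count_nonzero(d >= 1)) / d.size >= genome_detection


def genome_quality_filter(
    completion: float | None,
    redundancy: float | None,
    min_completion: float = 50.0,
    max_redundancy: float = 10.0,
) -> bool:
    """Medium-quality draft filter: completion >= 50% and redundancy <= 10%.

    Both bounds are inclusive.
    """
    if completion is None or redundancy is None:
        raise ValueError("completion and redundancy must both be present")
    return completion >= min_completion and redundancy <= max_redundancy
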