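"""Integration of detection profiles with sample/sequence structure.

The central object is the detection matrix: metagenome samples as rows,
cluster representatives as columns, each value the fraction of that
representative covered by at least one read in that sample.  Reference
genomes that no sample detects convincingly are removed (MAGs binned
from the profiled samples themselves are always kept), samples and
sequences are clustered hierarchically on their detection patterns, and
Shannon diversity / richness are summarised from the Q2Q3 coverage.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .recruit import CoverageProfile


def assemble_matrix(profiles: Sequence[CoverageProfile], value: str = "detection") -> pd.DataFrame:
    """Samples x representatives matrix of detection (or q2q3_mean) values.

    Pairs without a profile are 0.0; a duplicated (ref, sample) pair is an
    error.  Rows and columns are sorted lexicographically so the matrix is
    independent of profile order.
    """
    seen: set[tuple[str, str]] = set()
    for p in profiles:
        key = (p.ref_id, p.sample_id)
        if key in seen:
            raise ValueError(f"duplicate profile for ref {p.ref_id!r} in sample {p.sample_id!r}")
        seen.add(key)
    samples = sorted({p.sample_id for p in profiles})
    refs = sorted({p.ref_id for p in profiles})
    mat = pd.DataFrame(0.0, index=samples, columns=refs)
    for p in profiles:
        mat.loc[p.sample_id, p.ref_id] = getattr(p, value)
    mat.index.name = "sample_id"
    return mat


def filter_undetected_references(
    matrix: pd.DataFrame,
    ref_sources: Mapping[str, tuple[str, bool]],
    detection_filter: float = 0.9,
) -> pd.DataFrame:
    """Drop reference-genome columns never convincingly detected.

    ``ref_sources`` maps each representative to (source_type,
    from_profiled_samples).  A column backed by a reference genome — an
    isolate or SAG, or a MAG that does not originate from the profiled
    samples — is dropped unless its maximum detection over samples
    reaches ``detection_filter``.  Sample-derived MAGs and assembly-only
    columns are always kept.
    """
    keep = []
    for col in matrix.columns:
        if col not in ref_sources:
            raise KeyError(f"representative {col!r} missing from ref_sources")
        source_type, from_samples = ref_sources[col]
        is_reference = source_type in ("isolate", "SAG") or (
            source_type == "MAG" and not from_samples
        )
        if not is_reference or matrix[col].max() >= detection_filter:
            keep.append(col)
    return matrix[keep]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result on one axis of the matrix.

    ``labels`` are in the (lexicographic) order used to build the
    linkage, which makes the result invariant to input row order.
    """

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray | None

    @property
    def leaf_order(self) -> list[str]:
        if self.linkage_matrix is None:
            return list(self.labels)
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def cut(self, k: int) -> dict[str, int]:
        """Partition into k flat clusters; returns label -> cluster index."""
        if self.linkage_matrix is None:
            return {lab: 1 for lab in self.labels}
        assign = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assign)))

    def merge_heights(self) -> list[float]:
        if self.linkage_matrix is None:
            return []
        return [float(h) for h in self.linkage_matrix[:, 2]]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string (heights as branch lengths)."""
        if self.linkage_matrix is None:
            return f"{self.labels[0]};"
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        rep: dict[int, str] = {i: self.labels[i] for i in range(n)}
        for t, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            rep[n + t] = f"({rep[a]}:{la:.6f},{rep[b]}:{lb:.6f})"
            height[n + t] = h
        return rep[n + len(self.linkage_matrix) - 1] + ";"


def hcluster(
    matrix: pd.DataFrame,
    axis: str = "samples",
    method: str = "ward",
    metric: str = "euclidean",
) -> Dendrogram:
    """Hierarchically cluster samples (rows) or sequences (columns).

    Ward linkage on Euclidean distances by default.  Labels are sorted
    before clustering so permuting the input leaves the result unchanged.
    """
    if axis == "samples":
        data = matrix
    elif axis == "sequences":
        data = matrix.T
    else:
        raise ValueError("axis must be 'samples' or 'sequences'")
    data = data.sort_index()
    labels = tuple(data.index)
    if len(labels) < 2:
        return Dendrogram(labels=labels, linkage_matrix=None)
    Z = linkage(data.to_numpy(dtype=float), method=method, metric=metric)
    return Dendrogram(labels=labels, linkage_matrix=Z)


def shannon_and_richness(abundance: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon diversity H and richness S.

    Rows are samples, columns representatives, values the per-sample Q2Q3
    coverage (or any non-negative abundance proxy).  H uses natural log;
    a sample with one or zero non-zero entries has H = 0.
    """
    vals = abundance.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("abundances must be non-negative")
    out = []
    for sample, row in zip(abundance.index, vals):
        total = row.sum()
        s = int(np.count_nonzero(row > 0))
        if total <= 0 or s <= 1:
            h = 0.0
        else:
            p = row[row > 0] / total
            h = float(-(p * np.log(p)).sum())
        out.append({"sample_id": sample, "shannon": h, "richness": s})
    return pd.DataFrame(out, columns=["sample_id", "shannon", "richness"])
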