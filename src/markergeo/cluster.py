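"""Greedy dereplication of marker nucleotide sequences.

Sequences are clustered at a nucleotide-identity threshold (default 97%,
a conservative boundary for ribosomal proteins whose identity between
distinct species runs higher than the 95% whole-genome convention).
Identity is computed from a global alignment with free terminal gaps
("glocal"), so an extended open reading frame clusters with its core as
long as the shorter sequence — the target — is well covered.  Each
cluster also carries the provenance of its members (isolate genome, MAG,
SAG, or raw metagenomic assembly), which is what ultimately powers the
genome-recovery bookkeeping.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align

from .hits import SOURCE_TYPES, Thresholds

_DNA_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class SequenceCluster:
    cluster_id: str
    representative_id: str
    member_ids: tuple[str, ...]
    source_flags: frozenset = frozenset()
    taxon: str | None = None

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError(
                f"representative {self.representative_id!r} not among members of {self.cluster_id}"
            )


def _make_aligner(match: float = 2.0, mismatch: float = -3.0,
                  gap_open: float = -5.0, gap_extend: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free terminal gaps on both sequences -> glocal alignment
    aligner.open_end_gap_score = 0.0
    aligner.extend_end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> tuple[float, float]:
    """Glocal identity and target coverage between two DNA sequences.

    Identity counts identical aligned positions over all alignment columns
    excluding terminal-gap columns (``N`` never counts as a match).
    Target coverage is the fraction of the shorter sequence aligned to the
    other, so a full-length gene and its exact fragment score (1.0, 1.0).
    """
    a, b = a.upper(), b.upper()
    for name, s in (("first", a), ("second", b)):
        if not s:
            raise ValueError(f"{name} sequence is empty")
        if not set(s) <= _DNA_ALPHABET:
            raise ValueError(f"{name} sequence has non-DNA characters: {sorted(set(s) - _DNA_ALPHABET)}")
    if a == b:
        return 1.0, 1.0
    aln = _ALIGNER.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    if len(blocks_a) == 0:
        return 0.0, 0.0
    matches = 0
    aligned_len = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        aligned_len += ae - as_
        for ca, cb in zip(a[as_:ae], b[bs:be]):
            if ca == cb and ca != "N":
                matches += 1
    # internal gap columns sit between consecutive aligned blocks
    internal_gaps = 0
    for i in range(1, len(blocks_a)):
        internal_gaps += blocks_a[i][0] - blocks_a[i - 1][1]
        internal_gaps += blocks_b[i][0] - blocks_b[i - 1][1]
    core_cols = aligned_len + internal_gaps
    identity = matches / core_cols if core_cols else 0.0
    target_coverage = aligned_len / min(len(a), len(b))
    return identity, target_coverage


def cluster_greedy(
    seqs: Mapping[str, str],
    t: Thresholds | None = None,
    identity: float | None = None,
    min_target_coverage: float | None = None,
) -> list[SequenceCluster]:
    """Greedy centroid clustering against cluster representatives.

    Sequences are visited longest-first (ties broken by id) and join the
    first existing cluster whose representative they match at
    ``identity >= threshold`` and ``target_coverage >= min coverage``;
    otherwise they seed a new cluster and become its representative.
    Output is sorted by descending cluster size, then cluster id.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    t = t or Thresholds()
    id_thr = t.cluster_identity if identity is None else identity
    cov_thr = t.min_target_coverage if min_target_coverage is None else min_target_coverage
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    reps: list[str] = []
    members: list[list[str]] = []
    for sid in order:
        seq = seqs[sid]
        for ci, rep in enumerate(reps):
            ident, cov = pairwise_identity(seq, seqs[rep])
            if ident >= id_thr and cov >= cov_thr:
                members[ci].append(sid)
                break
        else:
            reps.append(sid)
            members.append([sid])
    clusters = [
        SequenceCluster(
            cluster_id=f"C{ci:05d}",
            representative_id=rep,
            member_ids=tuple(mem),
        )
        for ci, (rep, mem) in enumerate(zip(reps, members))
    ]
    clusters.sort(key=lambda c: (-len(c.member_ids), c.cluster_id))
    return clusters


def attach_provenance(
    clusters: Sequence[SequenceCluster],
    roster: Mapping[str, str],
    gene_sources: Mapping[str, str],
) -> list[SequenceCluster]:
    """Annotate each cluster with the union of its members' source types.

    Clusters whose flags are exactly ``{metagenome_assembly}`` are the
    "assembly-only" populations: seen in assemblies, in no genome.
    """
    out = []
    for c in clusters:
        flags = set()
        for gid in c.member_ids:
            if gid not in gene_sources:
                raise KeyError(f"gene {gid!r} has no source mapping")
            src = gene_sources[gid]
            if src not in roster:
                raise KeyError(f"source {src!r} of gene {gid!r} not in roster")
            st = roster[src]
            if st not in SOURCE_TYPES:
                raise KeyError(f"source {src!r} has unknown type {st!r}")
            flags.add(st)
        out.append(replace(c, source_flags=frozenset(flags)))
    return out


def is_assembly_only(cluster: SequenceCluster) -> bool:
    return cluster.source_flags == frozenset({"metagenome_assembly"})


def recluster_representatives(
    rep_seqs: Mapping[str, str],
    recluster_identity: float,
    coarse_identity: float | None = None,
    min_target_coverage: float = 0.8,
) -> list[SequenceCluster]:
    """Re-cluster representative sequences at a finer identity threshold.

    Used to split clusters that at the coarse threshold lump several
    distinct populations (e.g. near-identical isolate genomes).  A finer
    threshold below the coarse one is suspicious but allowed, with a
    warning.
    """
    if coarse_identity is not None and recluster_identity < coarse_identity:
        warnings.warn(
            f"recluster identity {recluster_identity} is coarser than the original "
            f"{coarse_identity}; cluster count may decrease",
            stacklevel=2,
        )
    return cluster_greedy(rep_seqs, identity=recluster_identity, min_target_coverage=min_target_coverage)


def clusters_to_frame(
    clusters: Sequence[SequenceCluster],
    gene_sources: Mapping[str, str] | None = None,
    roster: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Long-format cluster table: one row per member."""
    rows = []
    for c in clusters:
        for gid in c.member_ids:
            src = gene_sources.get(gid, "") if gene_sources else ""
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "representative_id": c.representative_id,
                    "member_id": gid,
                    "source_id": src,
                    "source_type": roster.get(src, "") if roster else "",
                    "taxon": c.taxon or "",
                }
            )
    return pd.DataFrame(
        rows, columns=["cluster_id", "representative_id", "member_id", "source_id", "source_type", "taxon"]
    )
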