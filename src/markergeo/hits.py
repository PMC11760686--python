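"""Marker-gene hit ingestion, filtering, and marker-family selection.

Marker occurrences arrive as HMMER ``--domtblout`` domain tables (one line
per domain hit of a profile HMM against a gene).  A hit is retained when
it spans enough of the model (model alignment coverage) and when the gene
call is a complete open reading frame, which removes partial genes at
contig edges and other assembly artifacts.  A copy-number survey across
genomes then identifies which candidate family behaves as a single-copy
core gene, and a median screen on metagenome hit counts discards families
that are under- or over-assembled relative to their peers.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

SOURCE_TYPES = ("isolate", "MAG", "SAG", "metagenome_assembly")

#: source types that represent recovered genomes (as opposed to raw assemblies)
GENOME_SOURCE_TYPES = ("isolate", "MAG", "SAG")


@dataclass(frozen=True)
class Thresholds:
    """All numeric cut-offs of the workflow, with their defaults.

    Fractions are in [0, 1]; completion/redundancy are percentages.
    """

    min_model_coverage: float = 0.8
    require_complete_orf: bool = True
    cluster_identity: float = 0.97
    recluster_identity: float = 0.98
    min_target_coverage: float = 0.8
    max_seq_gap_fraction: float = 0.5
    detection_filter: float = 0.9
    genome_detection: float = 0.5
    min_completion: float = 50.0
    max_redundancy: float = 10.0
    min_taxonomy_similarity: float = 0.9

    def __post_init__(self) -> None:
        fracs = dict(
            min_model_coverage=self.min_model_coverage,
            cluster_identity=self.cluster_identity,
            recluster_identity=self.recluster_identity,
            min_target_coverage=self.min_target_coverage,
            max_seq_gap_fraction=self.max_seq_gap_fraction,
            detection_filter=self.detection_filter,
            genome_detection=self.genome_detection,
            min_taxonomy_similarity=self.min_taxonomy_similarity,
        )
        for name, v in fracs.items():
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        for name, v in (("min_completion", self.min_completion), ("max_redundancy", self.max_redundancy)):
            if not 0.0 <= float(v) <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")


@dataclass(frozen=True)
class RawDomHit:
    """One domain line of a ``--domtblout`` table (hmmsearch dialect).

    The target is the gene sequence, the query is the profile HMM.
    """

    gene_id: str
    gene_len: int
    model_name: str
    model_length: int
    full_evalue: float
    full_score: float
    dom_score: float
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    env_from: int
    env_to: int


@dataclass(frozen=True)
class MarkerHit:
    """A marker-gene occurrence tied to its source assembly or genome."""

    gene_id: str
    source_id: str
    source_type: str
    model_name: str
    model_length: int
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    model_coverage: float
    gene_coverage: float
    orf_complete: bool
    nt_seq: str
    aa_seq: str

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(f"unknown source_type {self.source_type!r}")
        if not (1 <= self.hmm_from <= self.hmm_to <= self.model_length):
            raise ValueError(
                f"model coordinates out of order for {self.gene_id}: "
                f"{self.hmm_from}..{self.hmm_to} (model length {self.model_length})"
            )
        for name, v in (("model_coverage", self.model_coverage), ("gene_coverage", self.gene_coverage)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


# 22 mandatory whitespace-delimited columns precede the free-text description.
_N_DOMTBL_COLS = 22


def parse_domtblout(path: str | Path) -> list[RawDomHit]:
    """Parse a domtblout file into raw domain hits, preserving line order.

    Lines starting with ``#`` are comments.  A data line with fewer than
    the 22 mandatory columns raises a :class:`ValueError` naming the line.
    """
    hits: list[RawDomHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _N_DOMTBL_COLS:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {_N_DOMTBL_COLS} columns, got {len(cols)}"
                )
            try:
                hits.append(
                    RawDomHit(
                        gene_id=cols[0],
                        gene_len=int(cols[2]),
                        model_name=cols[3],
                        model_length=int(cols[5]),
                        full_evalue=float(cols[6]),
                        full_score=float(cols[7]),
                        dom_score=float(cols[13]),
                        hmm_from=int(cols[15]),
                        hmm_to=int(cols[16]),
                        ali_from=int(cols[17]),
                        ali_to=int(cols[18]),
                        env_from=int(cols[19]),
                        env_to=int(cols[20]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field ({exc})") from exc
    return hits


def compute_model_coverage(hmm_from: int, hmm_to: int, model_length: int) -> float:
    """Fraction of the profile HMM's match states spanned by a hit."""
    if not (1 <= hmm_from <= hmm_to <= model_length):
        raise ValueError(
            f"require 1 <= hmm_from <= hmm_to <= model_length, got "
            f"({hmm_from}, {hmm_to}, {model_length})"
        )
    return (hmm_to - hmm_from + 1) / model_length


def build_marker_hits(
    raw_hits: Iterable[RawDomHit],
    nt_seqs: Mapping[str, str],
    aa_seqs: Mapping[str, str],
    gene_sources: Mapping[str, str],
    roster: Mapping[str, str],
    orf_complete: Mapping[str, bool],
) -> list[MarkerHit]:
    """Join raw domain hits with sequences, sources and ORF metadata.

    ``gene_sources`` maps gene_id -> source_id, ``roster`` maps
    source_id -> source_type, ``orf_complete`` maps gene_id -> flag.
    """
    out = []
    for h in raw_hits:
        if h.gene_id not in nt_seqs:
            raise KeyError(f"gene {h.gene_id!r} has a hit but no nucleotide sequence")
        src = gene_sources[h.gene_id]
        if src not in roster:
            raise KeyError(f"source {src!r} of gene {h.gene_id!r} not in roster")
        gene_cov = (h.ali_to - h.ali_from + 1) / h.gene_len if h.gene_len else 0.0
        out.append(
            MarkerHit(
                gene_id=h.gene_id,
                source_id=src,
                source_type=roster[src],
                model_name=h.model_name,
                model_length=h.model_length,
                hmm_from=h.hmm_from,
                hmm_to=h.hmm_to,
                ali_from=h.ali_from,
                ali_to=h.ali_to,
                model_coverage=compute_model_coverage(h.hmm_from, h.hmm_to, h.model_length),
                gene_coverage=min(1.0, gene_cov),
                orf_complete=bool(orf_complete.get(h.gene_id, True)),
                nt_seq=nt_seqs[h.gene_id],
                aa_seq=aa_seqs.get(h.gene_id, ""),
            )
        )
    return out


def filter_hits(hits: Sequence[MarkerHit], t: Thresholds) -> list[MarkerHit]:
    """Keep hits with sufficient model coverage and (optionally) complete ORFs.

    Input order is preserved; the operation is idempotent.
    """
    return [
        h
        for h in hits
        if h.model_coverage >= t.min_model_coverage
        and (h.orf_complete or not t.require_complete_orf)
    ]


def copy_number_survey(
    hits: Sequence[MarkerHit],
    roster_sources: Iterable[str],
) -> pd.DataFrame:
    """Count retained hits per (source_id, model_name).

    Every source in ``roster_sources`` is reported for every model seen in
    the hits, with zero for absent pairs, so single-copy and missing-marker
    genomes are both visible.
    """
    sources = sorted(set(roster_sources))
    models = sorted({h.model_name for h in hits})
    counts: dict[tuple[str, str], int] = {}
    for h in hits:
        key = (h.source_id, h.model_name)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"source_id": s, "model_name": m, "copy_count": counts.get((s, m), 0)}
        for s in sources
        for m in models
    ]
    return pd.DataFrame(rows, columns=["source_id", "model_name", "copy_count"])


def select_marker(
    survey: pd.DataFrame,
    metagenome_hit_counts: Mapping[str, int],
    rel_window: float = 0.5,
) -> str:
    """Pick the working marker family.

    Candidates whose metagenome hit count deviates from the median count
    across candidates by more than ``rel_window`` (default +/-50%) are
    screened out as under- or over-assembled.  Among the survivors the
    family maximising the fraction of genomes carrying it in exactly
    single copy wins; ties fall back to the fraction of genomes with the
    family present at all, then to the lexicographically smallest name.
    """
    models = sorted(survey["model_name"].unique())
    if not models:
        raise ValueError("no candidate marker models in the survey")
    counts = {m: int(metagenome_hit_counts.get(m, 0)) for m in models}
    med = statistics.median(counts.values())
    kept = [m for m in models if (1 - rel_window) * med <= counts[m] <= (1 + rel_window) * med]
    if not kept:
        raise ValueError(
            "every candidate marker was screened out as under- or over-assembled; "
            "relax rel_window or supply the marker explicitly"
        )
    n_genomes = survey["source_id"].nunique()
    best = None
    for m in kept:
        sub = survey[survey["model_name"] == m]
        frac_single = (sub["copy_count"] == 1).sum() / n_genomes
        frac_present = (sub["copy_count"] >= 1).sum() / n_genomes
        key = (-frac_single, -frac_present, m)
        if best is None or key < best[0]:
            best = (key, m)
    return best[1]


def hits_to_frame(hits: Sequence[MarkerHit]) -> pd.DataFrame:
    """Tabulate hits for TSV export (sequences included)."""
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "source_id": h.source_id,
                "source_type": h.source_type,
                "model_name": h.model_name,
                "model_length": h.model_length,
                "hmm_from": h.hmm_from,
                "hmm_to": h.hmm_to,
                "ali_from": h.ali_from,
                "ali_to": h.ali_to,
                "model_coverage": round(h.model_coverage, 6),
                "gene_coverage": round(h.gene_coverage, 6),
                "orf_complete": int(h.orf_complete),
                "nt_seq": h.nt_seq,
                "aa_seq": h.aa_seq,
            }
            for h in hits
        ]
    )
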