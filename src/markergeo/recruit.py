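"""Metagenomic read recruitment against cluster representatives.

Reads are placed on the (short) representative sequences with an exact
k-mer seeded, ungapped scorer on both strands; alternatively precomputed
alignments arrive as a SAM file with AS/XS score tags.  From per-sample
alignments the module derives the two statistics the workflow runs on:

* detection — the fraction of reference positions covered by at least
  one read, robust to non-specific recruitment;
* Q2Q3 coverage — mean depth over the interquartile positions of the
  depth distribution, robust to coverage spikes.

A read whose best and second-best placement scores tie is multi-mapped;
the fraction of such reads among all mapped reads measures non-specific
recruitment between closely related references.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadAlignment:
    read_id: str
    ref_id: str | None
    ref_start: int
    ref_end: int
    score: int
    secondary_best_score: int | None
    is_mapped: bool
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.is_mapped:
            if self.ref_id is None or not 0 <= self.ref_start < self.ref_end:
                raise ValueError(f"mapped read {self.read_id} has invalid coordinates")
            if self.secondary_best_score is not None and self.secondary_best_score > self.score:
                raise ValueError(f"secondary score exceeds primary for {self.read_id}")

    @property
    def is_multimapped(self) -> bool:
        return self.is_mapped and self.secondary_best_score == self.score


@dataclass(frozen=True)
class CoverageProfile:
    ref_id: str
    sample_id: str
    depth: np.ndarray
    detection: float
    q2q3_mean: float
    mapped_reads: int


def _build_index(refs: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for rid in sorted(refs):
        seq = refs[rid]
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], []).append((rid, pos))
    return index


def map_reads(
    reads: Iterable[tuple[str, str]],
    refs: Mapping[str, str],
    k: int = 15,
    match: int = 2,
    mismatch: int = -3,
    min_score: int = 0,
) -> list[ReadAlignment]:
    """Exact-seed, ungapped read mapper.

    Every k-mer of the read (sampled every k bases plus the final window)
    is looked up in the reference index on both strands; each candidate
    diagonal that places the read fully inside a reference is scored
    ungapped over the whole read.  The primary placement maximises the
    score, with ties broken by reference id then leftmost position;
    the best score among all other placements is kept so multi-mapping
    can be recognised downstream.  Reads whose best score falls below
    ``min_score`` are reported unmapped.
    """
    if not refs:
        raise ValueError("no reference sequences")
    reads = list(reads)
    if reads and max(len(s) for _, s in reads) < k:
        raise ValueError(f"seed length k={k} exceeds every read length")
    index = _build_index(refs, k)
    enc = {rid: np.frombuffer(seq.encode(), dtype=np.uint8) for rid, seq in refs.items()}
    out: list[ReadAlignment] = []
    span = match - mismatch
    for read_id, seq in reads:
        L = len(seq)
        placements: dict[tuple[str, int, str], int] = {}
        if L >= k:
            for strand in "+-":
                s = seq if strand == "+" else reverse_complement(seq)
                s_arr = np.frombuffer(s.encode(), dtype=np.uint8)
                offsets = list(range(0, L - k + 1, k))
                if offsets[-1] != L - k:
                    offsets.append(L - k)
                seen: set[tuple[str, int]] = set()
                for off in offsets:
                    for rid, pos in index.get(s[off : off + k], ()):
                        start = pos - off
                        if start < 0 or start + L > len(refs[rid]) or (rid, start) in seen:
                            continue
                        seen.add((rid, start))
                        key = (rid, start, strand)
                        if key in placements:
                            continue
                        m = int(np.count_nonzero(enc[rid][start : start + L] == s_arr))
                        placements[key] = span * m + mismatch * L
        if not placements:
            out.append(ReadAlignment(read_id, None, 0, 0, 0, None, False))
            continue
        ranked = sorted(placements.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1], kv[0][2]))
        (rid, start, strand), best = ranked[0]
        if best < min_score:
            out.append(ReadAlignment(read_id, None, 0, 0, best, None, False))
            continue
        secondary = ranked[1][1] if len(ranked) > 1 else None
        out.append(ReadAlignment(read_id, rid, start, start + L, best, secondary, True, strand))
    return out


def ingest_sam(path: str | Path, refs: Mapping[str, str]) -> list[ReadAlignment]:
    """Read primary alignments from a SAM file with AS (and optional XS) tags."""
    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                out.append(ReadAlignment(rec.query_name, None, 0, 0, 0, None, False))
                continue
            rid = rec.reference_name
            if rid not in refs:
                raise KeyError(f"SAM reference {rid!r} absent from the reference set")
            score = int(rec.get_tag("AS"))
            xs = int(rec.get_tag("XS")) if rec.has_tag("XS") else None
            out.append(
                ReadAlignment(
                    rec.query_name,
                    rid,
                    rec.reference_start,
                    rec.reference_end,
                    score,
                    xs,
                    True,
                    "-" if rec.is_reverse else "+",
                )
            )
    return out


def write_sam(path: str | Path, alignments: Sequence[ReadAlignment], refs: Mapping[str, str]) -> None:
    """Write mapped alignments as a minimal SAM (ungapped CIGAR, AS/XS tags)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": rid, "LN": len(refs[rid])} for rid in sorted(refs)],
    }
    tid = {rid: i for i, rid in enumerate(sorted(refs))}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for a in alignments:
            if not a.is_mapped:
                continue
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = a.read_id
            rec.reference_id = tid[a.ref_id]
            rec.reference_start = a.ref_start
            rec.mapping_quality = 255
            rec.flag = 16 if a.strand == "-" else 0
            rec.cigartuples = [(0, a.ref_end - a.ref_start)]
            tags = [("AS", a.score)]
            if a.secondary_best_score is not None:
                tags.append(("XS", a.secondary_best_score))
            rec.tags = tags
            sam.write(rec)


def q2q3_mean(depth: Sequence[int] | np.ndarray) -> float:
    """Mean depth over the interquartile (middle-half) positions.

    Positions are ranked by depth; the mean is taken over 1-based ranks
    ceil(n/4)+1 .. floor(3n/4).  Vectors shorter than 4 use all positions.
    """
    d = np.asarray(depth, dtype=float)
    if d.size == 0:
        raise ValueError("empty depth vector")
    if d.size < 4:
        return float(d.mean())
    s = np.sort(d)
    lo = math.ceil(d.size / 4)
    hi = math.floor(3 * d.size / 4)
    return float(s[lo:hi].mean())


def build_profile(
    alignments: Sequence[ReadAlignment],
    ref_id: str,
    sample_id: str,
    ref_length: int,
) -> CoverageProfile:
    """Per-position depth, detection, and Q2Q3 summary for one (ref, sample)."""
    if ref_length <= 0:
        raise ValueError("ref_length must be positive")
    delta = np.zeros(ref_length + 1, dtype=np.int64)
    n = 0
    for a in alignments:
        if not a.is_mapped:
            continue
        if a.ref_id != ref_id:
            raise ValueError(f"alignment of {a.read_id} is on {a.ref_id}, not {ref_id}")
        if a.ref_start < 0 or a.ref_end > ref_length:
            raise ValueError(f"alignment of {a.read_id} out of reference bounds")
        delta[a.ref_start] += 1
        delta[a.ref_end] -= 1
        n += 1
    depth = np.cumsum(delta[:-1])
    detection = float(np.count_nonzero(depth >= 1)) / ref_length
    return CoverageProfile(
        ref_id=ref_id,
        sample_id=sample_id,
        depth=depth,
        detection=detection,
        q2q3_mean=q2q3_mean(depth),
        mapped_reads=n,
    )


def profiles_for_sample(
    alignments: Sequence[ReadAlignment],
    refs: Mapping[str, str],
    sample_id: str,
) -> list[CoverageProfile]:
    """Split one sample's alignments by reference and profile each."""
    by_ref: dict[str, list[ReadAlignment]] = {rid: [] for rid in refs}
    for a in alignments:
        if a.is_mapped:
            by_ref[a.ref_id].append(a)
    return [
        build_profile(by_ref[rid], rid, sample_id, len(refs[rid]))
        for rid in sorted(refs)
    ]


def nonspecific_fraction(alignments: Sequence[ReadAlignment]) -> float:
    """Multi-mapped reads / mapped reads for one sample (0 when none map)."""
    mapped = [a for a in alignments if a.is_mapped]
    if not mapped:
        return 0.0
    multi = sum(1 for a in mapped if a.is_multimapped)
    return multi / len(mapped)


def profiles_to_frame(profiles: Sequence[CoverageProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_id": p.ref_id,
                "sample_id": p.sample_id,
                "detection": round(p.detection, 6),
                "q2q3_mean": round(p.q2q3_mean, 6),
                "mapped_reads": p.mapped_reads,
            }
            for p in profiles
        ],
        columns=["ref_id", "sample_id", "detection", "q2q3_mean", "mapped_reads"],
    )
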