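"""End-to-end orchestration: detect -> cluster -> recruit -> tree -> integrate -> recover.

Each stage reads the previous stage's plain-text outputs, writes its own,
and records its inputs' checksums, parameters and record counts in a JSON
manifest.  On a re-run a stage is skipped when its outputs exist and its
inputs' checksums are unchanged, so corrupting or replacing an
intermediate re-executes only the stages downstream of it.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import cluster as clu
from . import geography as geo
from . import hits as hd
from . import io_utils as io
from . import phylo
from . import recovery as rec
from . import recruit as rr

log = logging.getLogger("markergeo")


class ConfigError(Exception):
    """Invalid run configuration (exit code 2 from the CLI)."""


class StageError(Exception):
    """A pipeline stage failed (exit code 3 from the CLI)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    genes_nt: Path
    genes_aa: Path
    hits: Path
    roster: Path
    reads_dir: Path
    out_dir: Path
    taxonomy: Path | None = None
    marker: str = "auto"
    thresholds: hd.Thresholds = field(default_factory=hd.Thresholds)
    k: int = 15
    match: int = 2
    mismatch: int = -3
    min_score: int = 0
    max_col_gap_fraction: float = 0.5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        thr = raw.pop("thresholds", {})
        try:
            thresholds = hd.Thresholds(**thr)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid thresholds: {exc}") from exc
        missing = {"genes_nt", "genes_aa", "hits", "roster", "reads_dir", "out_dir"} - set(raw)
        if missing:
            raise ConfigError(f"missing required config keys: {sorted(missing)}")
        for key in ("genes_nt", "genes_aa", "hits", "roster", "reads_dir", "taxonomy", "out_dir"):
            if key in raw and raw[key] is not None:
                raw[key] = Path(raw[key])
        cfg = cls(thresholds=thresholds, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("genes_nt", "genes_aa", "hits", "roster", "reads_dir"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"input path for {key!r} does not exist: {p}")
        if self.taxonomy is not None and not Path(self.taxonomy).exists():
            raise ConfigError(f"taxonomy path does not exist: {self.taxonomy}")
        if self.k < 1:
            raise ConfigError("seed length k must be positive")


# ---------------------------------------------------------------------------
# stage implementations


def stage_detect(cfg: RunConfig, out: Path) -> dict:
    raw = hd.parse_domtblout(cfg.hits)
    nt, attrs = io.read_fasta_attrs(cfg.genes_nt)
    aa, _ = io.read_fasta_attrs(cfg.genes_aa)
    roster_df = io.read_roster(cfg.roster)
    roster = dict(zip(roster_df["source_id"], roster_df["source_type"]))
    gene_sources = {g: a["source"] for g, a in attrs.items() if "source" in a}
    orf_complete = {g: a.get("complete", "1") == "1" for g, a in attrs.items()}
    marker_hits = hd.build_marker_hits(raw, nt, aa, gene_sources, roster, orf_complete)
    kept = hd.filter_hits(marker_hits, cfg.thresholds)
    genome_hits = [h for h in kept if h.source_type in hd.GENOME_SOURCE_TYPES]
    assembly_hits = [h for h in kept if h.source_type == "metagenome_assembly"]
    if cfg.marker == "auto":
        genome_sources = roster_df.loc[
            roster_df["source_type"].isin(hd.GENOME_SOURCE_TYPES), "source_id"
        ]
        survey = hd.copy_number_survey(genome_hits, genome_sources)
        meta_counts: dict[str, int] = {}
        for h in assembly_hits:
            meta_counts[h.model_name] = meta_counts.get(h.model_name, 0) + 1
        marker = hd.select_marker(survey, meta_counts)
    else:
        marker = cfg.marker
        if not any(h.model_name == marker for h in kept):
            raise ValueError(f"no retained hits for marker {marker!r}")
    final = [h for h in kept if h.model_name == marker]
    io.write_tsv(out / "hits.tsv", hd.hits_to_frame(final))
    return {"marker": marker, "n_hits_raw": len(raw), "n_hits_kept": len(final)}


def stage_cluster(cfg: RunConfig, out: Path) -> dict:
    df = pd.read_csv(out / "hits.tsv", sep="\t", dtype={"orf_complete": int})
    seqs = dict(zip(df["gene_id"], df["nt_seq"]))
    aa = dict(zip(df["gene_id"], df["aa_seq"]))
    gene_sources = dict(zip(df["gene_id"], df["source_id"]))
    roster_df = io.read_roster(cfg.roster)
    roster = dict(zip(roster_df["source_id"], roster_df["source_type"]))
    clusters = clu.cluster_greedy(seqs, cfg.thresholds)
    clusters = clu.attach_provenance(clusters, roster, gene_sources)
    io.write_tsv(out / "clusters.tsv", clu.clusters_to_frame(clusters, gene_sources, roster))
    reps = {c.representative_id: seqs[c.representative_id] for c in clusters}
    io.write_fasta(out / "reps_nt.fasta", reps)
    io.write_fasta(out / "reps_aa.fasta", {r: aa[r] for r in reps})
    return {"n_sequences": len(seqs), "n_clusters": len(clusters)}


def stage_recruit(cfg: RunConfig, out: Path) -> dict:
    refs = io.read_fasta(out / "reps_nt.fasta")
    fastqs = sorted(Path(cfg.reads_dir).glob("*.fastq"))
    if not fastqs:
        raise ValueError(f"no FASTQ files in {cfg.reads_dir}")
    profiles: list[rr.CoverageProfile] = []
    ns_rows = []
    for fq in fastqs:
        sample = fq.stem
        reads = io.read_fastq(fq)
        alns = rr.map_reads(reads, refs, k=cfg.k, match=cfg.match,
                            mismatch=cfg.mismatch, min_score=cfg.min_score)
        profiles.extend(rr.profiles_for_sample(alns, refs, sample))
        ns_rows.append(
            {
                "sample_id": sample,
                "n_reads": len(reads),
                "n_mapped": sum(1 for a in alns if a.is_mapped),
                "nonspecific_fraction": round(rr.nonspecific_fraction(alns), 6),
            }
        )
    io.write_tsv(out / "profiles.tsv", rr.profiles_to_frame(profiles))
    io.write_tsv(out / "nonspecific.tsv", pd.DataFrame(ns_rows))
    return {"n_samples": len(fastqs), "n_profiles": len(profiles)}


def stage_tree(cfg: RunConfig, out: Path) -> dict:
    aa = io.read_fasta(out / "reps_aa.fasta")
    dropped: list[str] = []
    if len(aa) == 1:
        (out / "tree.nwk").write_text(f"{next(iter(aa))};\n")
        n_tips = 1
    else:
        aln = phylo.progressive_msa(aa)
        aln = phylo.trim_gappy_columns(aln, cfg.max_col_gap_fraction)
        cleaned = phylo.drop_gappy_sequences(aln, cfg.thresholds.max_seq_gap_fraction)
        dropped = sorted(set(aln.rows) - set(cleaned.rows))
        if len(cleaned.rows) == 1:
            (out / "tree.nwk").write_text(f"{next(iter(cleaned.rows))};\n")
            n_tips = 1
        else:
            dm = phylo.protein_distance_matrix(cleaned)
            tree = phylo.nj_tree(dm)
            phylo.write_newick(tree, out / "tree.nwk")
            n_tips = len(cleaned.rows)
    flags = []
    if n_tips >= 3:
        flags = phylo.flag_long_branches(phylo.read_newick(out / "tree.nwk"))
    io.write_tsv(out / "longbranch.tsv", pd.DataFrame({"gene_id": flags}))
    io.write_tsv(out / "dropped_sequences.tsv", pd.DataFrame({"gene_id": dropped}))
    return {"n_tips": n_tips, "n_dropped": len(dropped), "n_long_branches": len(flags)}


def _profiles_from_tsv(path: Path) -> list[rr.CoverageProfile]:
    df = pd.read_csv(path, sep="\t")
    empty = np.array([], dtype=np.int64)
    return [
        rr.CoverageProfile(
            ref_id=row.ref_id,
            sample_id=row.sample_id,
            depth=empty,
            detection=float(row.detection),
            q2q3_mean=float(row.q2q3_mean),
            mapped_reads=int(row.mapped_reads),
        )
        for row in df.itertuples()
    ]


def _ref_sources(out: Path, cfg: RunConfig) -> dict[str, tuple[str, bool]]:
    cl = pd.read_csv(out / "clusters.tsv", sep="\t")
    roster_df = io.read_roster(cfg.roster)
    from_samples = dict(zip(roster_df["source_id"], roster_df["from_profiled_samples"]))
    reps = cl[cl["member_id"] == cl["representative_id"]]
    return {
        r.representative_id: (r.source_type, bool(from_samples.get(r.source_id, False)))
        for r in reps.itertuples()
    }


def stage_integrate(cfg: RunConfig, out: Path) -> dict:
    profiles = _profiles_from_tsv(out / "profiles.tsv")
    matrix = geo.assemble_matrix(profiles, value="detection")
    ref_sources = _ref_sources(out, cfg)
    filtered = geo.filter_undetected_references(
        matrix, ref_sources, cfg.thresholds.detection_filter
    )
    dropped = sorted(set(matrix.columns) - set(filtered.columns))
    filtered.to_csv(out / "matrix.tsv", sep="\t")
    io.write_tsv(out / "dropped_refs.tsv", pd.DataFrame({"gene_id": dropped}))
    abundance = geo.assemble_matrix(profiles, value="q2q3_mean")[filtered.columns]
    io.write_tsv(out / "diversity.tsv", geo.shannon_and_richness(abundance))
    for axis, name in (("samples", "samples_dendrogram.nwk"), ("sequences", "sequences_dendrogram.nwk")):
        if filtered.shape[0 if axis == "samples" else 1] >= 1:
            (out / name).write_text(geo.hcluster(filtered, axis=axis).to_newick() + "\n")
    return {
        "n_samples": int(filtered.shape[0]),
        "n_refs_kept": int(filtered.shape[1]),
        "n_refs_dropped": len(dropped),
    }


def stage_recover(cfg: RunConfig, out: Path) -> dict:
    cl = pd.read_csv(out / "clusters.tsv", sep="\t")
    taxonomy = io.read_taxonomy(cfg.taxonomy) if cfg.taxonomy else {}
    clusters = []
    for cid, grp in cl.groupby("cluster_id", sort=True):
        members = tuple(grp["member_id"])
        rep = grp["representative_id"].iloc[0]
        flags = frozenset(grp["source_type"])
        taxon = rec.consensus_taxonomy([taxonomy.get(m) for m in members])
        clusters.append(
            clu.SequenceCluster(
                cluster_id=cid, representative_id=rep, member_ids=members,
                source_flags=flags, taxon=taxon,
            )
        )
    # tree-guided propagation for clusters the consensus left unassigned
    tree_path = out / "tree.nwk"
    propagated: dict[str, str] = {}
    if tree_path.exists() and any(c.taxon is None for c in clusters):
        tree = phylo.read_newick(tree_path)
        tips = {t.name for t in tree.tips()}
        assignments = {
            c.representative_id: c.taxon for c in clusters if c.representative_id in tips
        }
        if len(tips) >= 3:
            result = rec.propagate_taxonomy_from_tree(tree, assignments)
            rep_to_cluster = {c.representative_id: i for i, c in enumerate(clusters)}
            for name, (lineage, was_propagated) in result.items():
                if was_propagated and lineage is not None:
                    i = rep_to_cluster[name]
                    clusters[i] = clu.SequenceCluster(
                        cluster_id=clusters[i].cluster_id,
                        representative_id=clusters[i].representative_id,
                        member_ids=clusters[i].member_ids,
                        source_flags=clusters[i].source_flags,
                        taxon=lineage,
                    )
                    propagated[clusters[i].cluster_id] = lineage
    prof = pd.read_csv(out / "profiles.tsv", sep="\t")
    max_det = prof.groupby("ref_id")["detection"].max()
    detections = {
        c.cluster_id: float(max_det.get(c.representative_id, 0.0)) for c in clusters
    }
    report = rec.recovery_report(clusters, detections=detections)
    io.write_tsv(out / "recovery.tsv", report)
    assembly_only = sorted(c.cluster_id for c in clusters if clu.is_assembly_only(c))
    io.write_tsv(out / "assembly_only.tsv", pd.DataFrame({"cluster_id": assembly_only}))
    io.write_tsv(
        out / "propagated_taxa.tsv",
        pd.DataFrame(
            [{"cluster_id": k, "taxon": v, "propagated": 1} for k, v in sorted(propagated.items())],
            columns=["cluster_id", "taxon", "propagated"],
        ),
    )
    return {
        "n_clusters": len(clusters),
        "n_assembly_only": len(assembly_only),
        "n_propagated": len(propagated),
    }


# ---------------------------------------------------------------------------
# the stage graph


def _stage_table(cfg: RunConfig, out: Path):
    tax = [Path(cfg.taxonomy)] if cfg.taxonomy else []
    reads = sorted(Path(cfg.reads_dir).glob("*.fastq"))
    return [
        ("detect", [Path(cfg.hits), Path(cfg.genes_nt), Path(cfg.genes_aa), Path(cfg.roster)],
         [out / "hits.tsv"], stage_detect),
        ("cluster", [out / "hits.tsv", Path(cfg.roster)],
         [out / "clusters.tsv", out / "reps_nt.fasta", out / "reps_aa.fasta"], stage_cluster),
        ("recruit", [out / "reps_nt.fasta", *reads],
         [out / "profiles.tsv", out / "nonspecific.tsv"], stage_recruit),
        ("tree", [out / "reps_aa.fasta"],
         [out / "tree.nwk", out / "longbranch.tsv", out / "dropped_sequences.tsv"], stage_tree),
        ("integrate", [out / "profiles.tsv", out / "clusters.tsv", Path(cfg.roster)],
         [out / "matrix.tsv", out / "dropped_refs.tsv", out / "diversity.tsv"], stage_integrate),
        ("recover", [out / "clusters.tsv", out / "profiles.tsv", out / "tree.nwk", *tax],
         [out / "recovery.tsv", out / "assembly_only.tsv", out / "propagated_taxa.tsv"], stage_recover),
    ]


def _params_fingerprint(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, Path):
            d[k] = str(v)
    return d


def run_all(cfg: RunConfig, force: bool = False) -> dict:
    """Run every stage in order; returns (and writes) the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text()).get("stages", {})
        except json.JSONDecodeError:
            previous = {}
    params = _params_fingerprint(cfg)
    manifest: dict = {"params": params, "stages": {}}
    params_changed = previous and json.loads(manifest_path.read_text()).get("params") != params
    for name, inputs, outputs, fn in _stage_table(cfg, out):
        checksums = {str(p): io.md5_file(p) for p in inputs if p.exists()}
        prev = previous.get(name)
        fresh = (
            not force
            and not params_changed
            and prev is not None
            and prev.get("inputs") == checksums
            and all(p.exists() for p in outputs)
        )
        if fresh:
            log.info("[%s] outputs up to date, skipping", name)
            manifest["stages"][name] = {**prev, "status": "skipped"}
            continue
        log.info("[%s] running", name)
        try:
            counts = fn(cfg, out)
        except Exception as exc:
            manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
            raise StageError(name, exc) from exc
        # re-hash inputs that this stage's predecessors may have rewritten
        checksums = {str(p): io.md5_file(p) for p in inputs if p.exists()}
        manifest["stages"][name] = {
            "inputs": checksums,
            "outputs": [str(p) for p in outputs],
            "counts": counts,
            "status": "completed",
        }
        previous[name] = manifest["stages"][name]
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def report(run_dir: str | Path) -> str:
    """Deterministic plain-text summary of a completed run."""
    out = Path(run_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {run_dir}; run the workflow first")
    manifest = json.loads(manifest_path.read_text())
    lines = ["# markergeo run report", ""]
    lines.append("## stage counts")
    for name, entry in manifest.get("stages", {}).items():
        counts = ", ".join(f"{k}={v}" for k, v in sorted(entry.get("counts", {}).items()))
        lines.append(f"{name}: {entry['status']} ({counts})")
    recovery = pd.read_csv(out / "recovery.tsv", sep="\t")
    lines += ["", "## genome recovery rates (percent of clusters per taxon)"]
    lines.append(recovery.to_csv(sep="\t", index=False).rstrip())
    for title, fname, col in (
        ("assembly-only clusters", "assembly_only.tsv", "cluster_id"),
        ("reference genomes never detected", "dropped_refs.tsv", "gene_id"),
        ("long-branch tips flagged for review", "longbranch.tsv", "gene_id"),
    ):
        lines += ["", f"## {title}"]
        df = pd.read_csv(out / fname, sep="\t")
        values = list(df[col]) if col in df.columns and len(df) else []
        lines.append("\n".join(str(v) for v in values) if values else "(none)")
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
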