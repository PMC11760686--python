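"""Seeded synthetic communities with known marker phylogeny and recovery truth.

The simulator emulates the study design the pipeline is built for: a
single-copy marker gene (default 393 nt, the scale of a short ribosomal
protein) evolves along a Yule phylogeny under Jukes-Cantor substitutions
with a faster third codon position, taxa are assigned to habitats with
log-normal abundances, and each taxon is independently designated as
recovered by an isolate genome, a MAG, neither, or both.  Every taxon
present in a habitat sheds reads into that habitat's metagenomes whether
or not any genome represents it, which is exactly the gap the recovery
statistics measure.

All outputs are plain text (FASTA/FASTQ/TSV/domtblout/JSON) and every
random choice flows from a single integer seed, so the same seed always
produces byte-identical fixtures.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from io import StringIO
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio.Seq import Seq
from skbio.tree import TreeNode

from .cluster import cluster_greedy

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class SimParams:
    n_taxa: int = 24
    n_habitats: int = 2
    samples_per_habitat: int = 6
    marker_length: int = 393
    reads_per_sample: int = 20000
    read_length: int = 100
    error_rate: float = 0.005
    birth_rate: float = 1.0
    median_tip_distance: float = 0.15
    third_pos_rate: float = 3.0
    p_cosmopolitan: float = 0.1
    p_isolate: float = 0.4
    p_mag: float = 0.6
    p_assembly_dropout: float = 0.1
    lognorm_sigma: float = 1.0
    abundance_floor: float = 0.005
    cluster_identity: float = 0.97
    min_target_coverage: float = 0.8
    model_name: str = "RP_L19_syn"


@dataclass(frozen=True)
class TaxonTruth:
    nt_seq: str
    aa_seq: str
    lineage: str
    habitat: int  # -1 for cosmopolitan taxa
    abundances: tuple[float, ...]  # per habitat, each habitat sums to 1
    has_isolate: bool
    has_mag: bool
    in_assembly: bool


@dataclass(frozen=True)
class SimTruth:
    seed: int
    params: SimParams
    tree_newick: str
    taxa: dict[str, TaxonTruth]
    expected_clusters: tuple[tuple[str, ...], ...]
    expected_rates: dict[str, dict[str, float | int]]

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "params": asdict(self.params),
            "tree_newick": self.tree_newick,
            "taxa": {name: asdict(t) for name, t in self.taxa.items()},
            "expected_clusters": [list(c) for c in self.expected_clusters],
            "expected_rates": self.expected_rates,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            params=SimParams(**d["params"]),
            tree_newick=d["tree_newick"],
            taxa={
                name: TaxonTruth(**{**t, "abundances": tuple(t["abundances"])})
                for name, t in d["taxa"].items()
            },
            expected_clusters=tuple(tuple(c) for c in d["expected_clusters"]),
            expected_rates=d["expected_rates"],
        )


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    median_tip_distance: float = 0.15,
) -> TreeNode:
    """Yule (pure-birth) tree, rescaled to a target median tip-to-tip distance."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    a, b = TreeNode(length=0.0), TreeNode(length=0.0)
    root.append(a)
    root.append(b)
    active = [a, b]
    while len(active) < n_taxa:
        dt = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length += dt
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        c1, c2 = TreeNode(length=0.0), TreeNode(length=0.0)
        parent.append(c1)
        parent.append(c2)
        active.extend([c1, c2])
    dt = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length += dt
    for i, tip in enumerate(root.tips()):
        tip.name = f"T{i + 1:02d}"
    dm = root.tip_tip_distances()
    med = float(np.median(dm.condensed_form()))
    if med > 0:
        scale = median_tip_distance / med
        for node in root.traverse(include_self=False):
            if node.length is not None:
                node.length *= scale
    return root


def random_marker(length: int, rng: np.random.Generator) -> str:
    """Random stop-free coding sequence of the given length (multiple of 3)."""
    if length % 3:
        raise ValueError("marker length must be a multiple of 3")
    sense = sorted(
        a + b + c
        for a in _BASES
        for b in _BASES
        for c in _BASES
        if a + b + c not in _STOPS
    )
    codons = rng.integers(0, len(sense), size=length // 3)
    return "".join(sense[i] for i in codons)


def _mutate(seq: str, branch_length: float, rates: np.ndarray, rng: np.random.Generator) -> str:
    """Jukes-Cantor substitutions along one branch; stop codons are avoided."""
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * branch_length * rates))
    hit = np.nonzero(rng.random(len(seq)) < p)[0]
    if hit.size == 0:
        return seq
    chars = list(seq)
    for site in hit:
        old = chars[site]
        alts = [b for b in _BASES if b != old]
        pick = int(rng.integers(3))
        codon_start = (site // 3) * 3
        for off in range(3):
            cand = alts[(pick + off) % 3]
            chars[site] = cand
            codon = "".join(chars[codon_start : codon_start + 3])
            if codon not in _STOPS:
                break
        else:
            chars[site] = old  # every substitution would create a stop
    return "".join(chars)


def evolve_marker(
    tree: TreeNode,
    root_seq: str | None = None,
    length: int = 393,
    seed: int | np.random.SeedSequence = 0,
    third_pos_rate: float = 3.0,
) -> dict[str, str]:
    """Evolve a coding marker along the tree; returns per-tip nt sequences.

    Site rates follow codon structure: the first two positions mutate at
    a reduced rate and the third position ``third_pos_rate`` times faster,
    normalised to a mean rate of 1 — a crude mimic of purifying selection
    that keeps nucleotide identity between close sisters high while the
    protein changes slowly.
    """
    rng = np.random.default_rng(seed)
    if root_seq is None:
        root_seq = random_marker(length, rng)
    if len(root_seq) % 3:
        raise ValueError("root sequence length must be a multiple of 3")
    if set(root_seq) - set(_BASES):
        raise ValueError("root sequence must be plain ACGT")
    base = 3.0 / (2.0 + third_pos_rate)
    rates = np.tile([base, base, base * third_pos_rate], len(root_seq) // 3)
    out: dict[str, str] = {}

    def descend(node: TreeNode, seq: str) -> None:
        for child in node.children:
            child_seq = _mutate(seq, child.length or 0.0, rates, rng)
            if child.is_tip():
                out[child.name] = child_seq
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    return out


def design_community(
    taxa: list[str],
    n_habitats: int = 2,
    seed: int | np.random.SeedSequence = 0,
    p_cosmopolitan: float = 0.1,
    p_isolate: float = 0.4,
    p_mag: float = 0.6,
    p_assembly_dropout: float = 0.1,
    lognorm_sigma: float = 1.0,
    abundance_floor: float = 0.005,
) -> dict[str, dict]:
    """Assign habitats, abundances and recovery-method designations.

    Each taxon lives in one habitat (or is cosmopolitan), with log-normal
    relative abundances normalised per habitat.  A small abundance floor
    keeps every present taxon comfortably detectable at typical marker
    sequencing depth.  ``in_assembly`` is True unless the taxon is an
    assembly dropout, which models populations whose marker never
    assembles (e.g. high strain complexity).
    """
    if n_habitats < 1:
        raise ValueError("need at least one habitat")
    rng = np.random.default_rng(seed)
    design: dict[str, dict] = {}
    for i, taxon in enumerate(taxa):
        cosmopolitan = rng.random() < p_cosmopolitan
        habitat = -1 if cosmopolitan else int(rng.integers(n_habitats))
        # force one resident per habitat so no habitat is empty
        if i < n_habitats:
            cosmopolitan, habitat = False, i
        design[taxon] = {
            "habitat": habitat,
            "has_isolate": bool(rng.random() < p_isolate),
            "has_mag": bool(rng.random() < p_mag),
            "in_assembly": not (rng.random() < p_assembly_dropout),
            "raw": rng.lognormal(mean=0.0, sigma=lognorm_sigma, size=n_habitats),
        }
    for taxon in taxa:
        d = design[taxon]
        present = np.zeros(n_habitats)
        for h in range(n_habitats):
            if d["habitat"] in (-1, h):
                present[h] = d["raw"][h]
        d["present"] = present
    for h in range(n_habitats):
        col = np.array([design[t]["present"][h] for t in taxa])
        total = col.sum()
        if total <= 0:
            raise RuntimeError("habitat with no resident taxa")
        col = col / total
        nz = col > 0
        col[nz] = col[nz] + abundance_floor
        col = col / col.sum()
        for t, v in zip(taxa, col):
            design[t]["present"][h] = v
    for t in taxa:
        d = design[t]
        d["abundances"] = tuple(float(v) for v in d.pop("present"))
        d.pop("raw")
    return design


def _lineages(taxa: list[str]) -> dict[str, str]:
    """Synthetic lineages with real rank structure; adjacent tips share genera."""
    out = {}
    for i, t in enumerate(taxa):
        out[t] = (
            f"d__Bacteria;p__P{i // 8 + 1:02d};c__C{i // 8 + 1:02d};"
            f"o__O{i // 4 + 1:02d};f__F{i // 4 + 1:02d};g__G{i // 2 + 1:02d}"
        )
    return out


def _consensus_recount(lineages: list[str]) -> str:
    """Independent per-rank majority recount used only for truth bookkeeping."""
    split = [l.split(";") for l in lineages]
    n = len(split)
    kept = []
    for rank in range(max(len(s) for s in split)):
        tally: dict[str, int] = {}
        for s in split:
            if rank < len(s):
                tally[s[rank]] = tally.get(s[rank], 0) + 1
        winners = [lab for lab in sorted(tally) if tally[lab] * 2 > n]
        if not winners:
            break
        kept.append(winners[0])
    return ";".join(kept) if kept else "Unassigned"


def build_truth(seed: int = 42, params: SimParams | None = None) -> SimTruth:
    """Simulate the community and precompute the ground-truth answers."""
    params = params or SimParams()
    ss = np.random.SeedSequence(seed)
    s_tree, s_evolve, s_design = ss.spawn(3)
    tree = simulate_tree(
        params.n_taxa, params.birth_rate, s_tree, params.median_tip_distance
    )
    nt = evolve_marker(
        tree, length=params.marker_length, seed=s_evolve, third_pos_rate=params.third_pos_rate
    )
    taxa_names = sorted(nt)
    design = design_community(
        taxa_names,
        params.n_habitats,
        s_design,
        params.p_cosmopolitan,
        params.p_isolate,
        params.p_mag,
        params.p_assembly_dropout,
        params.lognorm_sigma,
        params.abundance_floor,
    )
    lineages = _lineages(taxa_names)
    taxa: dict[str, TaxonTruth] = {}
    for t in taxa_names:
        d = design[t]
        taxa[t] = TaxonTruth(
            nt_seq=nt[t],
            aa_seq=str(Seq(nt[t]).translate()),
            lineage=lineages[t],
            habitat=d["habitat"],
            abundances=d["abundances"],
            has_isolate=d["has_isolate"],
            has_mag=d["has_mag"],
            in_assembly=d["in_assembly"],
        )
    gene_seqs, gene_sources, _ = truth_gene_table(taxa)
    clusters = cluster_greedy(
        gene_seqs,
        identity=params.cluster_identity,
        min_target_coverage=params.min_target_coverage,
    )
    expected_clusters = tuple(tuple(sorted(c.member_ids)) for c in clusters)
    expected_rates = _expected_rates(expected_clusters, gene_sources, taxa)
    buf = StringIO()
    tree.write(buf, format="newick")
    return SimTruth(
        seed=seed,
        params=params,
        tree_newick=buf.getvalue().strip(),
        taxa=taxa,
        expected_clusters=expected_clusters,
        expected_rates=expected_rates,
    )


def truth_gene_table(
    taxa: Mapping[str, TaxonTruth],
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Emitted marker genes: (gene -> nt seq, gene -> source id, source -> type)."""
    gene_seqs: dict[str, str] = {}
    gene_sources: dict[str, str] = {}
    roster: dict[str, str] = {}
    for t in sorted(taxa):
        tt = taxa[t]
        emit = []
        if tt.has_isolate:
            emit.append((f"{t}_iso", f"ISO_{t}", "isolate"))
        if tt.has_mag:
            emit.append((f"{t}_mag", f"MAG_{t}", "MAG"))
        if tt.in_assembly:
            emit.append((f"{t}_asm", f"ASM_{t}", "metagenome_assembly"))
        for gid, src, stype in emit:
            gene_seqs[gid] = tt.nt_seq
            gene_sources[gid] = src
            roster[src] = stype
    return gene_seqs, gene_sources, roster


_RATE_COMBOS = {
    "rate_MAG": {"MAG"},
    "rate_isolate": {"isolate"},
    "rate_MAG_isolate": {"MAG", "isolate"},
    "rate_any_genome": {"MAG", "isolate", "SAG"},
}


def _expected_rates(
    expected_clusters: tuple[tuple[str, ...], ...],
    gene_sources: Mapping[str, str],
    taxa: Mapping[str, TaxonTruth],
) -> dict[str, dict[str, float | int]]:
    """Recount recovery rates directly from designations and the partition."""
    src_type = {}
    for gid, src in gene_sources.items():
        src_type[gid] = {"ISO": "isolate", "MAG": "MAG", "ASM": "metagenome_assembly"}[src[:3]]
    per_cluster = []
    for members in expected_clusters:
        flags = {src_type[g] for g in members}
        lineage = _consensus_recount([taxa[g.rsplit("_", 1)[0]].lineage for g in members])
        per_cluster.append((lineage, flags))
    rates: dict[str, dict[str, float | int]] = {}
    groups = sorted({lin for lin, _ in per_cluster})
    for label in groups + ["ALL"]:
        sub = [f for lin, f in per_cluster if label == "ALL" or lin == label]
        entry: dict[str, float | int] = {
            "n_clusters": len(sub),
            "n_MAG": sum(1 for f in sub if "MAG" in f),
            "n_isolate": sum(1 for f in sub if "isolate" in f),
            "n_SAG": sum(1 for f in sub if "SAG" in f),
            "n_assembly_only": sum(1 for f in sub if f == {"metagenome_assembly"}),
        }
        for col, srcs in _RATE_COMBOS.items():
            entry[col] = round(100.0 * sum(1 for f in sub if f & srcs) / len(sub), 1)
        rates[label] = entry
    return rates


# ---------------------------------------------------------------------------
# fixture emission


def _fasta(path: Path, seqs: Mapping[str, str], attrs: Mapping[str, Mapping] | None = None) -> None:
    with open(path, "w") as fh:
        for sid in seqs:
            desc = ""
            if attrs and sid in attrs:
                desc = " " + " ".join(f"{k}={v}" for k, v in attrs[sid].items())
            fh.write(f">{sid}{desc}\n")
            s = seqs[sid]
            for i in range(0, len(s), 80):
                fh.write(s[i : i + 80] + "\n")


def _domtblout_line(
    gene_id: str,
    gene_len_aa: int,
    model: str,
    model_len: int,
    hmm_from: int,
    hmm_to: int,
    ali_from: int,
    ali_to: int,
) -> str:
    cols = [
        gene_id, "-", str(gene_len_aa), model, "-", str(model_len),
        "1e-50", "200.0", "0.1", "1", "1", "1e-52", "1e-50", "198.0", "0.1",
        str(hmm_from), str(hmm_to), str(ali_from), str(ali_to),
        str(max(1, ali_from - 1)), str(min(gene_len_aa, ali_to + 1)), "0.98",
        "synthetic marker gene",
    ]
    return " ".join(cols)


def emit_fixtures(truth: SimTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the full fixture set for one simulated community.

    Produces genomes.fasta, roster.tsv, genes_nt.fasta / genes_aa.fasta
    (headers carry ``source=`` and ``complete=`` tokens), hits.domtblout
    with planted low-coverage and partial-ORF decoys, per-sample FASTQ
    reads, taxonomy.tsv, and truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    p = truth.params
    ss = np.random.SeedSequence(truth.seed)
    _, _, _, s_flanks, s_reads = ss.spawn(5)
    rng_fl = np.random.default_rng(s_flanks)

    gene_seqs, gene_sources, roster = truth_gene_table(truth.taxa)
    aa = {g: truth.taxa[g.rsplit("_", 1)[0]].aa_seq for g in gene_seqs}

    # decoys exercise the hit filters: one low-model-coverage hit, one partial ORF
    first = sorted(truth.taxa)[0]
    decoy_lowcov = "DECOY_lowcov_asm"
    decoy_partial = "DECOY_partial_asm"
    trunc = truth.taxa[first].nt_seq[: (p.marker_length // 5) * 3]
    all_nt = dict(gene_seqs)
    all_nt[decoy_lowcov] = truth.taxa[first].nt_seq
    all_nt[decoy_partial] = trunc
    all_aa = dict(aa)
    all_aa[decoy_lowcov] = truth.taxa[first].aa_seq
    all_aa[decoy_partial] = str(Seq(trunc).translate())
    attrs = {g: {"source": gene_sources[g], "complete": 1} for g in gene_seqs}
    attrs[decoy_lowcov] = {"source": "ASM_DECOY", "complete": 1}
    attrs[decoy_partial] = {"source": "ASM_DECOY", "complete": 0}
    roster = dict(roster)
    roster["ASM_DECOY"] = "metagenome_assembly"

    paths = {
        "genes_nt": out / "genes_nt.fasta",
        "genes_aa": out / "genes_aa.fasta",
        "hits": out / "hits.domtblout",
        "roster": out / "roster.tsv",
        "genomes": out / "genomes.fasta",
        "taxonomy": out / "taxonomy.tsv",
        "truth": out / "truth.json",
        "reads_dir": reads_dir,
    }
    _fasta(paths["genes_nt"], all_nt, attrs)
    _fasta(paths["genes_aa"], all_aa, attrs)

    model_len = p.marker_length // 3
    with open(paths["hits"], "w") as fh:
        fh.write("# synthetic domtblout (hmmsearch dialect)\n")
        for g in all_nt:
            aa_len = len(all_aa[g])
            if g == decoy_lowcov:
                hmm_to = max(1, int(round(0.6 * model_len)))
                fh.write(_domtblout_line(g, aa_len, p.model_name, model_len, 1, hmm_to, 1, hmm_to) + "\n")
            else:
                fh.write(_domtblout_line(g, aa_len, p.model_name, model_len, 1, model_len, 1, aa_len) + "\n")

    with open(paths["roster"], "w") as fh:
        fh.write("source_id\tsource_type\tfrom_profiled_samples\n")
        for src in sorted(roster):
            from_samples = roster[src] in ("MAG", "metagenome_assembly")
            fh.write(f"{src}\t{roster[src]}\t{int(from_samples)}\n")

    genomes = {}
    for g, src in sorted(gene_sources.items()):
        flank_a = "".join(_BASES[i] for i in rng_fl.integers(0, 4, size=300))
        flank_b = "".join(_BASES[i] for i in rng_fl.integers(0, 4, size=300))
        genomes[src] = flank_a + all_nt[g] + flank_b
    _fasta(paths["genomes"], genomes)

    with open(paths["taxonomy"], "w") as fh:
        fh.write("gene_id\tlineage\n")
        for g in gene_seqs:
            taxon = g.rsplit("_", 1)[0]
            fh.write(f"{g}\t{truth.taxa[taxon].lineage}\n")

    _emit_reads(truth, reads_dir, s_reads)

    paths["truth"].write_text(truth.to_json())
    return paths


def _emit_reads(truth: SimTruth, reads_dir: Path, seed: np.random.SeedSequence) -> None:
    p = truth.params
    taxa_names = sorted(truth.taxa)
    markers = {
        t: np.frombuffer(truth.taxa[t].nt_seq.encode(), dtype=np.uint8) for t in taxa_names
    }
    base_idx = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        base_idx[ord(b)] = i
    base_ord = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    comp = np.array([3, 2, 1, 0])
    sample_seeds = seed.spawn(p.n_habitats * p.samples_per_habitat)
    si = 0
    for h in range(p.n_habitats):
        probs = np.array([truth.taxa[t].abundances[h] for t in taxa_names])
        for rep in range(p.samples_per_habitat):
            rng = np.random.default_rng(sample_seeds[si])
            si += 1
            sample = f"H{h + 1}_s{rep + 1:02d}"
            counts = rng.multinomial(p.reads_per_sample, probs)
            chunks: list[str] = []
            for t, count in zip(taxa_names, counts):
                if count == 0:
                    continue
                m = base_idx[markers[t]].astype(np.int64)
                L = len(m)
                rl = min(p.read_length, L)
                starts = rng.integers(0, L - rl + 1, size=count)
                mat = m[starts[:, None] + np.arange(rl)[None, :]]
                err = rng.random((count, rl)) < p.error_rate
                shift = rng.integers(1, 4, size=(count, rl))
                mat = np.where(err, (mat + shift) % 4, mat)
                rev = rng.random(count) < 0.5
                mat[rev] = comp[mat[rev]][:, ::-1]
                qual = "I" * rl
                seq_bytes = base_ord[mat]
                for i in range(count):
                    chunks.append(
                        f"@{t}_{sample}_r{i}\n{seq_bytes[i].tobytes().decode()}\n+\n{qual}\n"
                    )
            (reads_dir / f"{sample}.fastq").write_text("".join(chunks))


def simulate_fixture_set(
    out_dir: str | Path,
    seed: int = 42,
    params: SimParams | None = None,
) -> tuple[SimTruth, dict[str, Path]]:
    """Convenience wrapper: build the truth and emit all fixture files."""
    truth = build_truth(seed=seed, params=params)
    return truth, emit_fixtures(truth, out_dir)
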