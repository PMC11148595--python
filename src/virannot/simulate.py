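"""Synthetic fixtures and the end-to-end evaluation harness.

Everything the pipeline needs can be generated on the fly, seeded and
bit-reproducible: a toy dual-kingdom taxonomy in taxdump dialect, random
viral/bacterial genomes, error-bearing reads with per-read ground truth,
and the four toy search databases of the tiered classifier (viral aa,
multikingdom aa, viral nt, polymicrobial nt). A mock mixed virus-bacteria
community run through cluster -> align -> classify -> bigtable yields
sensitivity and false-positive-rate estimates against the ground truth,
mirroring (at desk scale) the in-silico benchmark design such pipelines
are validated with.

The default error model is substitutions only; that keeps read-to-source
identity analytically simple. Real sequencing error additionally has
indels and quality structure, so passing here shows bookkeeping and
routing correctness, not production recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from virannot.errors import IntegrityError
from virannot.taxonomy import (
    RANKS7,
    SENTINEL,
    SENTINEL_TAXID,
    TaxonomyTree,
    lineage7,
    load_taxdump,
)

_BASES = np.array(list("ACGT"))


# -- synthetic taxonomy ------------------------------------------------------

@dataclass
class SynthTaxonomy:
    nodes_path: Path
    names_path: Path
    tree: TaxonomyTree
    viral_species: list[int]  # one species taxid per viral family
    bacterial_species: list[int]  # one per bacterial genus
    viral_families: list[str]


def synth_taxonomy(
    n_viral_families: int,
    n_bacterial_genera: int,
    seed: int = 0,
    out_dir=None,
) -> SynthTaxonomy:
    """Emit a loadable toy taxdump: root(1), Viruses(10239), Bacteria(2).

    Each viral family gets its own full 7-rank path directly under the
    virus root (so two families only meet at taxid 10239, exercising the
    cross-realm augmentation case); each bacterial genus gets a full path
    under Bacteria. Output is byte-deterministic for given arguments.
    """
    if n_viral_families < 1 or n_bacterial_genera < 1:
        raise ValueError("need at least one viral family and one bacterial genus")
    del seed  # generation is fully deterministic; accepted for API symmetry
    nodes: list[tuple[int, int, str]] = [
        (1, 1, "no rank"),
        (10239, 1, "superkingdom"),
        (2, 1, "superkingdom"),
    ]
    names: dict[int, str] = {1: "root", 10239: "Viruses", 2: "Bacteria"}
    viral_species: list[int] = []
    viral_families: list[str] = []
    bacterial_species: list[int] = []
    ranks = ("phylum", "class", "order", "family", "genus", "species")
    next_id = 100
    for i in range(1, n_viral_families + 1):
        parent = 10239
        for rank in ranks:
            names[next_id] = f"v{i}_{rank.capitalize()}" if rank != "family" \
                else f"Toyviridae{i}"
            nodes.append((next_id, parent, rank))
            if rank == "family":
                viral_families.append(names[next_id])
            if rank == "species":
                viral_species.append(next_id)
            parent = next_id
            next_id += 1
    for i in range(1, n_bacterial_genera + 1):
        parent = 2
        for rank in ranks:
            names[next_id] = f"b{i}_{rank.capitalize()}" if rank != "family" \
                else f"Toybacteraceae{i}"
            nodes.append((next_id, parent, rank))
            if rank == "species":
                bacterial_species.append(next_id)
            parent = next_id
            next_id += 1

    out_dir = Path(out_dir) if out_dir is not None else Path(".")
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes_path = out_dir / "nodes.dmp"
    names_path = out_dir / "names.dmp"
    with open(nodes_path, "w") as fh:
        for taxid, parent, rank in nodes:
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w") as fh:
        for taxid in sorted(names):
            fh.write(f"{taxid}\t|\t{names[taxid]}\t|\t\t|\tscientific name\t|\n")
    tree = load_taxdump(nodes_path, names_path)
    return SynthTaxonomy(nodes_path, names_path, tree,
                         viral_species, bacterial_species, viral_families)


# -- mock community ----------------------------------------------------------

@dataclass
class MockCommunitySpec:
    """Design of a simulated mixed virus-bacteria community.

    ``viral_genomes``: (label, length, taxid, genome_type);
    ``bacterial_genomes``: (label, length, taxid). Reads are sampled
    uniformly from both strands with i.i.d. substitutions at
    ``substitution_rate`` (optional ``indel_rate``, default 0); seeded
    generation is bit-reproducible and every read carries a truth label.
    """

    viral_genomes: list[tuple[str, int, int, str]]
    bacterial_genomes: list[tuple[str, int, int]]
    reads_per_genome: int = 200
    read_length: int = 150
    substitution_rate: float = 0.01
    indel_rate: float = 0.0
    seed: int = 42
    samples: tuple[str, ...] = ("S1",)


@dataclass
class Community:
    genomes: list[tuple[str, str]]  # (genome_id, sequence)
    genome_taxids: dict[str, int]
    viral_ids: list[str]
    bacterial_ids: list[str]
    reads: dict[str, list[tuple[str, str]]]  # sample -> [(read_id, seq)]
    truth: dict[str, int]  # read_id -> source taxid

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.truth.items()), columns=["read_id", "taxid"]
        )


_COMP = str.maketrans("ACGT", "TGCA")


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float) -> str:
    arr = np.array(list(seq))
    if sub_rate > 0:
        hits = rng.random(len(arr)) < sub_rate
        for i in np.flatnonzero(hits):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    seq = "".join(arr)
    if indel_rate > 0:
        out = []
        for ch in seq:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(ch)
            if r > 1 - indel_rate / 2:
                out.append("ACGT"[rng.integers(0, 4)])  # insertion
        seq = "".join(out)
    return seq


def synth_community(spec: MockCommunitySpec) -> Community:
    """Generate genomes, per-sample reads and ground truth from a spec."""
    rng = np.random.default_rng(spec.seed)
    genomes: list[tuple[str, str]] = []
    genome_taxids: dict[str, int] = {}
    viral_ids, bacterial_ids = [], []
    for label, length, taxid, _gtype in spec.viral_genomes:
        if spec.read_length > length:
            raise ValueError(f"read_length exceeds genome length for {label!r}")
        genomes.append((label, _random_genome(rng, length)))
        genome_taxids[label] = taxid
        viral_ids.append(label)
    for label, length, taxid in spec.bacterial_genomes:
        if spec.read_length > length:
            raise ValueError(f"read_length exceeds genome length for {label!r}")
        genomes.append((label, _random_genome(rng, length)))
        genome_taxids[label] = taxid
        bacterial_ids.append(label)

    gdict = dict(genomes)
    reads: dict[str, list[tuple[str, str]]] = {s: [] for s in spec.samples}
    truth: dict[str, int] = {}
    for sample in spec.samples:
        counter = 0
        for gid in viral_ids + bacterial_ids:
            gseq = gdict[gid]
            for _ in range(spec.reads_per_genome):
                pos = int(rng.integers(0, len(gseq) - spec.read_length + 1))
                fragment = gseq[pos:pos + spec.read_length]
                if rng.random() < 0.5:
                    fragment = fragment.translate(_COMP)[::-1]
                read = _mutate(rng, fragment, spec.substitution_rate,
                               spec.indel_rate)
                rid = f"{sample}_r{counter:05d}"
                counter += 1
                reads[sample].append((rid, read))
                truth[rid] = genome_taxids[gid]
    return Community(genomes, genome_taxids, viral_ids, bacterial_ids,
                     reads, truth)


# -- toy search databases ----------------------------------------------------

@dataclass
class ToyDatabases:
    """The four reference collections of the tiered design, toy scale."""

    viral_aa: list[tuple[str, str]]
    mk_aa: list[tuple[str, str]]
    viral_nt: list[tuple[str, str]]
    poly_nt: list[tuple[str, str]]
    taxid_map: dict[str, int]


def build_toy_databases(community: Community) -> ToyDatabases:
    """Derive toy databases from the community's genomes.

    Protein entries are the frame-1 translation of each genome (stop
    codons retained), so any read's in-phase 6-frame translation is a
    near-exact substring of its source protein.
    """
    def protein(gid: str, seq: str) -> tuple[str, str]:
        trimmed = seq[: len(seq) - len(seq) % 3]
        return (f"prot_{gid}", str(Seq(trimmed).translate()))

    gdict = dict(community.genomes)
    viral_prot = [protein(g, gdict[g]) for g in community.viral_ids]
    bact_prot = [protein(g, gdict[g]) for g in community.bacterial_ids]
    viral_nt = [(g, gdict[g]) for g in community.viral_ids]
    poly_nt = [(g, gdict[g]) for g in community.viral_ids + community.bacterial_ids]
    taxid_map = dict(community.genome_taxids)
    for pid, _ in viral_prot + bact_prot:
        taxid_map[pid] = community.genome_taxids[pid[len("prot_"):]]
    return ToyDatabases(viral_aa=viral_prot, mk_aa=viral_prot + bact_prot,
                        viral_nt=viral_nt, poly_nt=poly_nt, taxid_map=taxid_map)


# -- evaluation --------------------------------------------------------------

@dataclass
class EvalReport:
    """Sensitivity / false-positive-rate report against ground truth."""

    per_genome: pd.DataFrame  # taxid, true_positive, false_positive, false_negative
    true_positive: int
    false_positive: int
    false_negative: int
    n_viral_reads: int
    n_negative_reads: int

    @property
    def sensitivity(self) -> float:
        denom = self.true_positive + self.false_negative
        return self.true_positive / denom if denom else float("nan")

    @property
    def false_positive_rate(self) -> float:
        # no negatives -> no false positive is possible -> rate 0
        return (self.false_positive / self.n_negative_reads
                if self.n_negative_reads else 0.0)

    def to_frame(self) -> pd.DataFrame:
        return self.per_genome


def _rank_value(tree: TaxonomyTree, taxid: int, rank: str) -> str | int:
    if rank == "taxid":
        return taxid
    lin = lineage7(tree, taxid)
    return getattr(lin, "class_" if rank == "class" else rank)


def evaluate(
    annotations,
    truth: Mapping[str, int] | pd.DataFrame,
    tree: TaxonomyTree,
    rank: str = "family",
    clusters: Sequence | None = None,
) -> EvalReport:
    """Score read annotations against ground truth at a taxonomic rank.

    ``annotations`` is a bigtable DataFrame (or tier-annotation list);
    assignments are keyed by seq_id/query_id. When ``clusters`` (the
    SeqClusters behind the representatives) is given, each
    representative's verdict is propagated to its member reads; otherwise
    annotation keys are taken to be read ids directly.

    A read from a viral genome is a true positive iff it is annotated
    viral and its assigned lineage matches the truth lineage at ``rank``;
    a non-viral read annotated viral is a false positive.
    """
    if rank not in (*RANKS7, "taxid"):
        raise ValueError(f"rank must be one of {RANKS7 + ('taxid',)}, got {rank!r}")
    if isinstance(truth, pd.DataFrame):
        truth = dict(zip(truth["read_id"].astype(str), truth["taxid"].astype(int)))

    # (verdict, taxid) per annotation key
    if isinstance(annotations, pd.DataFrame):
        calls = {str(r.seq_id): (r.verdict, int(r.taxid))
                 for r in annotations.itertuples(index=False)}
    else:
        calls = {a.query_id: (a.verdict, a.taxid) for a in annotations}

    # expand to per-read calls
    if clusters is not None:
        read_calls: dict[str, tuple[str, int]] = {}
        for c in clusters:
            call = calls.get(c.seq_id, ("unclassified", SENTINEL_TAXID))
            for rid in c.member_ids:
                read_calls[rid] = call
    else:
        read_calls = calls

    missing = sorted(set(read_calls) - set(truth))
    if missing:
        raise IntegrityError(f"reads missing from truth: {missing[:5]}")

    counters: dict[int, dict[str, int]] = {}
    tp = fp = fn = n_viral = n_neg = 0
    for rid, true_taxid in truth.items():
        verdict, assigned = read_calls.get(rid, ("unclassified", SENTINEL_TAXID))
        is_viral_truth = tree.is_viral(true_taxid)
        bucket = counters.setdefault(
            true_taxid, {"true_positive": 0, "false_positive": 0,
                         "false_negative": 0})
        if is_viral_truth:
            n_viral += 1
            correct = False
            if verdict == "viral" and assigned != SENTINEL_TAXID and assigned in tree:
                correct = (_rank_value(tree, assigned, rank)
                           == _rank_value(tree, true_taxid, rank))
                if rank != "taxid" and _rank_value(tree, true_taxid, rank) == SENTINEL:
                    correct = False
            if correct:
                tp += 1
                bucket["true_positive"] += 1
            else:
                fn += 1
                bucket["false_negative"] += 1
        else:
            n_neg += 1
            if verdict == "viral":
                fp += 1
                bucket["false_positive"] += 1

    per_genome = pd.DataFrame(
        [{"taxid": t, **c} for t, c in sorted(counters.items())]
    )
    return EvalReport(per_genome=per_genome, true_positive=tp,
                      false_positive=fp, false_negative=fn,
                      n_viral_reads=n_viral, n_negative_reads=n_neg)


# -- end-to-end pipeline on a mock community ---------------------------------

@dataclass
class PipelineResult:
    taxonomy: SynthTaxonomy
    community: Community
    clusters: list
    sample_totals: dict[str, int]
    annotations: list
    bigtable: pd.DataFrame
    report: EvalReport


def default_mock_spec(
    tax: SynthTaxonomy,
    n_viral: int = 4,
    n_bacterial: int = 2,
    reads_per_genome: int = 200,
    read_length: int = 150,
    substitution_rate: float = 0.01,
    seed: int = 42,
    viral_length: int = 4000,
    bacterial_length: int = 8000,
) -> MockCommunitySpec:
    """The standard desk-scale benchmark: 4 viral + 2 bacterial genomes."""
    genome_types = ["dsDNA", "ssDNA", "dsRNA", "ssRNA"]
    viral = [(f"virus{i+1}", viral_length, tax.viral_species[i],
              genome_types[i % len(genome_types)]) for i in range(n_viral)]
    bact = [(f"bact{i+1}", bacterial_length, tax.bacterial_species[i])
            for i in range(n_bacterial)]
    return MockCommunitySpec(viral_genomes=viral, bacterial_genomes=bact,
                             reads_per_genome=reads_per_genome,
                             read_length=read_length,
                             substitution_rate=substitution_rate, seed=seed)


def run_pipeline(
    workdir,
    seed: int = 42,
    spec: MockCommunitySpec | None = None,
    tax: SynthTaxonomy | None = None,
    eval_rank: str = "family",
) -> PipelineResult:
    """Simulate, cluster, align, classify, assemble and evaluate.

    The full chain on a mock community: synthetic taxonomy + genomes ->
    per-sample greedy dereplication -> naive alignment against the four
    toy databases -> tiered classification -> bigtable -> truth scoring.
    """
    from virannot.align import naive_align
    from virannot.bigtable import build_bigtable
    from virannot.classify import tiered_classify
    from virannot.seqtable import greedy_cluster
    from virannot.taxonomy import load_baltimore

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if tax is None:
        tax = synth_taxonomy(4, 2, seed=seed, out_dir=workdir / "taxonomy")
    if spec is None:
        spec = default_mock_spec(tax, seed=seed)
    community = synth_community(spec)
    dbs = build_toy_databases(community)

    clusters = []
    sample_totals = {}
    for sample, reads in community.reads.items():
        sample_totals[sample] = len(reads)
        clusters.extend(greedy_cluster(reads, sample_id=sample))

    reps = [(c.seq_id, c.representative_seq) for c in clusters]
    viral_aa = naive_align(reps, dbs.viral_aa, dbs.taxid_map, mode="aa-6frame")
    mk_aa = naive_align(reps, dbs.mk_aa, dbs.taxid_map, mode="aa-6frame")
    viral_nt = naive_align(reps, dbs.viral_nt, dbs.taxid_map, mode="nt")
    poly_nt = naive_align(reps, dbs.poly_nt, dbs.taxid_map, mode="nt")

    annotations = tiered_classify(
        [c.seq_id for c in clusters], viral_aa, mk_aa, viral_nt, poly_nt,
        tax.tree,
    )
    bigtable = build_bigtable(clusters, annotations, tax.tree,
                              load_baltimore(), sample_totals)
    report = evaluate(bigtable, community.truth, tax.tree, rank=eval_rank,
                      clusters=clusters)
    return PipelineResult(taxonomy=tax, community=community, clusters=clusters,
                          sample_totals=sample_totals, annotations=annotations,
                          bigtable=bigtable, report=report)
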