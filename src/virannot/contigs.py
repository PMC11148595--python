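"""Contig-level annotation products.

Per-sample contig abundances from read mappings with three library-size
normalizations, contig properties (length, GC, coverage), unmapped-read
pooling for the merged-assembly flow, the contig-to-read-annotation join
(contigSeqTable), and LCA-based contig taxonomy.

Normalization definitions, for contig i with length l_i, per-sample
mapped-read count r_i, sample mapped totals R (reads) and F (fragments):

* RPKM_i = r_i * 1e9 / (R * l_i)
* FPKM_i = f_i * 1e9 / (F * l_i), a fragment being a read pair counted
  once when both mates map to the same contig, else each mate counts
* SPM_i  = 1e6 * (r_i / l_i) / sum_j (r_j / l_j)  (TPM-style rate share;
  sums to 1e6 per sample whenever any read maps)

Counting is deterministic: primary alignments only, one row per read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from virannot.classify import ClassifyConfig, TierAnnotation
from virannot.errors import IntegrityError
from virannot.hits import AlignmentHit, lca_hit_set, rank_hits
from virannot.taxonomy import (
    SENTINEL,
    SENTINEL_TAXID,
    RANKS7,
    TaxonomyTree,
    augmented_lca,
    lineage7,
)

_MATE_SUFFIX = re.compile(r"(/[12]|_R[12])$")


@dataclass(frozen=True)
class ReadMapping:
    """One read's (primary) mapping outcome against the contig collection."""

    read_id: str
    sample_id: str
    contig_id: str | None = None
    start: int | None = None  # 0-based half-open contig coordinates
    end: int | None = None
    mapq: int | None = None
    is_mapped: bool = False

    def __post_init__(self):
        if not self.is_mapped and self.contig_id is not None:
            raise ValueError("unmapped reads carry no contig coordinates")

    @property
    def fragment_id(self) -> str:
        """Mate-pair key: read_id with a trailing /1, /2, _R1 or _R2 stripped."""
        return _MATE_SUFFIX.sub("", self.read_id)


def pool_unmapped(mappings: Sequence[ReadMapping]) -> dict[str, list[str]]:
    """Unmapped reads pooled across samples, provenance retained.

    Input must contain one row per read (mapped or unmapped); a read
    appearing both mapped and unmapped is a data-integrity error.
    """
    status: dict[tuple[str, str], bool] = {}
    for m in mappings:
        key = (m.sample_id, m.read_id)
        if key in status and status[key] != m.is_mapped:
            raise IntegrityError(
                f"read {m.read_id!r} ({m.sample_id}) appears both mapped and unmapped"
            )
        status[key] = m.is_mapped
    pool: dict[str, list[str]] = {}
    for (sample, read), mapped in status.items():
        if not mapped:
            pool.setdefault(sample, []).append(read)
    for sample in pool:
        pool[sample].sort()
    return pool


def _gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def _covered_bases(spans: list[tuple[int, int]]) -> int:
    spans.sort()
    covered = 0
    cur_start = cur_end = None
    for s, e in spans:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered


def contig_abundance(
    mappings: Sequence[ReadMapping],
    contigs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Per-(contig, sample) abundance and property table.

    Columns: contig_id, sample_id, length, gc_fraction, raw_count, rpkm,
    fpkm, spm, coverage_percent. Only contig/sample pairs with at least
    one mapped read get a row; unmapped rows in ``mappings`` contribute
    nothing here (see :func:`pool_unmapped`).
    """
    contig_seqs = dict(contigs)
    mapped = [m for m in mappings if m.is_mapped]
    for m in mapped:
        if m.contig_id not in contig_seqs:
            raise IntegrityError(f"mapping to unknown contig {m.contig_id!r}")

    rows = []
    samples = sorted({m.sample_id for m in mapped})
    for sample in samples:
        mine = [m for m in mapped if m.sample_id == sample]
        by_contig: dict[str, list[ReadMapping]] = {}
        for m in mine:
            by_contig.setdefault(m.contig_id, []).append(m)
        read_total = len(mine)
        fragment_total = 0
        frag_counts: dict[str, int] = {}
        for cid, ms in by_contig.items():
            nfrag = len({m.fragment_id for m in ms})
            frag_counts[cid] = nfrag
            fragment_total += nfrag
        rate_sum = sum(
            len(ms) / len(contig_seqs[cid]) for cid, ms in by_contig.items()
        )
        for cid in sorted(by_contig):
            ms = by_contig[cid]
            length = len(contig_seqs[cid])
            r_i = len(ms)
            spans = [(m.start, m.end) for m in ms
                     if m.start is not None and m.end is not None]
            covered = _covered_bases(spans)
            rows.append({
                "contig_id": cid,
                "sample_id": sample,
                "length": length,
                "gc_fraction": round(_gc_fraction(contig_seqs[cid]), 4),
                "raw_count": r_i,
                "rpkm": r_i * 1e9 / (read_total * length),
                "fpkm": frag_counts[cid] * 1e9 / (fragment_total * length),
                "spm": 1e6 * (r_i / length) / rate_sum,
                "coverage_percent": 100.0 * covered / length,
            })
    return pd.DataFrame(rows, columns=[
        "contig_id", "sample_id", "length", "gc_fraction", "raw_count",
        "rpkm", "fpkm", "spm", "coverage_percent",
    ])


def contig_seq_table(
    mappings: Sequence[ReadMapping],
    bigtable_rows: pd.DataFrame,
) -> pd.DataFrame:
    """Join read-based taxonomy onto contig mappings (contigSeqTable).

    One row per mapped (read, contig) pair: contig/coordinate/mapq fields
    plus the read's verdict and 7-rank lineage from the bigtable (keyed by
    seq_id). Reads absent from the bigtable join with sentinel taxonomy
    (outer-join semantics); row count always equals the mapped-pair count.
    """
    mapped = [m for m in mappings if m.is_mapped]
    left = pd.DataFrame([{
        "seq_id": m.read_id, "sample_id": m.sample_id, "contig_id": m.contig_id,
        "start": m.start, "end": m.end, "mapq": m.mapq,
    } for m in mapped])
    tax_cols = ["verdict", "taxid", *RANKS7]
    if left.empty:
        return pd.DataFrame(columns=["seq_id", "sample_id", "contig_id",
                                     "start", "end", "mapq", *tax_cols])
    right = bigtable_rows.drop_duplicates("seq_id")[["seq_id", *tax_cols]]
    joined = left.merge(right, on="seq_id", how="left")
    joined["verdict"] = joined["verdict"].fillna("unclassified")
    joined["taxid"] = joined["taxid"].fillna(SENTINEL_TAXID).astype(int)
    for rank in RANKS7:
        joined[rank] = joined[rank].fillna(SENTINEL)
    return joined


def contig_annotate(
    contig_hits: Sequence[AlignmentHit],
    tree: TaxonomyTree,
    config: ClassifyConfig | None = None,
    contig_ids: Iterable[str] | None = None,
) -> list[TierAnnotation]:
    """Direct contig taxonomy from polymicrobial-database hits.

    Per contig: augmented LCA over the e-value-windowed hit set; the
    verdict is viral exactly when the assigned taxid sits under the virus
    root. Contigs listed in ``contig_ids`` but without hits come back
    unclassified with sentinel taxonomy.
    """
    config = config or ClassifyConfig()
    by_contig: dict[str, list[AlignmentHit]] = {}
    for h in contig_hits:
        by_contig.setdefault(h.query_id, []).append(h)
    universe = set(contig_ids) if contig_ids is not None else set(by_contig)
    universe |= set(by_contig)

    annotations = []
    for cid in sorted(universe):
        hits = by_contig.get(cid)
        if not hits:
            annotations.append(TierAnnotation(
                query_id=cid, verdict="unclassified", taxid=SENTINEL_TAXID,
                search_type=None, lca=None, top_hit=None,
                tier_trace=("polymicrobial_nt",),
            ))
            continue
        window = lca_hit_set(hits, cid, config.evalue_factor)
        known = [h.target_taxid for h in window if h.target_taxid in tree]
        top = rank_hits(hits)[0]
        if not known:
            annotations.append(TierAnnotation(
                query_id=cid, verdict="unclassified", taxid=SENTINEL_TAXID,
                search_type="nt", lca=None, top_hit=top,
                tier_trace=("polymicrobial_nt",),
            ))
            continue
        lcares = augmented_lca(tree, known)
        verdict = "viral" if tree.is_viral(lcares.taxid) else "nonviral"
        annotations.append(TierAnnotation(
            query_id=cid, verdict=verdict, taxid=lcares.taxid,
            search_type="nt", lca=lcares, top_hit=top,
            tier_trace=("polymicrobial_nt",),
        ))
    return annotations


def contig_count_table(
    abundance: pd.DataFrame,
    annotations: Sequence[TierAnnotation],
    tree: TaxonomyTree,
) -> pd.DataFrame:
    """Final contig table: abundance plus 7-rank lineage per contig."""
    lineage_rows = {}
    for a in annotations:
        if a.taxid != SENTINEL_TAXID and a.taxid in tree:
            lin = lineage7(tree, a.taxid)
        else:
            lin = None
        lineage_rows[a.query_id] = {
            "taxid": a.taxid,
            **{rank: (getattr(lin, "class_" if rank == "class" else rank)
                      if lin else SENTINEL) for rank in RANKS7},
        }
    out = abundance.copy()
    for col in ("taxid", *RANKS7):
        out[col] = [
            lineage_rows.get(cid, {"taxid": SENTINEL_TAXID, **{r: SENTINEL for r in RANKS7}})[col]
            for cid in out["contig_id"]
        ]
    return out


# -- mapping ingestion -------------------------------------------------------

def read_sam_mappings(path, sample_id: str) -> list[ReadMapping]:
    """Read mappings from a SAM file (primary alignments only).

    Secondary (0x100) and supplementary (0x800) records are skipped so
    every read contributes at most one mapped row; unmapped records come
    through with ``is_mapped=False``.
    """
    import pysam

    mappings = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.is_unmapped:
                mappings.append(ReadMapping(
                    read_id=rec.query_name, sample_id=sample_id, is_mapped=False,
                ))
            else:
                mappings.append(ReadMapping(
                    read_id=rec.query_name, sample_id=sample_id,
                    contig_id=rec.reference_name,
                    start=rec.reference_start, end=rec.reference_end,
                    mapq=rec.mapping_quality, is_mapped=True,
                ))
    return mappings


def read_mappings_tsv(path) -> list[ReadMapping]:
    """Native mapping table: read_id, sample_id, contig_id, start, end, mapq, is_mapped."""
    frame = pd.read_csv(path, sep="\t")
    mappings = []
    for row in frame.itertuples(index=False):
        mapped = bool(row.is_mapped)
        mappings.append(ReadMapping(
            read_id=str(row.read_id), sample_id=str(row.sample_id),
            contig_id=str(row.contig_id) if mapped else None,
            start=int(row.start) if mapped else None,
            end=int(row.end) if mapped else None,
            mapq=int(row.mapq) if mapped else None,
            is_mapped=mapped,
        ))
    return mappings


def write_mappings_tsv(mappings: Sequence[ReadMapping], path) -> None:
    pd.DataFrame([{
        "read_id": m.read_id, "sample_id": m.sample_id,
        "contig_id": m.contig_id if m.is_mapped else "",
        "start": m.start if m.is_mapped else "",
        "end": m.end if m.is_mapped else "",
        "mapq": m.mapq if m.is_mapped else "",
        "is_mapped": m.is_mapped,
    } for m in mappings]).to_csv(path, sep="\t", index=False)
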