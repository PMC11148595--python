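"""Read dereplication bookkeeping: clustering, seqtable headers, count tables.

Per-sample reads are collapsed to representative sequences whose FASTA
headers encode ``sample:cluster_index:member_count:percent_of_sample``.
Unpacking those headers recovers per-sample counts, which serve as the
count table downstream, reported raw and normalized to library size
(counts per million).

The built-in clusterer is a deterministic greedy centroid algorithm
(longest-first; a read joins the first centroid it matches at >=97%
identity over an alignment covering >=80% of the centroid, mirroring
Linclust-style thresholds). Production-scale clusterings can be supplied
instead as a 2-column membership TSV (read_id, representative_id);
only the bookkeeping contract is load-bearing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from virannot.errors import ParseError, VirannotError

HEADER_DELIM = ":"
_VALID_CHARS = re.compile(r"^[ACGTN]*$")


@dataclass
class SeqCluster:
    """One representative sequence with its per-sample membership count."""

    representative_seq: str
    sample_id: str
    member_count: int
    percent_of_sample: float
    cluster_index: int
    representative_id: str = ""
    member_ids: tuple[str, ...] = ()

    @property
    def seq_id(self) -> str:
        """The encoded seqtable header; the primary key of all downstream joins."""
        return HEADER_DELIM.join((
            self.sample_id, str(self.cluster_index),
            str(self.member_count), f"{self.percent_of_sample:.1f}",
        ))


def _sanitize(read_id: str, seq: str) -> str:
    seq = seq.upper()
    if not _VALID_CHARS.match(seq):
        warnings.warn(f"read {read_id!r}: non-ACGTN characters mapped to N",
                      stacklevel=3)
        seq = re.sub(r"[^ACGTN]", "N", seq)
    return seq


def _identity_and_coverage(read: str, centroid: str) -> tuple[float, float]:
    """Infix-align read into centroid; identity over aligned columns, centroid coverage."""
    res = edlib.align(read, centroid, mode="HW", task="path")
    cigar = res["cigar"]
    matches = columns = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
    start, end = res["locations"][0]
    coverage = (end - start + 1) / len(centroid)
    identity = matches / columns if columns else 0.0
    return identity, coverage


def greedy_cluster(
    reads: Sequence[tuple[str, str]],
    sample_id: str = "sample",
    min_identity: float = 0.97,
    min_target_coverage: float = 0.8,
    sample_total: int | None = None,
    prefilter_k: int | None = 15,
) -> list[SeqCluster]:
    """Greedy centroid clustering of one sample's reads.

    Reads are processed longest-first (ties broken by read_id); each read
    joins the first existing centroid it matches at ``min_identity``
    (matches / alignment columns, gaps count against) over an alignment
    covering ``min_target_coverage`` of the centroid, else founds a new
    cluster. ``sample_total`` is the denominator for percent_of_sample
    (post-host-removal read count); defaults to the number of input reads.

    ``prefilter_k`` restricts alignment to centroids sharing an exact
    k-mer with the read (pigeonhole: any gap-free join candidate at the
    default thresholds shares a 15-mer for reads up to ~480 bases); pass
    ``None`` to force all-centroid comparison.
    """
    if not reads:
        raise ValueError("cannot cluster an empty read set")
    clean = [(rid, _sanitize(rid, seq)) for rid, seq in reads]
    ordered = sorted(clean, key=lambda r: (-len(r[1]), r[0]))
    total = sample_total if sample_total is not None else len(reads)
    if total <= 0:
        raise ValueError("sample_total must be positive")

    centroids: list[tuple[str, str, list[str]]] = []  # (rep_id, rep_seq, members)
    kmer_index: dict[str, set[int]] = {}

    def candidate_indices(seq: str):
        if prefilter_k is None or len(seq) < prefilter_k:
            return range(len(centroids))
        cands: set[int] = set()
        for pos in range(len(seq) - prefilter_k + 1):
            cands |= kmer_index.get(seq[pos:pos + prefilter_k], set())
        return sorted(cands)

    for rid, seq in ordered:
        for idx in candidate_indices(seq):
            rep_id, rep_seq, members = centroids[idx]
            identity, coverage = _identity_and_coverage(seq, rep_seq)
            if identity >= min_identity and coverage >= min_target_coverage:
                members.append(rid)
                break
        else:
            idx = len(centroids)
            centroids.append((rid, seq, [rid]))
            if prefilter_k is not None:
                for pos in range(len(seq) - prefilter_k + 1):
                    kmer_index.setdefault(seq[pos:pos + prefilter_k], set()).add(idx)

    return [
        SeqCluster(
            representative_seq=rep_seq,
            sample_id=sample_id,
            member_count=len(members),
            percent_of_sample=100.0 * len(members) / total,
            cluster_index=idx,
            representative_id=rep_id,
            member_ids=tuple(members),
        )
        for idx, (rep_id, rep_seq, members) in enumerate(centroids)
    ]


def clusters_from_membership(
    membership: Iterable[tuple[str, str]],
    reads: Mapping[str, str],
    sample_id: str = "sample",
    sample_total: int | None = None,
) -> list[SeqCluster]:
    """Build SeqClusters from an externally produced (read_id, representative_id) table."""
    groups: dict[str, list[str]] = {}
    n = 0
    for read_id, rep_id in membership:
        groups.setdefault(rep_id, []).append(read_id)
        n += 1
    if not groups:
        raise ValueError("empty membership table")
    total = sample_total if sample_total is not None else n
    clusters = []
    for idx, rep_id in enumerate(sorted(groups, key=lambda r: (-len(groups[r]), r))):
        if rep_id not in reads:
            raise VirannotError(f"representative {rep_id!r} absent from reads")
        members = groups[rep_id]
        clusters.append(SeqCluster(
            representative_seq=_sanitize(rep_id, reads[rep_id]),
            sample_id=sample_id, member_count=len(members),
            percent_of_sample=100.0 * len(members) / total,
            cluster_index=idx, representative_id=rep_id,
            member_ids=tuple(sorted(members)),
        ))
    return clusters


def encode_seqtable(clusters: Sequence[SeqCluster]) -> list[tuple[str, str]]:
    """(header, sequence) FASTA records with packed cluster metadata.

    Header syntax: ``sample:cluster_index:member_count:percent`` with the
    percentage rendered at 1 decimal.
    """
    records = []
    for c in clusters:
        if HEADER_DELIM in c.sample_id:
            raise VirannotError(
                f"sample_id {c.sample_id!r} contains the header delimiter "
                f"{HEADER_DELIM!r}; sanitize sample names first"
            )
        records.append((c.seq_id, c.representative_seq))
    return records


def decode_seqtable(records: Iterable[tuple[str, str]]) -> list[SeqCluster]:
    """Inverse of :func:`encode_seqtable` (percent at 1-decimal precision)."""
    clusters = []
    for header, seq in records:
        parts = header.split(HEADER_DELIM)
        if len(parts) != 4:
            raise ParseError(f"seqtable header {header!r} does not have 4 fields")
        sample_id, idx, count, pct = parts
        try:
            clusters.append(SeqCluster(
                representative_seq=seq, sample_id=sample_id,
                member_count=int(count), percent_of_sample=float(pct),
                cluster_index=int(idx),
            ))
        except ValueError as exc:
            raise ParseError(f"bad seqtable header {header!r}: {exc}") from None
    return clusters


def write_seqtable_fasta(clusters: Sequence[SeqCluster], path) -> None:
    with open(path, "w") as fh:
        for header, seq in encode_seqtable(clusters):
            fh.write(f">{header}\n{seq}\n")


def read_seqtable_fasta(path) -> list[SeqCluster]:
    from virannot.io import read_fasta
    return decode_seqtable(read_fasta(path))


def count_table(
    clusters: Sequence[SeqCluster],
    sample_totals: Mapping[str, int],
) -> pd.DataFrame:
    """Raw and library-size-normalized (counts-per-million) count table.

    One row per cluster: seq_id, sample_id, raw_count, cpm with
    ``cpm = raw * 1e6 / sample_totals[sample]``; rows ordered by
    (sample_id, raw_count desc, seq_id).
    """
    rows = []
    for c in clusters:
        if c.sample_id not in sample_totals:
            raise VirannotError(f"no sample total for {c.sample_id!r}")
        total = sample_totals[c.sample_id]
        if total <= 0:
            raise ValueError(f"sample total for {c.sample_id!r} must be positive")
        rows.append({
            "seq_id": c.seq_id,
            "sample_id": c.sample_id,
            "raw_count": c.member_count,
            "cpm": c.member_count * 1e6 / total,
        })
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["sample_id", "raw_count", "seq_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
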