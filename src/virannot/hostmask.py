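"""Viral-aware host-genome masking.

Host-read removal can silently delete genuine viral reads when the host
reference contains virus-like sequence (endogenous elements, integrated
prophage, contamination). The remedy implemented here: shred a viral
reference collection into short overlapping fragments (85 bp windows
sharing a 30 bp overlap), locate those fragments on the host genome at
>=90% identity allowing at most 2 insertion/deletion events, and hard-mask
every matched interval with ``N`` so mapping against the host can no
longer swallow reads from those regions.

Externally produced mappings are accepted as BED intervals
(0-based half-open); the built-in seed-and-extend mapper serves desk-scale
use and tests.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib

from virannot.errors import VirannotError

DEFAULT_FRAGMENT_LENGTH = 85
DEFAULT_OVERLAP = 30
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MAX_INDELS = 2

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Fragment:
    """A shred window on a source sequence (0-based half-open coordinates)."""

    source_id: str
    start: int
    end: int
    sequence: str


@dataclass(frozen=True)
class MaskInterval:
    """A host-genome interval to mask (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    provenance: str = "internal_map"  # internal_map | external


def shred(
    seq_id: str,
    sequence: str,
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    overlap: int = DEFAULT_OVERLAP,
) -> list[Fragment]:
    """Cut a sequence into overlapping windows.

    Windows start at multiples of ``fragment_length - overlap`` (step 55
    at the defaults); the final window is truncated at the sequence end,
    so every base is covered by at least one fragment. Sequences shorter
    than one window yield a single full-length fragment.
    """
    if not sequence:
        raise ValueError(f"cannot shred empty sequence {seq_id!r}")
    if not fragment_length > overlap >= 0:
        raise ValueError("need fragment_length > overlap >= 0")
    step = fragment_length - overlap
    n = len(sequence)
    fragments = []
    start = 0
    while start + fragment_length < n:
        fragments.append(Fragment(seq_id, start, start + fragment_length,
                                  sequence[start:start + fragment_length]))
        start += step
    fragments.append(Fragment(seq_id, start, n, sequence[start:n]))
    return fragments


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(matches, columns, indel events) from an edlib extended CIGAR."""
    matches = columns = indel_events = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(count)
        columns += n
        if op == "=":
            matches += n
        if op in "ID":
            indel_events += 1  # one event per gap run
    return matches, columns, indel_events


def map_fragments(
    fragments: Sequence[Fragment],
    host: Sequence[tuple[str, str]] | Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_indels: int = DEFAULT_MAX_INDELS,
    seed_k: int = 13,
) -> list[MaskInterval]:
    """Locate fragments on the host (both strands) and return hit intervals.

    Seed-and-extend: exact ``seed_k``-mer seeds anchor candidate diagonals;
    each candidate window is verified by infix alignment (edlib). An
    alignment is accepted when identity over its columns is at least
    ``min_identity`` and it contains at most ``max_indels`` insertion or
    deletion *events* (gap runs). Zero matches is a valid empty result.
    """
    contigs = dict(host) if not isinstance(host, Mapping) else dict(host)
    index: dict[str, list[tuple[str, int]]] = {}
    for cid, seq in contigs.items():
        seq = seq.upper()
        for pos in range(len(seq) - seed_k + 1):
            kmer = seq[pos:pos + seed_k]
            if "N" not in kmer:
                index.setdefault(kmer, []).append((cid, pos))

    accepted: set[MaskInterval] = set()
    for frag in fragments:
        for seq in (frag.sequence.upper(), revcomp(frag.sequence.upper())):
            if len(seq) < seed_k:
                continue
            # candidate (contig, diagonal) pairs from exact seeds
            candidates: set[tuple[str, int]] = set()
            for q in range(len(seq) - seed_k + 1):
                for cid, pos in index.get(seq[q:q + seed_k], ()):
                    candidates.add((cid, pos - q))
            # merge nearby diagonals (within the indel budget)
            seen_windows: set[tuple[str, int]] = set()
            for cid, diag in candidates:
                margin = max_indels + 3
                w_start = max(0, diag - margin)
                key = (cid, w_start // max(1, margin))
                if key in seen_windows:
                    continue
                seen_windows.add(key)
                w_end = min(len(contigs[cid]), diag + len(seq) + margin)
                window = contigs[cid].upper()[w_start:w_end]
                res = edlib.align(seq, window, mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                matches, columns, indels = _cigar_stats(res["cigar"])
                if columns == 0 or matches / columns < min_identity:
                    continue
                if indels > max_indels:
                    continue
                loc_start, loc_end = res["locations"][0]
                accepted.add(MaskInterval(
                    cid, w_start + loc_start, w_start + loc_end + 1,
                    provenance="internal_map",
                ))
    return sorted(accepted, key=lambda iv: (iv.contig_id, iv.start, iv.end))


def merge_intervals(intervals: Iterable[MaskInterval]) -> dict[str, list[tuple[int, int]]]:
    """Union of intervals per contig as sorted disjoint (start, end) pairs."""
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        per_contig.setdefault(iv.contig_id, []).append((iv.start, iv.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for cid, spans in per_contig.items():
        spans.sort()
        out: list[tuple[int, int]] = []
        for start, end in spans:
            if out and start <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], end))
            else:
                out.append((start, end))
        merged[cid] = out
    return merged


def mask_intervals(
    host: Sequence[tuple[str, str]],
    intervals: Iterable[MaskInterval],
    mask_char: str = "N",
) -> list[tuple[str, str]]:
    """Hard-mask the union of intervals; everything else is untouched.

    Lengths are conserved and masking is idempotent. An interval that
    overruns its contig raises, naming the contig.
    """
    lengths = {cid: len(seq) for cid, seq in host}
    for iv in intervals:
        if iv.contig_id not in lengths:
            raise VirannotError(f"interval on unknown contig {iv.contig_id!r}")
        if not (0 <= iv.start < iv.end <= lengths[iv.contig_id]):
            raise VirannotError(
                f"interval [{iv.start},{iv.end}) out of bounds on contig "
                f"{iv.contig_id!r} (length {lengths[iv.contig_id]})"
            )
    merged = merge_intervals(intervals)
    out = []
    for cid, seq in host:
        chars = list(seq)
        for start, end in merged.get(cid, ()):
            chars[start:end] = mask_char * (end - start)
        out.append((cid, "".join(chars)))
    return out


def mask_host(
    host: Sequence[tuple[str, str]],
    viral: Sequence[tuple[str, str]],
    fragment_length: int = DEFAULT_FRAGMENT_LENGTH,
    overlap: int = DEFAULT_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    max_indels: int = DEFAULT_MAX_INDELS,
) -> tuple[list[tuple[str, str]], list[MaskInterval]]:
    """The full recipe: shred the viral set, map, mask. Returns (masked host, intervals)."""
    fragments = [f for cid, seq in viral for f in shred(cid, seq, fragment_length, overlap)]
    intervals = map_fragments(fragments, host, min_identity, max_indels)
    return mask_intervals(host, intervals), intervals


def read_bed(path) -> list[MaskInterval]:
    """3-column BED (0-based half-open) as externally provided mask intervals."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append(MaskInterval(
                fields[0], int(fields[1]), int(fields[2]), provenance="external",
            ))
    return intervals


def write_bed(intervals: Iterable[MaskInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\n")
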