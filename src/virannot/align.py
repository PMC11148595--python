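"""Naive seed-and-extend aligner emitting BLAST-tabular hits.

A deterministic, desk-scale stand-in for a production aligner so that the
classification tiers can be exercised end to end on toy databases.
Queries are anchored by exact k-mer seeds and verified by infix alignment
(edlib); nucleotide mode searches both strands, amino-acid mode
translates queries in all 6 frames with the standard genetic code.

Scores are a documented bitscore-like proxy, not comparable to a
production aligner's: ungapped-style scoring (nt: +2/-3, gap open -5,
extend -2, Karlin-Altschul constants lambda=0.625, K=0.41; aa: +4/-2,
gap open -6, extend -1, lambda=0.267, K=0.041) with
``E = m * n * 2**-bits``. Thresholds applied to them are calibrated on
the packaged fixtures.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import log, log2
from typing import Mapping, Sequence

import edlib
from Bio.Seq import Seq

from virannot.hits import AlignmentHit
from virannot.hostmask import revcomp

DEFAULT_MAX_EVALUE = 1e-3


@dataclass(frozen=True)
class _ScoreScheme:
    match: float
    mismatch: float
    gap_open: float
    gap_extend: float
    lam: float
    k: float

    def bits(self, matches: int, mismatches: int, gap_runs: int, gap_cols: int) -> float:
        raw = (self.match * matches - self.mismatch * mismatches
               - self.gap_open * gap_runs
               - self.gap_extend * max(0, gap_cols - gap_runs))
        return (self.lam * raw - log(self.k)) / log(2)


_NT_SCHEME = _ScoreScheme(2.0, 3.0, 5.0, 2.0, 0.625, 0.41)
_AA_SCHEME = _ScoreScheme(4.0, 2.0, 6.0, 1.0, 0.267, 0.041)


def six_frame_translate(seq: str) -> list[tuple[int, str]]:
    """(frame, peptide) for frames 1..3 (forward) and -1..-3 (reverse)."""
    out = []
    rc = revcomp(seq.upper())
    for frame in (0, 1, 2):
        for sign, s in ((1, seq.upper()), (-1, rc)):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                out.append((sign * (frame + 1), str(Seq(sub).translate())))
    return out


def _cigar_stats(cigar: str) -> tuple[int, int, int, int]:
    matches = mismatches = gap_runs = gap_cols = 0
    for count, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(count)
        if op == "=":
            matches += n
        elif op in "XM":
            mismatches += n
        else:
            gap_runs += 1
            gap_cols += n
    return matches, mismatches, gap_runs, gap_cols


def _candidates(seq: str, index: Mapping[str, list[tuple[str, int]]], k: int):
    cands: set[tuple[str, int]] = set()
    for q in range(0, len(seq) - k + 1):
        for tid, pos in index.get(seq[q:q + k], ()):
            cands.add((tid, pos - q))
    return cands


def _build_index(targets: Sequence[tuple[str, str]], k: int):
    index: dict[str, list[tuple[str, int]]] = {}
    total = 0
    for tid, seq in targets:
        total += len(seq)
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos:pos + k], []).append((tid, pos))
    return index, total


def _align_one(
    qid: str, qseq: str, targets: Mapping[str, str],
    index, k: int, scheme: _ScoreScheme, db_len: int,
    search_type: str, strand: str, max_evalue: float, min_bitscore: float,
) -> list[AlignmentHit]:
    hits = []
    margin = 6
    seen: set[tuple[str, int]] = set()
    for tid, diag in sorted(_candidates(qseq, index, k)):
        w_start = max(0, diag - margin)
        key = (tid, w_start // margin if margin else w_start)
        if key in seen:
            continue
        seen.add(key)
        tseq = targets[tid]
        w_end = min(len(tseq), diag + len(qseq) + margin)
        res = edlib.align(qseq, tseq[w_start:w_end], mode="HW", task="path")
        if res["editDistance"] < 0:
            continue
        matches, mismatches, gap_runs, gap_cols = _cigar_stats(res["cigar"])
        columns = matches + mismatches + gap_cols
        if columns == 0:
            continue
        bits = scheme.bits(matches, mismatches, gap_runs, gap_cols)
        evalue = max(len(qseq) * db_len * 2.0 ** -bits, 0.0)
        if evalue > max_evalue or bits < min_bitscore:
            continue
        loc_start, loc_end = res["locations"][0]
        hits.append(AlignmentHit(
            query_id=qid, target_id=tid,
            pident=round(100.0 * matches / columns, 1),
            alnlen=columns, mismatch=mismatches, gapopen=gap_runs,
            qstart=1, qend=len(qseq),
            tstart=w_start + loc_start + 1, tend=w_start + loc_end + 1,
            evalue=evalue, bitscore=round(bits, 1),
            target_taxid=0, search_type=search_type, strand=strand,
        ))
    return hits


def naive_align(
    queries: Sequence[tuple[str, str]],
    targets: Sequence[tuple[str, str]],
    taxid_map: Mapping[str, int],
    mode: str = "nt",
    min_bitscore_proxy: float = 0.0,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    seed_k: int | None = None,
) -> list[AlignmentHit]:
    """Align queries against a small target collection; 13-column-m8-shaped hits.

    ``mode`` is ``"nt"`` (both strands) or ``"aa-6frame"`` (nucleotide
    queries translated in 6 frames against protein targets; coordinates
    are peptide coordinates). ``taxid_map`` must cover every target.
    Output order is deterministic: (query_id, bitscore desc, evalue,
    target_id).
    """
    if mode not in ("nt", "aa-6frame"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [tid for tid, _ in targets if tid not in taxid_map]
    if missing:
        raise ValueError(f"targets without taxids: {missing[:5]}")
    search_type = "nt" if mode == "nt" else "aa"
    scheme = _NT_SCHEME if mode == "nt" else _AA_SCHEME
    k = seed_k if seed_k is not None else (13 if mode == "nt" else 5)
    tmap = {tid: seq.upper() for tid, seq in targets}
    index, db_len = _build_index(list(tmap.items()), k)

    all_hits: list[AlignmentHit] = []
    for qid, qseq in queries:
        qseq = qseq.upper()
        per_query: dict[tuple, AlignmentHit] = {}
        if mode == "nt":
            variants = [(qseq, "+"), (revcomp(qseq), "-")]
        else:
            variants = [(pep, f"frame{frame:+d}")
                        for frame, pep in six_frame_translate(qseq)]
        for seq, label in variants:
            strand = "-" if label == "-" else "+"
            for h in _align_one(qid, seq, tmap, index, k, scheme, db_len,
                                search_type, strand, max_evalue,
                                min_bitscore_proxy):
                key = (h.target_id, h.tstart, h.tend)
                prev = per_query.get(key)
                if prev is None or h.bitscore > prev.bitscore:
                    per_query[key] = h
        resolved = [
            AlignmentHit(**{**h.__dict__, "target_taxid": taxid_map[h.target_id]})
            for h in per_query.values()
        ]
        resolved.sort(key=lambda h: (-h.bitscore, h.evalue, h.target_id, h.tstart))
        all_hits.extend(resolved)
    return all_hits
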