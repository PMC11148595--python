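"""The unified per-representative annotation table ("bigtable") and QC quadrants.

Seqtable metadata (sample, member count, CPM), tier verdicts, the top
hit's alignment metrics, the 7-rank lineage and the Baltimore
classification are joined on the representative sequence id into one
tidy table — the study-wide substrate for downstream filtering and
statistics.

The quadrant classifier triages hits by percent identity and alignment
length into a 2x2 space (defaults: 70% identity for translated, 90% for
untranslated searches; 150 aligned bases): Q1 high identity/short, Q2
high/long, Q3 low/short, Q4 low/long. Boundary values count as the
high/long side.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from virannot.classify import TierAnnotation
from virannot.errors import IntegrityError
from virannot.hits import M8_COLUMNS
from virannot.seqtable import SeqCluster
from virannot.taxonomy import (
    RANKS7,
    SENTINEL,
    SENTINEL_TAXID,
    BaltimoreEntry,
    TaxonomyTree,
    lineage7,
)

logger = logging.getLogger(__name__)

BALTIMORE_NA = "NA"

HIT_COLUMNS = [c for c in M8_COLUMNS if c != "query_id"]

BIGTABLE_COLUMNS = (
    "seq_id", "sample_id", "member_count", "cpm", "verdict", "search_type",
    "augmented", *HIT_COLUMNS, "taxid", *RANKS7, "baltimore_group", "nucleic_acid",
)


@dataclass(frozen=True)
class QuadrantCall:
    quadrant: str  # Q1..Q4
    id_cutoff: float
    len_cutoff: int


def quadrant(
    pident: float,
    alnlen: int,
    search_type: str = "aa",
    id_cutoff_aa: float = 70.0,
    id_cutoff_nt: float = 90.0,
    len_cutoff: int = 150,
) -> QuadrantCall:
    """Classify one hit into the identity/alignment-length quadrant space."""
    if pident < 0 or alnlen < 0:
        raise ValueError("pident and alnlen must be non-negative")
    cutoff = id_cutoff_aa if search_type == "aa" else id_cutoff_nt
    high = pident >= cutoff
    long_ = alnlen >= len_cutoff
    if high:
        quad = "Q2" if long_ else "Q1"
    else:
        quad = "Q4" if long_ else "Q3"
    return QuadrantCall(quadrant=quad, id_cutoff=cutoff, len_cutoff=len_cutoff)


def build_bigtable(
    clusters: Sequence[SeqCluster],
    tiers: Sequence[TierAnnotation],
    tree: TaxonomyTree,
    baltimore: Mapping[str, BaltimoreEntry],
    sample_totals: Mapping[str, int],
) -> pd.DataFrame:
    """Assemble the bigtable: one row per (representative, sample).

    Left join on seq_id: every cluster yields a row even without a tier
    annotation (then unclassified with sentinel taxonomy). CPM is
    recomputed from member_count and the per-sample totals. The Baltimore
    columns join on the family name, sentinel ``NA`` for non-viral or
    unknown families. Row order: (sample_id, member_count desc, seq_id).
    """
    by_seq = {}
    for t in tiers:
        by_seq[t.query_id] = t
    known_ids = {c.seq_id for c in clusters}
    stray = sorted(set(by_seq) - known_ids)
    if stray:
        raise IntegrityError(f"tier annotations for unknown seq_ids: {stray[:5]}")

    rows = []
    for c in clusters:
        if c.sample_id not in sample_totals:
            raise IntegrityError(f"no sample total for {c.sample_id!r}")
        t = by_seq.get(c.seq_id)
        row: dict = {
            "seq_id": c.seq_id,
            "sample_id": c.sample_id,
            "member_count": c.member_count,
            "cpm": c.member_count * 1e6 / sample_totals[c.sample_id],
        }
        if t is None or t.verdict == "unclassified":
            row.update(verdict="unclassified", search_type="", augmented=False,
                       taxid=SENTINEL_TAXID)
            row.update({col: "" for col in HIT_COLUMNS})
            row.update({rank: SENTINEL for rank in RANKS7})
        else:
            row.update(verdict=t.verdict, search_type=t.search_type,
                       augmented=t.augmented, taxid=t.taxid)
            hit = t.top_hit
            if hit is not None:
                fields = dict(zip(M8_COLUMNS, hit.m8_fields()))
                row.update({col: fields[col] for col in HIT_COLUMNS})
            else:
                row.update({col: "" for col in HIT_COLUMNS})
            if t.taxid != SENTINEL_TAXID and t.taxid in tree:
                lin = lineage7(tree, t.taxid)
                for rank in RANKS7:
                    attr = "class_" if rank == "class" else rank
                    row[rank] = getattr(lin, attr)
            else:
                row.update({rank: SENTINEL for rank in RANKS7})
        entry = baltimore.get(row["family"]) if row.get("family") else None
        row["baltimore_group"] = entry.baltimore_group if entry else BALTIMORE_NA
        row["nucleic_acid"] = entry.nucleic_acid if entry else BALTIMORE_NA
        rows.append(row)

    frame = pd.DataFrame(rows, columns=list(BIGTABLE_COLUMNS))
    frame = frame.sort_values(
        ["sample_id", "member_count", "seq_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    dupes = frame.duplicated(["seq_id", "sample_id"])
    if dupes.any():
        raise IntegrityError("duplicate (seq_id, sample_id) rows in bigtable")
    return frame


_OPS = {
    "eq": operator.eq, "==": operator.eq,
    "ne": operator.ne, "!=": operator.ne,
    "lt": operator.lt, "<": operator.lt,
    "le": operator.le, "<=": operator.le,
    "gt": operator.gt, ">": operator.gt,
    "ge": operator.ge, ">=": operator.ge,
}


def filter_bigtable(
    rows: pd.DataFrame,
    predicates: Sequence[tuple[str, str, object]],
) -> pd.DataFrame:
    """Filter by a conjunction of (field, op, value) predicates.

    Ops: eq/ne/lt/le/gt/ge (symbol aliases accepted). An unknown field or
    op is an argument error; the surviving row count is logged.
    """
    mask = pd.Series(True, index=rows.index)
    for field, op, value in predicates:
        if field not in rows.columns:
            raise ValueError(f"unknown bigtable column {field!r}")
        if op not in _OPS:
            raise ValueError(f"unknown predicate op {op!r}")
        mask &= _OPS[op](rows[field], value)
    out = rows[mask].reset_index(drop=True)
    logger.info("filter_bigtable: %d/%d rows pass %d predicate(s)",
                len(out), len(rows), len(predicates))
    return out


def write_bigtable(frame: pd.DataFrame, path) -> None:
    """Write bigtable.tsv with a '#'-prefixed, versioned header line."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(frame.columns) + "\n")
        frame.to_csv(fh, sep="\t", index=False, header=False)


def read_bigtable(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        frame = pd.read_csv(fh, sep="\t", names=header,
                            keep_default_na=False, na_values=[])
    for col in ("member_count", "taxid"):
        frame[col] = frame[col].astype(int)
    frame["cpm"] = frame["cpm"].astype(float)
    frame["augmented"] = frame["augmented"].astype(str).str.lower().isin(("true", "1"))
    return frame
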