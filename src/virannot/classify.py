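"""Tiered viral/multikingdom read classification.

Representative sequences are annotated in tiers:

1. primary query against a viral-only amino-acid database;
2. hits are cross-checked against a multikingdom amino-acid database to
   remove false positives (a non-viral secondary hit that strictly
   dominates every viral secondary hit by bitscore vetoes the viral call);
3. sequences with no viral aa evidence are queried against a viral-only
   nucleotide database;
4. those hits are cross-checked against a polymicrobial nucleotide
   database the same way;
5. verdicts are merged into one annotation per representative sequence.

Amino-acid-tier verdicts (viral or nonviral) are final: a sequence with
viral aa evidence never falls through to the nucleotide tier. Sequences
with no hits anywhere are retained as ``unclassified`` rather than
dropped, so downstream count conservation holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from virannot.errors import IntegrityError
from virannot.hits import AlignmentHit, M8_COLUMNS, lca_hit_set, rank_hits
from virannot.taxonomy import (
    SENTINEL_TAXID,
    LcaResult,
    TaxonomyTree,
    augmented_lca,
)

VERDICTS = ("viral", "nonviral", "unclassified")

TIER_VIRAL_AA = "viral_aa"
TIER_MK_AA = "multikingdom_aa"
TIER_VIRAL_NT = "viral_nt"
TIER_POLY_NT = "polymicrobial_nt"


@dataclass
class ClassifyConfig:
    """Knobs of the tiered classifier.

    evalue_factor: width of the e-value window around the top hit over
        which the LCA is computed (common 2b-LCA practice is one order of
        magnitude).
    """

    evalue_factor: float = 10.0


@dataclass(frozen=True)
class TierAnnotation:
    """The classification outcome for one representative sequence."""

    query_id: str
    verdict: str  # viral | nonviral | unclassified
    taxid: int  # SENTINEL_TAXID when unclassified
    search_type: str | None  # "aa" | "nt"; None when unclassified
    lca: LcaResult | None
    top_hit: AlignmentHit | None
    tier_trace: tuple[str, ...]

    @property
    def augmented(self) -> bool:
        return bool(self.lca and self.lca.augmented)


def _known_taxids(tree: TaxonomyTree, hits: Sequence[AlignmentHit]) -> list[int]:
    known, unknown = [], []
    for h in hits:
        (known if h.target_taxid in tree else unknown).append(h.target_taxid)
    if unknown:
        warnings.warn(
            f"{len(unknown)} hit(s) with taxids absent from the taxonomy "
            f"(e.g. {unknown[0]}); excluded from LCA", stacklevel=3,
        )
    return known


def confirm_viral(
    primary_top: AlignmentHit,
    secondary_hits: Sequence[AlignmentHit],
    tree: TaxonomyTree,
    evalue_factor: float = 10.0,
) -> tuple[str, LcaResult]:
    """Confirmatory cross-check of a putative viral hit.

    ``primary_top`` is the best hit from a viral-only database;
    ``secondary_hits`` are the same query's hits against the multikingdom
    (or polymicrobial) database. With no secondary evidence the primary
    call stands. Otherwise the viral verdict survives unless the best
    non-viral secondary hit strictly outscores every viral secondary hit;
    the surviving assignment is the augmented LCA over the e-value-windowed
    set of viral-consistent secondary hits.
    """
    if not secondary_hits:
        return "viral", LcaResult(taxid=primary_top.target_taxid,
                                  augmented=False, basis="lca")
    ranked = rank_hits(secondary_hits)
    unknown = [h.target_taxid for h in ranked if h.target_taxid not in tree]
    if unknown:
        warnings.warn(
            f"{len(unknown)} secondary hit(s) with taxids absent from the "
            f"taxonomy (e.g. {unknown[0]}); treated as non-viral", stacklevel=2,
        )
    viral_sec = [h for h in ranked if tree.is_viral(h.target_taxid)]
    top_sec = ranked[0]
    if not tree.is_viral(top_sec.target_taxid):
        best_viral_score = viral_sec[0].bitscore if viral_sec else None
        if best_viral_score is None or top_sec.bitscore > best_viral_score:
            taxid = (top_sec.target_taxid if top_sec.target_taxid in tree
                     else SENTINEL_TAXID)
            return "nonviral", LcaResult(taxid=taxid, augmented=False, basis="lca")
    # viral verdict: LCA over the e-value window of viral-consistent hits
    window = lca_hit_set(viral_sec, top_sec.query_id, evalue_factor)
    taxids = _known_taxids(tree, window)
    if not taxids:
        return "viral", LcaResult(taxid=primary_top.target_taxid,
                                  augmented=False, basis="lca")
    return "viral", augmented_lca(tree, taxids)


def _by_query(hits: Iterable[AlignmentHit]) -> dict[str, list[AlignmentHit]]:
    grouped: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return grouped


def tiered_classify(
    queries: Iterable[str],
    viral_aa: Sequence[AlignmentHit],
    mk_aa: Sequence[AlignmentHit],
    viral_nt: Sequence[AlignmentHit],
    poly_nt: Sequence[AlignmentHit],
    tree: TaxonomyTree,
    config: ClassifyConfig | None = None,
) -> list[TierAnnotation]:
    """Route every query through the tiers and return one annotation each.

    The four hit lists correspond to the four databases of the tiered
    design; ``queries`` is the universe of representative sequences. The
    result is sorted by query_id and invariant under permutation of the
    input hit lists.
    """
    config = config or ClassifyConfig()
    universe = set(queries)
    grouped = {
        TIER_VIRAL_AA: _by_query(viral_aa),
        TIER_MK_AA: _by_query(mk_aa),
        TIER_VIRAL_NT: _by_query(viral_nt),
        TIER_POLY_NT: _by_query(poly_nt),
    }
    for tier, table in grouped.items():
        stray = sorted(set(table) - universe)
        if stray:
            raise IntegrityError(
                f"{tier} hits for unknown queries: {stray[:5]}"
                + ("..." if len(stray) > 5 else "")
            )

    annotations: list[TierAnnotation] = []
    for qid in sorted(universe):
        v_aa = grouped[TIER_VIRAL_AA].get(qid)
        v_nt = grouped[TIER_VIRAL_NT].get(qid)
        if v_aa:
            primary_top = rank_hits(v_aa)[0]
            verdict, lcares = confirm_viral(
                primary_top, grouped[TIER_MK_AA].get(qid, []), tree,
                config.evalue_factor,
            )
            top = primary_top if verdict == "viral" else rank_hits(
                grouped[TIER_MK_AA][qid])[0]
            annotations.append(TierAnnotation(
                query_id=qid, verdict=verdict, taxid=lcares.taxid,
                search_type="aa", lca=lcares, top_hit=top,
                tier_trace=(TIER_VIRAL_AA, TIER_MK_AA),
            ))
        elif v_nt:
            primary_top = rank_hits(v_nt)[0]
            verdict, lcares = confirm_viral(
                primary_top, grouped[TIER_POLY_NT].get(qid, []), tree,
                config.evalue_factor,
            )
            top = primary_top if verdict == "viral" else rank_hits(
                grouped[TIER_POLY_NT][qid])[0]
            annotations.append(TierAnnotation(
                query_id=qid, verdict=verdict, taxid=lcares.taxid,
                search_type="nt", lca=lcares, top_hit=top,
                tier_trace=(TIER_VIRAL_AA, TIER_VIRAL_NT, TIER_POLY_NT),
            ))
        else:
            annotations.append(TierAnnotation(
                query_id=qid, verdict="unclassified", taxid=SENTINEL_TAXID,
                search_type=None, lca=None, top_hit=None,
                tier_trace=(TIER_VIRAL_AA, TIER_VIRAL_NT),
            ))
    return annotations


def annotations_to_frame(annotations: Sequence[TierAnnotation]) -> pd.DataFrame:
    """Tier annotations as a tidy table (one row per query).

    Columns: query_id, verdict, taxid, search_type, augmented, tier_trace
    (comma-joined) plus the top hit's 12 m8 metric columns (NA when there
    is no hit).
    """
    rows = []
    for a in annotations:
        row = {
            "query_id": a.query_id,
            "verdict": a.verdict,
            "taxid": a.taxid,
            "search_type": a.search_type if a.search_type else "",
            "augmented": a.augmented,
            "tier_trace": ",".join(a.tier_trace),
        }
        if a.top_hit is not None:
            for col, val in zip(M8_COLUMNS, a.top_hit.m8_fields()):
                if col != "query_id":
                    row[f"hit_{col}"] = val
        rows.append(row)
    frame = pd.DataFrame(rows)
    hit_cols = [f"hit_{c}" for c in M8_COLUMNS if c != "query_id"]
    for col in hit_cols:
        if col not in frame.columns:
            frame[col] = pd.NA
    return frame[["query_id", "verdict", "taxid", "search_type", "augmented",
                  "tier_trace"] + hit_cols]


def write_tier_tsv(annotations: Sequence[TierAnnotation], path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)
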