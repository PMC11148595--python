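"""BLAST-tabular ("m8") alignment hits: parsing, ranking, LCA hit sets.

The 12-column BLAST tabular layout (query, target, pident, alnlen,
mismatch, gapopen, qstart, qend, tstart, tend, evalue, bitscore) is the
lingua franca of the classification tiers; an optional 13th column carries
the target taxid, otherwise a target->taxid map must cover every target.

Coordinates are 1-based inclusive at the file boundary, as emitted by
aligners. Reverse-strand hits (tstart > tend) are normalized to ascending
coordinates with a ``strand`` flag of ``"-"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from virannot.errors import ParseError

#: Hits with evalue above this are discarded at parse time unless overridden.
DEFAULT_EVALUE_CEILING = 1e-3

M8_COLUMNS = (
    "query_id", "target_id", "pident", "alnlen", "mismatch", "gapopen",
    "qstart", "qend", "tstart", "tend", "evalue", "bitscore",
)


@dataclass(frozen=True)
class AlignmentHit:
    """One m8 row plus its target taxid; the unit of all classification."""

    query_id: str
    target_id: str
    pident: float  # percent, 0-100
    alnlen: int  # aligned columns, aa or nt units per search type
    mismatch: int
    gapopen: int
    qstart: int  # 1-based inclusive
    qend: int
    tstart: int
    tend: int
    evalue: float
    bitscore: float
    target_taxid: int
    search_type: str = "nt"  # "aa" | "nt"
    strand: str = "+"

    def __post_init__(self):
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident out of range: {self.pident}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue: {self.evalue}")
        if self.qstart > self.qend:
            raise ValueError("qstart > qend after normalization")

    def m8_fields(self) -> tuple:
        """The 12 standard m8 metric fields, file order."""
        return (self.query_id, self.target_id, self.pident, self.alnlen,
                self.mismatch, self.gapopen, self.qstart, self.qend,
                self.tstart, self.tend, self.evalue, self.bitscore)


def _normalize_orientation(fields: dict) -> dict:
    """Ascending coordinates on both axes; reverse orientation -> strand '-'."""
    strand = "+"
    if fields["qstart"] > fields["qend"]:
        fields["qstart"], fields["qend"] = fields["qend"], fields["qstart"]
        strand = "-"
    if fields["tstart"] > fields["tend"]:
        fields["tstart"], fields["tend"] = fields["tend"], fields["tstart"]
        strand = "-" if strand == "+" else "+"
    fields["strand"] = strand
    return fields


def parse_m8(
    path,
    search_type: str = "nt",
    taxid_map: Mapping[str, int] | None = None,
    evalue_ceiling: float | None = DEFAULT_EVALUE_CEILING,
) -> tuple[list[AlignmentHit], list[tuple[int, str]]]:
    """Parse a 12- or 13-column BLAST-tabular file.

    With 13 columns the last is the target taxid; with 12 the ``taxid_map``
    must cover the targets. Rows whose target cannot be mapped are returned
    in the reject report as (line number, raw line) pairs rather than
    silently dropped. Rows with evalue above ``evalue_ceiling`` are
    discarded (pass ``None`` to keep everything).

    Returns ``(hits, rejects)``.
    """
    if search_type not in ("aa", "nt"):
        raise ValueError(f"search_type must be 'aa' or 'nt', got {search_type!r}")
    hits: list[AlignmentHit] = []
    rejects: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise ParseError(
                    f"m8 row has {len(fields)} columns, expected 12 or 13",
                    path=path, line=lineno,
                )
            try:
                parsed = dict(
                    query_id=fields[0],
                    target_id=fields[1],
                    pident=float(fields[2]),
                    alnlen=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    tstart=int(fields[8]),
                    tend=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ParseError(f"non-numeric m8 field: {exc}",
                                 path=path, line=lineno) from None
            if len(fields) == 13:
                try:
                    taxid = int(fields[12])
                except ValueError:
                    raise ParseError("non-integer taxid column",
                                     path=path, line=lineno) from None
            elif taxid_map is not None and fields[1] in taxid_map:
                taxid = taxid_map[fields[1]]
            else:
                rejects.append((lineno, line))
                continue
            hit = AlignmentHit(**_normalize_orientation(parsed),
                               target_taxid=taxid, search_type=search_type)
            if evalue_ceiling is not None and hit.evalue > evalue_ceiling:
                continue
            hits.append(hit)
    return hits, rejects


def write_m8(hits: Iterable[AlignmentHit], path, with_taxid: bool = True) -> None:
    """Write hits as 12/13-column BLAST tabular (taxid in column 13)."""
    with open(path, "w") as fh:
        for h in hits:
            fields = [h.query_id, h.target_id, f"{h.pident:.1f}", h.alnlen,
                      h.mismatch, h.gapopen, h.qstart, h.qend, h.tstart,
                      h.tend, f"{h.evalue:.3g}", f"{h.bitscore:.1f}"]
            if with_taxid:
                fields.append(h.target_taxid)
            fh.write("\t".join(str(f) for f in fields) + "\n")


def _hit_rank_key(hit: AlignmentHit) -> tuple:
    # higher bitscore, then lower evalue, then lexicographically smallest target
    return (-hit.bitscore, hit.evalue, hit.target_id)


def rank_hits(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Deterministic hit ranking: bitscore desc, evalue asc, target_id asc."""
    return sorted(hits, key=_hit_rank_key)


def top_hit(hits: Sequence[AlignmentHit], query_id: str) -> AlignmentHit:
    """Best hit for one query; deterministic under input permutation."""
    mine = [h for h in hits if h.query_id == query_id]
    if not mine:
        raise LookupError(f"no hits for query {query_id!r}")
    return min(mine, key=_hit_rank_key)


def lca_hit_set(
    hits: Sequence[AlignmentHit], query_id: str, evalue_factor: float = 10.0
) -> list[AlignmentHit]:
    """The hit set an LCA assignment is computed over.

    Top hit first, followed by every hit of the query whose evalue is
    within ``evalue_factor`` of the top hit's (<= top.evalue * factor;
    exact ties with the top always retained). Ordering is the deterministic
    ranking of :func:`rank_hits`.
    """
    if evalue_factor <= 0:
        raise ValueError(f"evalue_factor must be positive, got {evalue_factor}")
    ranked = rank_hits([h for h in hits if h.query_id == query_id])
    if not ranked:
        raise LookupError(f"no hits for query {query_id!r}")
    top = ranked[0]
    cutoff = max(top.evalue * evalue_factor, top.evalue)
    return [h for h in ranked if h.evalue <= cutoff]
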