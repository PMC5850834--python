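"""Seed-ortholog search.

Two routes find each query's best seed ortholog in the database:

* ``direct`` — score the query against every database protein and keep the
  best passing hit (the fast path, suitable for large query sets such as
  metagenome gene catalogs; production pipelines use DIAMOND here);
* ``coarse_then_fine`` — first pick the best-matching orthologous group
  (here scored as the max member bitscore, standing in for a profile-HMM
  match), then re-rank only that group's members (the more sensitive path;
  production pipelines use hmmscan + phmmer here).

The built-in scorer is Smith-Waterman local alignment (BLOSUM62, affine gaps
open 11 / extend 1) with the standard bit-score transform
``(lambda*S - ln K)/ln 2`` and E-value ``m*n*2^-bitscore`` over an effective
search space.  Parsers for HMMER3 ``--domtblout`` and BLAST/DIAMOND tabular
format-6 files let externally computed hits drop in as alternatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio.Align import PairwiseAligner, substitution_matrices

from .ogdb import DatabaseBundle, TaxonomyTree, VALID_RESIDUES, taxid_of

logger = logging.getLogger(__name__)

# Karlin-Altschul constants for the bitscore transform (ungapped approximation).
LAMBDA = 0.267
K = 0.041

DIRECT = "direct"
COARSE_THEN_FINE = "coarse_then_fine"
EXTERNAL = "external"


class SearchInputError(ValueError):
    pass


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    target_id: str  # OG id in the coarse phase, protein id otherwise
    bitscore: float
    evalue: float
    aln_span: tuple[int, int] = (1, 1)  # 1-based inclusive query coordinates

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise SearchInputError("negative E-value")
        if self.aln_span[0] > self.aln_span[1]:
            raise SearchInputError("alignment span start > end")


@dataclass(frozen=True)
class SeedOrtholog:
    query_id: str
    protein_id: str
    bitscore: float
    evalue: float
    mode: str


@dataclass
class SearchFilters:
    max_evalue: float = 1e-3
    min_bitscore: float = 20.0
    excluded_taxa: set[int] = field(default_factory=set)
    exclude_self: bool = False
    query_taxid: Optional[int] = None


_default_aligner: Optional[PairwiseAligner] = None


def _aligner() -> PairwiseAligner:
    global _default_aligner
    if _default_aligner is None:
        aln = PairwiseAligner()
        aln.mode = "local"
        aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aln.open_gap_score = -11.0
        aln.extend_gap_score = -1.0
        _default_aligner = aln
    return _default_aligner


def _check_sequence(seq: str, who: str) -> str:
    if not seq:
        raise SearchInputError(f"{who}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise SearchInputError(f"{who}: invalid residues {sorted(bad)}")
    return seq


def bitscore_from_raw(raw_score: float) -> float:
    return (LAMBDA * raw_score - math.log(K)) / math.log(2)


def evalue_from_bitscore(bitscore: float, m: int, n: int) -> float:
    # m*n*2^-bit in log space to dodge under/overflow
    log2_e = math.log2(max(m, 1)) + math.log2(max(n, 1)) - bitscore
    if log2_e > 300:
        return math.inf
    return 2.0 ** log2_e


def raw_score(a: str, b: str) -> float:
    """Smith-Waterman local alignment raw score (BLOSUM62, gaps -11/-1)."""
    a = _check_sequence(a, "sequence a")
    b = _check_sequence(b, "sequence b")
    return float(_aligner().score(a, b))


def align_score(a: str, b: str) -> tuple[float, float]:
    """Bit-score and pairwise E-value (search space = len(a)*len(b))."""
    s = raw_score(a, b)
    bit = bitscore_from_raw(s)
    return bit, evalue_from_bitscore(bit, len(a), len(b))


# ---------------------------------------------------------------------------
# Filtering and seed selection
# ---------------------------------------------------------------------------


def _target_taxid(target_id: str) -> Optional[int]:
    try:
        return taxid_of(target_id)
    except ValueError:
        return None  # OG ids / external targets without a taxid prefix


def apply_filters(
    hits: Iterable[SearchHit],
    filters: SearchFilters,
    taxonomy: Optional[TaxonomyTree] = None,
) -> list[SearchHit]:
    """Drop hits failing E-value/bitscore cutoffs, excluded taxa, or self-hits.

    ``excluded_taxa`` removes hits to any species at or below the listed
    taxa (taxonomy required for clade expansion; without one, exact taxid
    match only).  Filtering is monotone: stricter settings never add hits.
    """
    excluded: set[int] = set()
    if filters.excluded_taxa:
        if taxonomy is not None:
            for t in filters.excluded_taxa:
                excluded |= taxonomy.descendants(t)
        else:
            excluded = set(filters.excluded_taxa)
    out = []
    for hit in hits:
        if hit.evalue > filters.max_evalue or hit.bitscore < filters.min_bitscore:
            continue
        if excluded:
            taxid = _target_taxid(hit.target_id)
            if taxid is not None and taxid in excluded:
                continue
        if filters.exclude_self and hit.target_id == hit.query_id:
            continue
        out.append(hit)
    return out


def _hit_order(hit: SearchHit) -> tuple:
    # best first: high bitscore, then low evalue, then lexicographic target
    return (-hit.bitscore, hit.evalue, hit.target_id)


def best_hit(hits: Iterable[SearchHit]) -> Optional[SearchHit]:
    hits = list(hits)
    if not hits:
        return None
    return min(hits, key=_hit_order)


def best_hits_per_query(hits: Iterable[SearchHit]) -> dict[str, SearchHit]:
    by_query: dict[str, list[SearchHit]] = {}
    for hit in hits:
        by_query.setdefault(hit.query_id, []).append(hit)
    return {q: best_hit(hs) for q, hs in by_query.items()}  # type: ignore[misc]


# ---------------------------------------------------------------------------
# Search modes
# ---------------------------------------------------------------------------


def _query_items(queries: Mapping[str, str]) -> list[tuple[str, str]]:
    """Validated (id, sequence) pairs; invalid queries are skipped with a warning."""
    items = []
    for qid in sorted(queries):
        try:
            items.append((qid, _check_sequence(queries[qid], f"query {qid}")))
        except SearchInputError as exc:
            logger.warning("skipping query %s: %s", qid, exc)
    return items


def search_direct(
    queries: Mapping[str, str],
    db: DatabaseBundle,
    filters: Optional[SearchFilters] = None,
) -> dict[str, Optional[SeedOrtholog]]:
    """Best seed ortholog per query, scored against every database protein.

    E-values use effective search space = query length x total database
    residues.  Result is independent of query/database iteration order.
    """
    filters = filters or SearchFilters()
    db_residues = db.total_residues()
    results: dict[str, Optional[SeedOrtholog]] = {qid: None for qid in queries}
    targets = [
        (pid, rec.sequence) for pid, rec in sorted(db.proteins.items()) if rec.sequence
    ]
    for qid, qseq in _query_items(queries):
        hits = []
        for pid, tseq in targets:
            bit = bitscore_from_raw(_aligner().score(qseq, tseq))
            ev = evalue_from_bitscore(bit, len(qseq), db_residues)
            hits.append(SearchHit(qid, pid, bit, ev, (1, len(qseq))))
        best = best_hit(apply_filters(hits, filters, db.taxonomy))
        if best is not None:
            results[qid] = SeedOrtholog(qid, best.target_id, best.bitscore, best.evalue, DIRECT)
    return results


def search_coarse_then_fine(
    queries: Mapping[str, str],
    db: DatabaseBundle,
    filters: Optional[SearchFilters] = None,
    og_level: Optional[int] = None,
) -> dict[str, Optional[tuple[str, SeedOrtholog]]]:
    """Two-phase search: best orthologous group first, then its best member.

    The coarse phase scores a query against each OG as the max member
    bitscore (a desk-scale stand-in for a profile-HMM match); the fine phase
    re-ranks only the chosen group's members, with effective search space =
    query length x group residues.  ``og_level`` restricts the coarse phase
    to groups at one clade level (default: the root level).
    """
    filters = filters or SearchFilters()
    if og_level is None and db.clade_levels:
        og_level = db.clade_levels[0]
    ogs = [og for og in db.ogs if og_level is None or og.clade == og_level]
    results: dict[str, Optional[tuple[str, SeedOrtholog]]] = {qid: None for qid in queries}
    excluded: set[int] = set()
    for t in filters.excluded_taxa:
        excluded |= db.taxonomy.descendants(t)

    for qid, qseq in _query_items(queries):
        og_hits = []
        member_bits: dict[str, dict[str, float]] = {}
        for og in sorted(ogs, key=lambda o: o.og_id):
            bits = {}
            for pid in sorted(og.members):
                rec = db.proteins.get(pid)
                if rec is None or not rec.sequence:
                    continue
                if excluded and rec.taxid in excluded:
                    continue
                if filters.exclude_self and pid == qid:
                    continue
                bits[pid] = bitscore_from_raw(_aligner().score(qseq, rec.sequence))
            if not bits:
                continue  # empty (or fully excluded) group is never selected
            member_bits[og.og_id] = bits
            group_bit = max(bits.values())
            og_hits.append(SearchHit(qid, og.og_id, group_bit, 0.0, (1, len(qseq))))
        best_og_hit = best_hit(og_hits)
        if best_og_hit is None:
            logger.info("query %s: no orthologous group matched", qid)
            continue
        og = db.og(best_og_hit.target_id)
        og_residues = sum(
            len(db.proteins[pid].sequence or "") for pid in og.members if pid in db.proteins
        )
        fine_hits = [
            SearchHit(qid, pid, bit, evalue_from_bitscore(bit, len(qseq), og_residues), (1, len(qseq)))
            for pid, bit in member_bits[og.og_id].items()
        ]
        best = best_hit(apply_filters(fine_hits, filters, db.taxonomy))
        if best is None:
            logger.info("query %s: best group %s had no member passing filters", qid, og.og_id)
            continue
        results[qid] = (
            og.og_id,
            SeedOrtholog(qid, best.target_id, best.bitscore, best.evalue, COARSE_THEN_FINE),
        )
    return results


# ---------------------------------------------------------------------------
# External format parsers
# ---------------------------------------------------------------------------


class ParseError(ValueError):
    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = str(path), lineno


def parse_tabular6(path: str | Path) -> list[SearchHit]:
    """BLAST/DIAMOND tabular format-6 (12 standard columns).

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  Comment lines (#) are ignored.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(path, lineno, f"expected 12 columns, got {len(cols)}")
            try:
                hits.append(
                    SearchHit(
                        query_id=cols[0],
                        target_id=cols[1],
                        bitscore=float(cols[11]),
                        evalue=float(cols[10]),
                        aln_span=(int(cols[6]), int(cols[7])),
                    )
                )
            except (ValueError, SearchInputError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return hits


def parse_domtblout(path: str | Path) -> list[SearchHit]:
    """HMMER3 ``--domtblout`` per-domain table.

    One hit per domain row: query = column 4 (query name), target = column 1
    (target name), E-value = per-domain independent E-value (column 13),
    score = per-domain bit score (column 14), span = ali coordinates
    (columns 18-19).  Comment lines (#) are ignored.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 22:
                raise ParseError(path, lineno, f"expected >= 22 columns, got {len(cols)}")
            try:
                hits.append(
                    SearchHit(
                        query_id=cols[3],
                        target_id=cols[0],
                        bitscore=float(cols[13]),
                        evalue=float(cols[12]),
                        aln_span=(int(cols[17]), int(cols[18])),
                    )
                )
            except (ValueError, SearchInputError) as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return hits


def best_hits_per_target(hits: Iterable[SearchHit]) -> dict[tuple[str, str], SearchHit]:
    """Per (query, target): keep the minimum-E-value hit (domain collapsing)."""
    out: dict[tuple[str, str], SearchHit] = {}
    for hit in hits:
        key = (hit.query_id, hit.target_id)
        prev = out.get(key)
        if prev is None or (hit.evalue, -hit.bitscore) < (prev.evalue, -prev.bitscore):
            out[key] = hit
    return out


def write_seed_orthologs(
    seeds: Mapping[str, Optional[SeedOrtholog]], path: str | Path
) -> None:
    """Seed-ortholog TSV: query, seed, evalue, bitscore, mode ('-' if unmapped)."""
    with open(path, "w") as fh:
        fh.write("#query\tseed_ortholog\tevalue\tbitscore\tmode\n")
        for qid in sorted(seeds):
            seed = seeds[qid]
            if seed is None:
                fh.write(f"{qid}\t-\t-\t-\t-\n")
            else:
                fh.write(
                    f"{qid}\t{seed.protein_id}\t{seed.evalue:.3g}\t{seed.bitscore:.2f}\t{seed.mode}\n"
                )
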