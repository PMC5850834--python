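"""Annotation transfer: scope resolution, ortholog selection, functional transfer.

For each query the pipeline composes: seed-ortholog search -> gene-tree
orthology on the orthologous group at the query's taxonomic scope ->
policy-based donor selection -> transfer of GO terms (evidence-filtered,
ancestor-propagated), KEGG pathways, the group COG category, and a
predicted gene name.

Taxonomic scope: in ``auto`` mode each query is annotated from the
narrowest clade level that hosts a group containing its seed, so transfers
come from the taxonomically closest orthologs; a ``fixed`` scope (e.g. the
root level) disables that adjustment.

Donor set: the seed itself, the seed's fine-grained orthologs, and the
seed's in-paralogs.  The query is an outgroup to the seed's local
duplication cluster (it reached the seed from outside that species), so the
seed's same-species co-descendants are co-orthologs of the query rather
than paralogs of it; they are tagged ``one2many`` donors.  Orthologs keep
the relation type inferred for the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from . import search as search_mod
from . import treeortho
from .ogdb import DatabaseBundle, OrthologousGroup, ogs_for_protein
from .ontology import GoDag, propagate
from .search import SearchFilters, SeedOrtholog
from .treeortho import GeneTree, label_events, infer_orthologs

logger = logging.getLogger(__name__)

EVIDENCE_EXPERIMENTAL = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})

STATUS_ANNOTATED = "annotated"
STATUS_SEED_ONLY = "seed_only"
STATUS_UNMAPPED = "unmapped"


class ConfigurationError(ValueError):
    pass


@dataclass
class ScopeSetting:
    mode: str = "auto"  # auto | fixed
    fixed_clade: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in ("auto", "fixed"):
            raise ConfigurationError(f"unknown scope mode {self.mode!r}")
        if self.mode == "fixed" and self.fixed_clade is None:
            raise ConfigurationError("fixed scope requires fixed_clade")


@dataclass
class TransferPolicy:
    target_orthologs: str = "all"  # all | one2one
    go_evidence: str = "experimental"  # experimental | non_electronic | all
    excluded_taxa: set[int] = field(default_factory=set)
    max_evalue: float = 1e-3
    min_bitscore: float = 20.0

    def __post_init__(self) -> None:
        if self.target_orthologs not in ("all", "one2one"):
            raise ConfigurationError(f"unknown target_orthologs {self.target_orthologs!r}")
        if self.go_evidence not in ("experimental", "non_electronic", "all"):
            raise ConfigurationError(f"unknown go_evidence {self.go_evidence!r}")

    def evidence_passes(self, code: str) -> bool:
        if self.go_evidence == "experimental":
            return code in EVIDENCE_EXPERIMENTAL
        if self.go_evidence == "non_electronic":
            return code != "IEA"
        return True

    def search_filters(self, exclude_self: bool = True) -> SearchFilters:
        return SearchFilters(
            max_evalue=self.max_evalue,
            min_bitscore=self.min_bitscore,
            excluded_taxa=set(self.excluded_taxa),
            exclude_self=exclude_self,
        )


@dataclass
class AnnotationResult:
    query_id: str
    status: str
    seed: Optional[SeedOrtholog] = None
    scope_clade: Optional[int] = None
    og_id: Optional[str] = None
    orthologs_used: set[tuple[str, str]] = field(default_factory=set)
    go_terms: set[str] = field(default_factory=set)
    kegg_pathways: set[str] = field(default_factory=set)
    cog_category: str = ""
    predicted_gene_name: Optional[str] = None


def resolve_scope(seed: SeedOrtholog, db: DatabaseBundle, setting: ScopeSetting) -> Optional[int]:
    """Clade level whose orthologous group will donate annotations.

    ``fixed`` returns the configured level.  ``auto`` walks the seed
    species' lineage from the deepest available clade level upward and
    returns the narrowest level hosting a group that contains the seed
    protein (the taxonomically closest usable source), falling back to
    wider levels and ultimately the root level.
    """
    if not db.clade_levels:
        raise ConfigurationError("database declares no clade levels")
    if setting.mode == "fixed":
        if setting.fixed_clade not in db.clade_levels:
            raise ConfigurationError(
                f"fixed clade {setting.fixed_clade} is not a database clade level"
            )
        return setting.fixed_clade
    seed_taxid = db.proteins[seed.protein_id].taxid
    lineage = set(db.taxonomy.lineage(seed_taxid))
    eligible = [lvl for lvl in db.clade_levels if lvl in lineage]
    if not eligible:
        raise ConfigurationError(
            f"species {seed_taxid} of seed {seed.protein_id} lies under no clade level"
        )
    og_levels = {og.clade for og in ogs_for_protein(db, seed.protein_id)}
    for level in sorted(eligible, key=lambda t: -db.taxonomy.depth(t)):
        if level in og_levels:
            return level
    return None  # seed in no OG at any eligible level -> seed_only downstream


def select_orthologs(
    donors: Iterable[tuple[str, str]],
    scope: int,
    policy: TransferPolicy,
    db: DatabaseBundle,
) -> set[tuple[str, str]]:
    """Filter donor (protein, relation) pairs by scope, exclusions and policy.

    Keeps donors whose species lies within the scope clade, drops any under
    an excluded taxon, and under the ``one2one`` policy keeps only one2one
    orthologs (the seed entry always survives: it is the query's own best
    match).
    """
    taxonomy = db.taxonomy
    excluded: set[int] = set()
    for t in policy.excluded_taxa:
        excluded |= taxonomy.descendants(t)
    out = set()
    for pid, rel in donors:
        taxid = db.proteins[pid].taxid
        if not taxonomy.is_descendant(taxid, scope):
            continue
        if taxid in excluded:
            continue
        if policy.target_orthologs == "one2one" and rel not in (treeortho.ONE2ONE, treeortho.SEED):
            continue
        out.add((pid, rel))
    return out


def transfer_go(
    orthologs_used: Iterable[tuple[str, str]],
    og: OrthologousGroup,
    dag: GoDag,
    policy: TransferPolicy,
) -> set[str]:
    """Union of evidence-passing GO terms over the donors, ancestor-propagated.

    Terms unknown to the DAG are dropped with a warning.
    """
    terms: set[str] = set()
    for pid, _ in orthologs_used:
        ann = og.per_member_annotations.get(pid)
        if ann is None:
            continue
        for term, ev in ann.go_terms:
            if policy.evidence_passes(ev):
                terms.add(term)
    known = {t for t in terms if t in dag}
    for t in sorted(terms - known):
        logger.warning("dropping GO term %s unknown to the ontology", t)
    return propagate(dag, known)


def transfer_kegg(orthologs_used: Iterable[tuple[str, str]], og: OrthologousGroup) -> set[str]:
    """Union of KEGG pathways over donors; empty set when none annotated."""
    out: set[str] = set()
    for pid, _ in orthologs_used:
        ann = og.per_member_annotations.get(pid)
        if ann is not None:
            out |= ann.kegg_pathways
    return out


def transfer_cog(og: OrthologousGroup) -> str:
    """COG category letters of the matched group (group-level annotation)."""
    return og.annotation.cog_category


def normalize_gene_name(name: str) -> str:
    """Case-fold and strip trailing copy-number digits/separators (trpB2 -> TRPB)."""
    name = name.strip()
    while name and (name[-1].isdigit() or name[-1] in "._- "):
        name = name[:-1]
    return name.upper()


def predict_gene_name(
    orthologs_used: Iterable[tuple[str, str]],
    og: OrthologousGroup,
    db: DatabaseBundle,
    seed_protein: Optional[str] = None,
) -> Optional[str]:
    """Most frequent normalized donor gene name.

    Ties break toward the name carried by the donor taxonomically closest
    to the seed (deepest LCA with the seed's species), then lexicographic.
    """
    counts: dict[str, int] = {}
    best_depth: dict[str, int] = {}
    seed_taxid = db.proteins[seed_protein].taxid if seed_protein else None
    for pid, _ in sorted(orthologs_used):
        ann = og.per_member_annotations.get(pid)
        name = ann.gene_name if ann else None
        if not name and pid in db.proteins:
            name = db.proteins[pid].gene_name
        if not name:
            continue
        norm = normalize_gene_name(name)
        if not norm:
            continue
        counts[norm] = counts.get(norm, 0) + 1
        if seed_taxid is not None:
            from .ogdb import lca

            depth = db.taxonomy.depth(lca(db.taxonomy, {seed_taxid, db.proteins[pid].taxid}))
            best_depth[norm] = max(best_depth.get(norm, -1), depth)
    if not counts:
        return None
    return min(counts, key=lambda n: (-counts[n], -best_depth.get(n, -1), n))


def annotate_query(
    query_id: str,
    sequence: str,
    db: DatabaseBundle,
    dag: GoDag,
    setting: Optional[ScopeSetting] = None,
    policy: Optional[TransferPolicy] = None,
    mode: str = search_mod.DIRECT,
    seed: Optional[SeedOrtholog] = None,
) -> AnnotationResult:
    """Run the full pipeline for one query sequence.

    A precomputed ``seed`` (e.g. from parsed external search output) skips
    the built-in search.  Status is ``unmapped`` when no seed passes the
    filters, ``seed_only`` when a seed is found but no donor survives
    selection, else ``annotated``.
    """
    setting = setting or ScopeSetting()
    policy = policy or TransferPolicy()

    if seed is None:
        filters = policy.search_filters(exclude_self=True)
        if mode == search_mod.DIRECT:
            seed = search_direct_one(query_id, sequence, db, filters)
        elif mode == search_mod.COARSE_THEN_FINE:
            res = search_mod.search_coarse_then_fine({query_id: sequence}, db, filters)[query_id]
            seed = res[1] if res else None
        else:
            raise ConfigurationError(f"unknown search mode {mode!r}")
    if seed is None:
        return AnnotationResult(query_id=query_id, status=STATUS_UNMAPPED)

    scope = resolve_scope(seed, db, setting)
    if scope is None:
        return AnnotationResult(query_id=query_id, status=STATUS_SEED_ONLY, seed=seed)
    og = next(
        (o for o in ogs_for_protein(db, seed.protein_id) if o.clade == scope), None
    )
    if og is None:
        return AnnotationResult(
            query_id=query_id, status=STATUS_SEED_ONLY, seed=seed, scope_clade=scope
        )

    tree = GeneTree.from_newick(og.gene_tree)
    labeling = label_events(tree)
    assignment = infer_orthologs(tree, labeling, seed.protein_id)
    donors = {(seed.protein_id, treeortho.SEED)}
    donors |= assignment.orthologs
    donors |= {(pid, treeortho.ONE2MANY) for pid in assignment.inparalogs}
    used = select_orthologs(donors, scope, policy, db)

    if not used:
        return AnnotationResult(
            query_id=query_id,
            status=STATUS_SEED_ONLY,
            seed=seed,
            scope_clade=scope,
            og_id=og.og_id,
            cog_category=transfer_cog(og),
        )
    return AnnotationResult(
        query_id=query_id,
        status=STATUS_ANNOTATED,
        seed=seed,
        scope_clade=scope,
        og_id=og.og_id,
        orthologs_used=used,
        go_terms=transfer_go(used, og, dag, policy),
        kegg_pathways=transfer_kegg(used, og),
        cog_category=transfer_cog(og),
        predicted_gene_name=predict_gene_name(used, og, db, seed.protein_id),
    )


def search_direct_one(
    query_id: str, sequence: str, db: DatabaseBundle, filters: SearchFilters
) -> Optional[SeedOrtholog]:
    return search_mod.search_direct({query_id: sequence}, db, filters)[query_id]


def annotate_queries(
    queries: Mapping[str, str],
    db: DatabaseBundle,
    dag: GoDag,
    setting: Optional[ScopeSetting] = None,
    policy: Optional[TransferPolicy] = None,
    mode: str = search_mod.DIRECT,
    seeds: Optional[Mapping[str, Optional[SeedOrtholog]]] = None,
) -> list[AnnotationResult]:
    """Annotate a whole query set; order of results follows sorted query ids."""
    out = []
    for qid in sorted(queries):
        seed = seeds.get(qid) if seeds is not None else None
        out.append(
            annotate_query(qid, queries[qid], db, dag, setting, policy, mode, seed=seed)
        )
    return out


ANNOTATION_COLUMNS = [
    "query",
    "seed_ortholog",
    "seed_evalue",
    "seed_bitscore",
    "scope_clade",
    "og_id",
    "relations",
    "predicted_gene_name",
    "go_terms",
    "kegg_pathways",
    "cog_category",
    "status",
]


def write_annotations(results: Iterable[AnnotationResult], path) -> None:
    """One TSV row per query; header prefixed with '#'; '-' marks empty fields."""

    def dash(value) -> str:
        return str(value) if value not in (None, "", set()) else "-"

    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ANNOTATION_COLUMNS) + "\n")
        for r in results:
            rel_summary = (
                ",".join(f"{pid}|{rel}" for pid, rel in sorted(r.orthologs_used)) or "-"
            )
            row = [
                r.query_id,
                r.seed.protein_id if r.seed else "-",
                f"{r.seed.evalue:.3g}" if r.seed else "-",
                f"{r.seed.bitscore:.2f}" if r.seed else "-",
                dash(r.scope_clade),
                dash(r.og_id),
                rel_summary,
                dash(r.predicted_gene_name),
                ",".join(sorted(r.go_terms)) or "-",
                ",".join(sorted(r.kegg_pathways)) or "-",
                dash(r.cog_category),
                r.status,
            ]
            fh.write("\t".join(row) + "\n")


def read_annotations(path) -> list[dict]:
    """Parse an annotation TSV back into dicts (inverse of write_annotations)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            values = line.split("\t")
            row = dict(zip(ANNOTATION_COLUMNS, values))
            row["go_terms"] = set() if row["go_terms"] == "-" else set(row["go_terms"].split(","))
            row["kegg_pathways"] = (
                set() if row["kegg_pathways"] == "-" else set(row["kegg_pathways"].split(","))
            )
            rows.append(row)
    return rows
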