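"""Orthology database bundle: taxonomy, proteins, orthologous groups, annotations.

The database emulates the layout of precomputed orthology resources: a species
taxonomy, a protein catalogue, and gene families (orthologous groups, OGs)
defined at nested taxonomic levels, each carrying a gene tree and functional
annotations (GO terms with evidence codes, KEGG pathways, COG categories,
gene names).

All on-disk formats are plain text: 3-column TSV taxonomy (child, parent,
name; root is self-parented), FASTA protein sequences, TSV OG membership,
one-newick-per-line gene trees, and TSV annotation tables.  A ``manifest.json``
ties a bundle together.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}

GO_TERM_RE = re.compile(r"^GO:\d{7}$")

#: Controlled vocabulary of GO evidence codes understood by the bundle.
EVIDENCE_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP", "ISS", "TAS", "IC", "IEA", "ND"}
)


class DatabaseError(Exception):
    """Base class for database structural/integrity problems."""


class TaxonomyError(DatabaseError):
    """Structural problem in the taxonomy (cycle, multiple roots, unknown taxid)."""


class IntegrityError(DatabaseError):
    """Cross-file inconsistency in a database bundle.

    Carries the full list of problems found so that a single load reports
    every defect at once.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "%d integrity problem(s):\n  %s" % (len(self.problems), "\n  ".join(self.problems))
        )


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTree:
    """Rooted species taxonomy over integer taxon ids.

    ``parent`` maps every non-root node to its parent; the root is not a key.
    """

    root: int
    parent: dict[int, int]
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._children: dict[int, list[int]] = {}
        for child, par in self.parent.items():
            self._children.setdefault(par, []).append(child)
        for kids in self._children.values():
            kids.sort()

    @property
    def nodes(self) -> set[int]:
        return {self.root} | set(self.parent)

    def children(self, taxid: int) -> list[int]:
        return self._children.get(taxid, [])

    def is_leaf(self, taxid: int) -> bool:
        return taxid not in self._children

    def leaves(self) -> list[int]:
        return sorted(t for t in self.nodes if self.is_leaf(t))

    def lineage(self, taxid: int) -> list[int]:
        """Root-to-node path, inclusive at both ends."""
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid: {taxid}")
        path = [taxid]
        while taxid != self.root:
            taxid = self.parent[taxid]
            path.append(taxid)
        path.reverse()
        return path

    def depth(self, taxid: int) -> int:
        return len(self.lineage(taxid)) - 1

    def is_descendant(self, taxid: int, ancestor: int) -> bool:
        """True iff ``taxid`` is ``ancestor`` or lies below it."""
        return ancestor in self.lineage(taxid)

    def descendants(self, taxid: int) -> set[int]:
        """All nodes at or below ``taxid`` (inclusive)."""
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid: {taxid}")
        out = {taxid}
        stack = [taxid]
        while stack:
            for child in self.children(stack.pop()):
                out.add(child)
                stack.append(child)
        return out


def lca(tree: TaxonomyTree, taxids: Iterable[int]) -> int:
    """Lowest common ancestor of a non-empty set of taxa."""
    taxids = list(taxids)
    if not taxids:
        raise ValueError("lca of an empty taxon set is undefined")
    common: Optional[list[int]] = None
    for t in taxids:
        lin = tree.lineage(t)
        if common is None:
            common = lin
        else:
            limit = min(len(common), len(lin))
            i = 0
            while i < limit and common[i] == lin[i]:
                i += 1
            common = common[:i]
    assert common, "lineages always share the root"
    return common[-1]


def load_taxonomy(path: str | Path) -> TaxonomyTree:
    """Read a 3-column TSV taxonomy (child, parent, name).

    The root row is self-parented.  Row order is irrelevant.  Raises
    :class:`TaxonomyError` on cycles or multiple roots.
    """
    parent: dict[int, int] = {}
    names: dict[int, str] = {}
    roots: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child_s, parent_s, *rest = line.split("\t")
            child, par = int(child_s), int(parent_s)
            if rest and rest[0]:
                names[child] = rest[0]
            if child == par:
                roots.append(child)
            else:
                if child in parent and parent[child] != par:
                    raise TaxonomyError(f"taxid {child} has multiple parents")
                parent[child] = par
    if len(roots) != 1:
        raise TaxonomyError(f"expected exactly one self-parented root row, found {len(roots)}")
    root = roots[0]
    tree = TaxonomyTree(root=root, parent=parent, names=names)
    # validate: every lineage terminates at root (detects cycles / orphans)
    for node in tree.nodes:
        seen: set[int] = set()
        cur = node
        while cur != root:
            if cur in seen:
                raise TaxonomyError(f"cycle detected in taxonomy at taxid {cur}")
            seen.add(cur)
            if cur not in parent:
                raise TaxonomyError(f"taxid {cur} has no path to the root")
            cur = parent[cur]
    return tree


def write_taxonomy(tree: TaxonomyTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for node in sorted(tree.nodes):
            par = node if node == tree.root else tree.parent[node]
            fh.write(f"{node}\t{par}\t{tree.names.get(node, '')}\n")


# ---------------------------------------------------------------------------
# Proteins, annotations, orthologous groups
# ---------------------------------------------------------------------------


def taxid_of(protein_id: str) -> int:
    """Taxon id encoded as the ``<taxid>.`` prefix of a protein id."""
    prefix = protein_id.split(".", 1)[0]
    try:
        return int(prefix)
    except ValueError as exc:
        raise ValueError(f"protein id {protein_id!r} does not start with '<taxid>.'") from exc


@dataclass
class ProteinRecord:
    protein_id: str
    taxid: int
    sequence: Optional[str] = None
    gene_name: Optional[str] = None


@dataclass
class FunctionalAnnotation:
    """Per-protein (or per-OG) functional descriptors."""

    go_terms: set[tuple[str, str]] = field(default_factory=set)  # (term, evidence)
    kegg_pathways: set[str] = field(default_factory=set)
    cog_category: str = ""
    gene_name: Optional[str] = None

    def validate(self) -> list[str]:
        problems = []
        for term, ev in self.go_terms:
            if not GO_TERM_RE.match(term):
                problems.append(f"malformed GO id {term!r}")
            if ev not in EVIDENCE_CODES:
                problems.append(f"unknown evidence code {ev!r} on {term}")
        return problems


@dataclass
class OrthologousGroup:
    og_id: str
    clade: int
    members: set[str]
    gene_tree: str  # newick over members
    annotation: FunctionalAnnotation = field(default_factory=FunctionalAnnotation)
    per_member_annotations: dict[str, FunctionalAnnotation] = field(default_factory=dict)


@dataclass
class DatabaseBundle:
    taxonomy: TaxonomyTree
    proteins: dict[str, ProteinRecord]
    ogs: list[OrthologousGroup]
    clade_levels: list[int]  # root level first, then increasingly narrow

    def __post_init__(self) -> None:
        self._og_by_id = {og.og_id: og for og in self.ogs}
        self._ogs_by_protein: dict[str, list[OrthologousGroup]] = {}
        for og in self.ogs:
            for member in og.members:
                self._ogs_by_protein.setdefault(member, []).append(og)

    def og(self, og_id: str) -> OrthologousGroup:
        return self._og_by_id[og_id]

    def total_residues(self) -> int:
        return sum(len(p.sequence) for p in self.proteins.values() if p.sequence)


def ogs_for_protein(db: DatabaseBundle, protein_id: str) -> list[OrthologousGroup]:
    """All OGs containing a protein, narrowest clade first (deepest lineage)."""
    if protein_id not in db.proteins:
        raise KeyError(f"unknown protein: {protein_id}")
    ogs = db._ogs_by_protein.get(protein_id, [])
    return sorted(ogs, key=lambda og: (-db.taxonomy.depth(og.clade), og.og_id))


def derive_clade_levels(taxonomy: TaxonomyTree, ogs: Iterable[OrthologousGroup]) -> list[int]:
    levels = {og.clade for og in ogs}
    return sorted(levels, key=lambda t: (taxonomy.depth(t), t))


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id; accepts any line wrapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(sequences.items())
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.json"

_DEFAULT_FILES = {
    "taxonomy": "taxonomy.tsv",
    "proteins": "proteins.fasta",
    "og_membership": "og_membership.tsv",
    "gene_trees": "gene_trees.tsv",
    "go": "go_annotations.tsv",
    "kegg": "kegg_annotations.tsv",
    "cog": "cog_annotations.tsv",
    "gene_names": "gene_names.tsv",
}


def write_database(db: DatabaseBundle, outdir: str | Path, extra_manifest: Optional[dict] = None) -> Path:
    """Write a bundle to ``outdir`` and return the manifest path.

    Output is byte-deterministic for a given bundle (all tables sorted).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = dict(_DEFAULT_FILES)

    write_taxonomy(db.taxonomy, outdir / files["taxonomy"])
    write_fasta(
        {p.protein_id: p.sequence for p in db.proteins.values() if p.sequence},
        outdir / files["proteins"],
    )
    with open(outdir / files["og_membership"], "w") as fh:
        for og in sorted(db.ogs, key=lambda o: o.og_id):
            for member in sorted(og.members):
                fh.write(f"{og.og_id}\t{og.clade}\t{member}\n")
    with open(outdir / files["gene_trees"], "w") as fh:
        for og in sorted(db.ogs, key=lambda o: o.og_id):
            fh.write(f"{og.og_id}\t{og.gene_tree}\n")
    with open(outdir / files["go"], "w") as fh:
        rows = set()
        for og in db.ogs:
            for pid, ann in og.per_member_annotations.items():
                for term, ev in ann.go_terms:
                    rows.add((pid, term, ev))
        for pid, term, ev in sorted(rows):
            fh.write(f"{pid}\t{term}\t{ev}\n")
    with open(outdir / files["kegg"], "w") as fh:
        rows = set()
        for og in db.ogs:
            for pid, ann in og.per_member_annotations.items():
                for pw in ann.kegg_pathways:
                    rows.add((pid, pw))
        for pid, pw in sorted(rows):
            fh.write(f"{pid}\t{pw}\n")
    with open(outdir / files["cog"], "w") as fh:
        for og in sorted(db.ogs, key=lambda o: o.og_id):
            if og.annotation.cog_category:
                fh.write(f"{og.og_id}\t{og.annotation.cog_category}\n")
    with open(outdir / files["gene_names"], "w") as fh:
        rows = set()
        for p in db.proteins.values():
            if p.gene_name:
                rows.add((p.protein_id, p.gene_name))
        for pid, name in sorted(rows):
            fh.write(f"{pid}\t{name}\n")

    manifest = {"format": "ogmap-bundle/1", "files": files}
    if extra_manifest:
        manifest.update(extra_manifest)
    manifest_path = outdir / MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path


def load_database(path: str | Path) -> DatabaseBundle:
    """Load a bundle from a manifest file or a directory containing one.

    All validation failures are collected and raised together as
    :class:`IntegrityError`.
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME if path.is_dir() else path
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    files = {k: base / v for k, v in manifest["files"].items()}

    taxonomy = load_taxonomy(files["taxonomy"])
    sequences = read_fasta(files["proteins"]) if files["proteins"].exists() else {}

    problems: list[str] = []

    go_by_protein: dict[str, set[tuple[str, str]]] = {}
    if files["go"].exists():
        for line in open(files["go"]):
            if not line.strip():
                continue
            pid, term, ev = line.rstrip("\n").split("\t")
            go_by_protein.setdefault(pid, set()).add((term, ev))
    kegg_by_protein: dict[str, set[str]] = {}
    if files["kegg"].exists():
        for line in open(files["kegg"]):
            if not line.strip():
                continue
            pid, pw = line.rstrip("\n").split("\t")
            kegg_by_protein.setdefault(pid, set()).add(pw)
    cog_by_og: dict[str, str] = {}
    if files["cog"].exists():
        for line in open(files["cog"]):
            if not line.strip():
                continue
            og_id, cat = line.rstrip("\n").split("\t")
            cog_by_og[og_id] = cat
    name_by_protein: dict[str, str] = {}
    if files["gene_names"].exists():
        for line in open(files["gene_names"]):
            if not line.strip():
                continue
            pid, name = line.rstrip("\n").split("\t")
            name_by_protein[pid] = name

    members_by_og: dict[str, tuple[int, set[str]]] = {}
    if files["og_membership"].exists():
        for line in open(files["og_membership"]):
            if not line.strip():
                continue
            og_id, clade_s, pid = line.rstrip("\n").split("\t")
            clade = int(clade_s)
            if og_id in members_by_og:
                prev_clade, members = members_by_og[og_id]
                if prev_clade != clade:
                    problems.append(f"OG {og_id}: inconsistent clade ({prev_clade} vs {clade})")
                members.add(pid)
            else:
                members_by_og[og_id] = (clade, {pid})
    trees_by_og: dict[str, str] = {}
    if files["gene_trees"].exists():
        for line in open(files["gene_trees"]):
            if not line.strip():
                continue
            og_id, newick = line.rstrip("\n").split("\t", 1)
            trees_by_og[og_id] = newick

    # assemble the protein catalogue from every table mentioning a protein
    protein_ids = set(sequences) | set(go_by_protein) | set(kegg_by_protein) | set(name_by_protein)
    for _, (_, members) in members_by_og.items():
        protein_ids |= members
    proteins: dict[str, ProteinRecord] = {}
    for pid in sorted(protein_ids):
        try:
            taxid = taxid_of(pid)
        except ValueError as exc:
            problems.append(str(exc))
            continue
        if taxid not in taxonomy.nodes:
            problems.append(f"protein {pid}: taxid {taxid} not in taxonomy")
            continue
        seq = sequences.get(pid)
        if seq and not set(seq) <= VALID_RESIDUES:
            bad = sorted(set(seq) - VALID_RESIDUES)
            problems.append(f"protein {pid}: invalid residues {bad}")
        proteins[pid] = ProteinRecord(pid, taxid, seq, name_by_protein.get(pid))

    # lazy import avoids a cycle (treeortho uses ogdb.taxid_of)
    from . import treeortho

    ogs: list[OrthologousGroup] = []
    per_level_membership: dict[tuple[str, int], str] = {}
    for og_id in sorted(members_by_og):
        clade, members = members_by_og[og_id]
        if clade not in taxonomy.nodes:
            problems.append(f"OG {og_id}: clade {clade} not in taxonomy")
            continue
        for member in sorted(members):
            if member not in proteins:
                problems.append(f"OG {og_id}: member {member} absent from protein table")
                continue
            if not taxonomy.is_descendant(proteins[member].taxid, clade):
                problems.append(f"OG {og_id}: member {member} outside clade {clade}")
            key = (member, clade)
            if key in per_level_membership:
                problems.append(
                    f"protein {member} in two OGs at level {clade}: "
                    f"{per_level_membership[key]} and {og_id}"
                )
            else:
                per_level_membership[key] = og_id
        newick = trees_by_og.get(og_id)
        if newick is None:
            problems.append(f"OG {og_id}: no gene tree")
            newick = ""
        else:
            try:
                leaves = set(treeortho.GeneTree.from_newick(newick).leaf_names())
            except Exception as exc:  # noqa: BLE001 - reported as integrity problem
                problems.append(f"OG {og_id}: unparseable gene tree ({exc})")
                leaves = set()
            if leaves and leaves != members:
                problems.append(
                    f"OG {og_id}: gene-tree leaf set differs from member set "
                    f"(only-in-tree={sorted(leaves - members)}, "
                    f"only-in-table={sorted(members - leaves)})"
                )
        per_member = {}
        for member in members:
            per_member[member] = FunctionalAnnotation(
                go_terms=set(go_by_protein.get(member, set())),
                kegg_pathways=set(kegg_by_protein.get(member, set())),
                gene_name=name_by_protein.get(member),
            )
            per_member[member].cog_category = cog_by_og.get(og_id, "")
        group_go = set().union(*(a.go_terms for a in per_member.values())) if per_member else set()
        group_kegg = (
            set().union(*(a.kegg_pathways for a in per_member.values())) if per_member else set()
        )
        ogs.append(
            OrthologousGroup(
                og_id=og_id,
                clade=clade,
                members=set(members),
                gene_tree=newick,
                annotation=FunctionalAnnotation(
                    go_terms=group_go,
                    kegg_pathways=group_kegg,
                    cog_category=cog_by_og.get(og_id, ""),
                ),
                per_member_annotations=per_member,
            )
        )

    if problems:
        raise IntegrityError(problems)

    return DatabaseBundle(
        taxonomy=taxonomy,
        proteins=proteins,
        ogs=ogs,
        clade_levels=derive_clade_levels(taxonomy, ogs),
    )
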