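"""Synthetic orthology-database generator with full ground truth.

Everything the annotation pipeline consumes is simulated here, internally
consistent and fully seeded: a species taxonomy, gene families evolved along
it by birth (duplication) and death (loss) events, protein sequences mutated
along the gene trees, a random GO DAG, per-protein annotations with evidence
codes, taxon constraints that hold by construction, and metagenomic samples
with gold functional profiles.

The recorded ground truth (true event label per gene-tree node, true
ortholog pairs with relation types, true term sets, gold profiles) is what
the test-suite oracles and the evaluation framework compare against.

Default parameters describe a small but structured clade: 20 species,
40 gene families, one duplication per ~10 species-tree branches, occasional
gene loss, 150-residue proteins at ~5% divergence per branch, and a 60-term
ontology annotated preferentially in a minority of "model organism" species.
"""

from __future__ import annotations

import dataclasses
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import ogdb, ontology
from .ogdb import (
    DatabaseBundle,
    FunctionalAnnotation,
    OrthologousGroup,
    ProteinRecord,
    TaxonomyTree,
)
from .ontology import GoDag, TaxonConstraint
from .treeortho import DUPLICATION, SPECIATION, TreeNode

AA = "ACDEFGHIKLMNPQRSTVWY"
COG_CATEGORIES = "JKLDVTMNUOCGEHFIPQ"


class SimulationError(RuntimeError):
    pass


@dataclass
class SimConfig:
    n_species: int = 20
    branching: tuple[int, int] = (2, 3)  # children per internal taxonomy node
    n_families: int = 40
    duplication_rate: float = 0.1  # per gene lineage per species-tree branch
    loss_rate: float = 0.05
    seq_length: int = 150
    subst_prob: float = 0.05  # per site per branch
    n_go_terms: int = 60
    dag_density: float = 0.3  # probability of a second parent per term
    root_terms_per_family: int = 3
    annotation_gain: float = 0.05  # per gene-tree branch
    annotation_loss: float = 0.05  # per term per gene-tree branch
    model_organism_fraction: float = 0.3
    p_experimental_model: float = 0.8  # evidence is experimental, model organisms
    p_experimental_other: float = 0.1
    unnamed_fraction: float = 0.1  # proteins without a gene name
    n_taxon_constraints: int = 5
    n_sample_species: int = 5  # metagenome sample richness
    reads_per_gene: float = 20.0  # expected reads at unit species abundance
    seed: int = 0
    max_redraws: int = 200

    def validate(self) -> None:
        for name in (
            "duplication_rate",
            "loss_rate",
            "subst_prob",
            "dag_density",
            "annotation_gain",
            "annotation_loss",
            "model_organism_fraction",
            "p_experimental_model",
            "p_experimental_other",
            "unnamed_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if self.subst_prob > 0 and len(AA) < 2:
            raise ValueError("substitution impossible with a 1-letter alphabet")


@dataclass
class FamilyTruth:
    family_id: str
    root: TreeNode  # every internal node carries .event in {S, D}
    newick: str  # with event labels as internal node names
    pairs: set[tuple[str, str, str]]  # (a, b, relation a->b), both directions stored


@dataclass
class GroundTruth:
    families: dict[str, FamilyTruth] = field(default_factory=dict)
    true_terms: dict[str, set[str]] = field(default_factory=dict)  # ancestor-closed
    raw_terms: dict[str, set[str]] = field(default_factory=dict)  # as annotated, pre-closure
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)
    model_organisms: set[int] = field(default_factory=set)


@dataclass
class SimResult:
    config: SimConfig
    taxonomy: TaxonomyTree
    db: DatabaseBundle
    dag: GoDag
    part_of_edges: set[tuple[str, str]]
    constraints: list[TaxonConstraint]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


def simulate_taxonomy(config: SimConfig, rng: np.random.Generator) -> TaxonomyTree:
    """Random rooted species tree with ``n_species`` leaves.

    Internal nodes are real taxa too (they become candidate clade levels).
    Node ids are assigned in creation (preorder) order; root id is 1.
    """
    config.validate()
    counter = [0]

    def next_id() -> int:
        counter[0] += 1
        return counter[0]

    parent: dict[int, int] = {}
    names: dict[int, str] = {}
    root = next_id()
    names[root] = "root"

    def split(node: int, n_leaves: int) -> None:
        if n_leaves == 1:
            names[node] = f"sp{node}"
            return
        lo, hi = config.branching
        k = int(rng.integers(lo, hi + 1))
        k = min(k, n_leaves)
        # distribute leaves over k children, each >= 1
        cuts = sorted(rng.choice(np.arange(1, n_leaves), size=k - 1, replace=False)) if k > 1 else []
        sizes = np.diff([0, *cuts, n_leaves])
        names.setdefault(node, f"clade{node}")
        for size in sizes:
            child = next_id()
            parent[child] = node
            split(child, int(size))

    split(root, config.n_species)
    names[root] = "root"
    return TaxonomyTree(root=root, parent=parent, names=names)


def choose_clade_levels(taxonomy: TaxonomyTree, max_levels: int = 3) -> list[int]:
    """Root plus a nested chain of the largest sub-clades (>= 3 species each)."""
    levels = [taxonomy.root]
    current = taxonomy.root
    while len(levels) < max_levels:
        internal_kids = [c for c in taxonomy.children(current) if not taxonomy.is_leaf(c)]
        candidates = [
            c
            for c in internal_kids
            if sum(1 for d in taxonomy.descendants(c) if taxonomy.is_leaf(d)) >= 3
        ]
        if not candidates:
            break
        current = max(
            candidates,
            key=lambda c: (sum(1 for d in taxonomy.descendants(c) if taxonomy.is_leaf(d)), -c),
        )
        levels.append(current)
    return levels


# ---------------------------------------------------------------------------
# Gene families
# ---------------------------------------------------------------------------


def simulate_family(
    config: SimConfig,
    taxonomy: TaxonomyTree,
    family_id: str,
    rng: np.random.Generator,
) -> FamilyTruth:
    """Evolve one gene family along the species tree.

    Each gene lineage traversing a species-tree branch is lost with
    ``loss_rate`` and duplicated with ``duplication_rate`` (duplications can
    cascade); surviving lineages speciate at internal species-tree nodes.
    Families with fewer than two surviving genes in fewer than two species
    are redrawn; generation fails loudly after ``max_redraws`` attempts.
    """
    gene_counter = [0]

    def new_leaf(taxid: int) -> TreeNode:
        gene_counter[0] += 1
        return TreeNode(name=f"{taxid}.{family_id}g{gene_counter[0]}")

    def along_branch(sp: int) -> Optional[TreeNode]:
        if rng.random() < config.loss_rate:
            return None
        if rng.random() < config.duplication_rate:
            a = along_branch(sp)
            b = along_branch(sp)
            if a is not None and b is not None:
                node = TreeNode(event=DUPLICATION)
                node.add(a)
                node.add(b)
                return node
            return a if a is not None else b
        return at_node(sp)

    def at_node(sp: int) -> Optional[TreeNode]:
        if taxonomy.is_leaf(sp):
            return new_leaf(sp)
        kids = [along_branch(c) for c in taxonomy.children(sp)]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        node = TreeNode(event=SPECIATION)
        for k in kids:
            node.add(k)
        return node

    for _ in range(config.max_redraws):
        gene_counter[0] = 0
        root = at_node(taxonomy.root)
        if root is None or root.is_leaf:
            continue
        leaves = root.leaves()
        species = {ogdb.taxid_of(l.name) for l in leaves}
        if len(leaves) >= 2 and len(species) >= 2:
            return FamilyTruth(
                family_id=family_id,
                root=root,
                newick=_newick_with_events(root),
                pairs=_true_pairs(root),
            )
    raise SimulationError(
        f"family {family_id}: no surviving multi-species family after "
        f"{config.max_redraws} redraws (rates too extreme?)"
    )


def _newick_with_events(root: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name or ""
        return "(" + ",".join(fmt(c) for c in node.children) + ")" + (node.event or "")

    return fmt(root) + ";"


def _true_pairs(root: TreeNode) -> set[tuple[str, str, str]]:
    """Ortholog pairs with relation types from the recorded event labels.

    Independent of the inference module: uses the simulator's own labels and
    naive leaf enumeration.  Both directions are stored: (a, b, rel) means
    b is an ortholog of a with relation rel (a's copies : b's copies).
    """
    leaves_below: dict[int, list[TreeNode]] = {}
    parent_of: dict[int, Optional[TreeNode]] = {}
    order = list(root.postorder())
    for node in order:
        if node.is_leaf:
            leaves_below[id(node)] = [node]
        else:
            acc: list[TreeNode] = []
            for c in node.children:
                acc.extend(leaves_below[id(c)])
            leaves_below[id(node)] = acc
        for c in node.children:
            parent_of[id(c)] = node

    def ancestors(node: TreeNode) -> list[TreeNode]:
        out = []
        cur: Optional[TreeNode] = node
        while cur is not None:
            out.append(cur)
            cur = parent_of.get(id(cur))
        return out

    def count(node: TreeNode, taxid: int) -> int:
        return sum(1 for l in leaves_below[id(node)] if ogdb.taxid_of(l.name) == taxid)

    pairs: set[tuple[str, str, str]] = set()
    leaves = leaves_below[id(root)]
    anc = {id(l): ancestors(l) for l in leaves}
    for i, a in enumerate(leaves):
        sa = ogdb.taxid_of(a.name)
        a_anc_ids = {id(n): k for k, n in enumerate(anc[id(a)])}
        for b in leaves[i + 1 :]:
            sb = ogdb.taxid_of(b.name)
            if sa == sb:
                continue
            lca_node = None
            a_side = b_side = None
            prev = b
            for n in anc[id(b)]:
                if id(n) in a_anc_ids:
                    lca_node = n
                    b_side = prev
                    k = a_anc_ids[id(n)]
                    a_side = anc[id(a)][k - 1] if k > 0 else a
                    break
                prev = n
            assert lca_node is not None
            if lca_node.event != SPECIATION:
                continue
            m = count(a_side, sa)
            n_ = count(b_side, sb)
            rel_ab = _rel(m, n_)
            rel_ba = _rel(n_, m)
            pairs.add((a.name, b.name, rel_ab))
            pairs.add((b.name, a.name, rel_ba))
    return pairs


def _rel(m: int, n: int) -> str:
    if m == 1 and n == 1:
        return "one2one"
    if m == 1:
        return "one2many"
    if n == 1:
        return "many2one"
    return "many2many"


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------


def simulate_sequences(
    root: TreeNode, config: SimConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Evolve sequences along a gene tree: uniform random root, per-site
    substitution with ``subst_prob`` on every branch."""
    aa = np.array(list(AA))
    root_seq = rng.choice(aa, size=config.seq_length)

    out: dict[str, str] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        if node.is_leaf:
            out[node.name] = "".join(seq)
            return
        for child in node.children:
            mutated = seq.copy()
            mask = rng.random(len(seq)) < config.subst_prob
            if mask.any():
                # substitute to a uniformly drawn *different* residue
                for idx in np.nonzero(mask)[0]:
                    choices = [c for c in AA if c != mutated[idx]]
                    mutated[idx] = choices[int(rng.integers(len(choices)))]
            walk(child, mutated)

    walk(root, root_seq)
    return out


# ---------------------------------------------------------------------------
# Ontology and annotations
# ---------------------------------------------------------------------------


def simulate_go_dag(
    config: SimConfig, rng: np.random.Generator
) -> tuple[GoDag, set[tuple[str, str]]]:
    """Random rooted DAG of GO-style terms (single namespace).

    Term 1 is the root; each later term gets one uniform parent among its
    predecessors, plus a second parent with probability ``dag_density``.
    Roughly 10% of edges are ``part_of``; two terms receive alternate ids.
    """
    n = config.n_go_terms
    terms = [f"GO:{i:07d}" for i in range(1, n + 1)]
    parents: dict[str, set[str]] = {terms[0]: set()}
    part_of: set[tuple[str, str]] = set()
    for i in range(1, n):
        p = int(rng.integers(0, i))
        ps = {terms[p]}
        if i >= 2 and rng.random() < config.dag_density:
            q = int(rng.integers(0, i))
            ps.add(terms[q])
        parents[terms[i]] = ps
        for parent in ps:
            if rng.random() < 0.1:
                part_of.add((terms[i], parent))
    alt_ids = {}
    if n >= 4:
        alt_ids[f"GO:{9000001:07d}"] = terms[2]
        alt_ids[f"GO:{9000002:07d}"] = terms[3]
    namespaces = {t: "biological_process" for t in terms}
    names = {t: f"synthetic term {i+1}" for i, t in enumerate(terms)}
    return GoDag(parents, namespaces, alt_ids, set(), names), part_of


def simulate_annotations(
    families: dict[str, FamilyTruth],
    dag: GoDag,
    taxonomy: TaxonomyTree,
    config: SimConfig,
    rng: np.random.Generator,
) -> GroundTruth:
    """Evolve GO term sets along each gene tree and assign evidence codes.

    The family root draws ``root_terms_per_family`` terms; along each branch
    every term is lost with ``annotation_loss`` and a new random term gained
    with ``annotation_gain``.  Leaf term sets are recorded raw and
    ancestor-closed.  Evidence per (protein, term) is experimental with a
    species-dependent probability (model organisms are curated much more
    often); everything else is electronically inferred (IEA).
    """
    experimental = sorted(ogdb.EVIDENCE_CODES & {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})
    non_root_terms = sorted(dag.terms - dag.roots())
    leaves_taxa = taxonomy.leaves()
    n_model = max(1, int(round(config.model_organism_fraction * len(leaves_taxa))))
    model_organisms = set(
        int(t) for t in rng.choice(np.array(leaves_taxa), size=n_model, replace=False)
    )

    truth = GroundTruth(model_organisms=model_organisms)
    for fam_id in sorted(families):
        fam = families[fam_id]
        k = min(config.root_terms_per_family, len(non_root_terms))
        root_terms = {
            non_root_terms[int(i)]
            for i in rng.choice(len(non_root_terms), size=k, replace=False)
        }

        def walk(node: TreeNode, terms: set[str]) -> None:
            if node.is_leaf:
                raw = set(terms)
                truth.raw_terms[node.name] = raw
                truth.true_terms[node.name] = ontology.propagate(dag, raw)
                taxid = ogdb.taxid_of(node.name)
                p_exp = (
                    config.p_experimental_model
                    if taxid in model_organisms
                    else config.p_experimental_other
                )
                for term in sorted(raw):
                    if rng.random() < p_exp:
                        code = experimental[int(rng.integers(len(experimental)))]
                    else:
                        code = "IEA"
                    truth.evidence[(node.name, term)] = code
                return
            for child in node.children:
                child_terms = {t for t in sorted(terms) if rng.random() >= config.annotation_loss}
                if rng.random() < config.annotation_gain:
                    child_terms.add(non_root_terms[int(rng.integers(len(non_root_terms)))])
                if not child_terms:  # keep every gene minimally annotated
                    child_terms = {non_root_terms[int(rng.integers(len(non_root_terms)))]}
                walk(child, child_terms)

        walk(fam.root, root_terms)
        truth.families[fam_id] = fam
    return truth


def derive_taxon_constraints(
    truth: GroundTruth,
    dag: GoDag,
    taxonomy: TaxonomyTree,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[TaxonConstraint]:
    """Constraints consistent with the generated annotations by construction.

    For candidate terms, the set of species carrying the term (or any of its
    descendants) is computed from the true closed sets; a ``never_in_taxon``
    constraint is emitted for a clade containing no carrier, and an
    ``only_in_taxon`` constraint for the carriers' LCA when it is a proper
    sub-clade.
    """
    carriers: dict[str, set[int]] = {t: set() for t in dag.terms}
    for pid, terms in truth.true_terms.items():
        taxid = ogdb.taxid_of(pid)
        for t in terms:
            carriers[t].add(taxid)

    internal = sorted(t for t in taxonomy.nodes if not taxonomy.is_leaf(t) and t != taxonomy.root)
    out: list[TaxonConstraint] = []
    candidates = sorted(t for t in dag.terms if carriers[t])
    rng.shuffle(candidates)  # noqa: NPY002 - Generator.shuffle is deterministic
    for term in candidates:
        if len(out) >= config.n_taxon_constraints:
            break
        # species carrying term itself or any descendant term
        carrying = set(carriers[term])
        for d in dag.descendants(term):
            carrying |= carriers[d]
        if not carrying:
            continue
        free_clades = [
            c
            for c in internal
            if not ({s for s in taxonomy.descendants(c) if taxonomy.is_leaf(s)} & carrying)
        ]
        if free_clades:
            out.append(TaxonConstraint(term, ontology.NEVER_IN, free_clades[0]))
            continue
        anc = ogdb.lca(taxonomy, carrying)
        if anc != taxonomy.root:
            out.append(TaxonConstraint(term, ontology.ONLY_IN, anc))
    return out


# ---------------------------------------------------------------------------
# Bundle assembly
# ---------------------------------------------------------------------------


def _prune_to_clade(
    root: TreeNode, clade: int, taxonomy: TaxonomyTree
) -> Optional[TreeNode]:
    """Copy of the gene tree restricted to leaves whose species lie in clade;
    unary nodes are suppressed, event labels kept on surviving nodes."""
    keep = {t for t in taxonomy.descendants(clade) if taxonomy.is_leaf(t)}

    def prune(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf:
            if ogdb.taxid_of(node.name) in keep:
                return TreeNode(name=node.name)
            return None
        kids = [prune(c) for c in node.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        new = TreeNode(event=node.event)
        for k in kids:
            new.add(k)
        return new

    return prune(root)


def _plain_newick(root: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return node.name or ""
        return "(" + ",".join(fmt(c) for c in node.children) + ")"

    return fmt(root) + ";"


def simulate_bundle(config: SimConfig) -> SimResult:
    """Generate the complete database bundle plus ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    taxonomy = simulate_taxonomy(config, rng)
    clade_levels = choose_clade_levels(taxonomy)

    families: dict[str, FamilyTruth] = {}
    sequences: dict[str, str] = {}
    for i in range(config.n_families):
        fam_id = f"F{i:03d}"
        fam = simulate_family(config, taxonomy, fam_id, rng)
        families[fam_id] = fam
        sequences.update(simulate_sequences(fam.root, config, rng))

    dag, part_of_edges = simulate_go_dag(config, rng)
    truth = simulate_annotations(families, dag, taxonomy, config, rng)
    constraints = derive_taxon_constraints(truth, dag, taxonomy, config, rng)

    # gene names: a base name per family, copy numbers for within-species duplicates
    letters = np.array(list(string.ascii_lowercase))
    gene_names: dict[str, str] = {}
    for fam_id in sorted(families):
        base = "".join(rng.choice(letters, size=3)) + rng.choice(letters).upper()
        per_species_count: dict[int, int] = {}
        for leaf in families[fam_id].root.leaves():
            taxid = ogdb.taxid_of(leaf.name)
            per_species_count[taxid] = per_species_count.get(taxid, 0) + 1
            copy = per_species_count[taxid]
            if rng.random() < config.unnamed_fraction:
                continue
            gene_names[leaf.name] = base if copy == 1 else f"{base}{copy}"

    # KEGG pathways per family
    fam_pathways: dict[str, set[str]] = {}
    for fam_id in sorted(families):
        n_pw = int(rng.integers(1, 3))
        fam_pathways[fam_id] = {f"map{int(rng.integers(0, 100000)):05d}" for _ in range(n_pw)}
    fam_cog: dict[str, str] = {}
    for fam_id in sorted(families):
        n_cat = int(rng.integers(1, 3))
        cats = rng.choice(np.array(list(COG_CATEGORIES)), size=n_cat, replace=False)
        fam_cog[fam_id] = "".join(sorted(cats))

    proteins: dict[str, ProteinRecord] = {}
    for fam_id in sorted(families):
        for leaf in families[fam_id].root.leaves():
            pid = leaf.name
            proteins[pid] = ProteinRecord(
                protein_id=pid,
                taxid=ogdb.taxid_of(pid),
                sequence=sequences[pid],
                gene_name=gene_names.get(pid),
            )

    ogs: list[OrthologousGroup] = []
    for fam_id in sorted(families):
        fam = families[fam_id]
        for clade in clade_levels:
            pruned = _prune_to_clade(fam.root, clade, taxonomy)
            if pruned is None or pruned.is_leaf:
                continue
            members = {l.name for l in pruned.leaves()}
            per_member: dict[str, FunctionalAnnotation] = {}
            for pid in members:
                go_terms = {
                    (term, truth.evidence[(pid, term)]) for term in truth.raw_terms.get(pid, set())
                }
                kegg = {pw for pw in sorted(fam_pathways[fam_id]) if rng.random() < 0.9}
                per_member[pid] = FunctionalAnnotation(
                    go_terms=go_terms,
                    kegg_pathways=kegg,
                    cog_category=fam_cog[fam_id],
                    gene_name=gene_names.get(pid),
                )
            group_go = set().union(*(a.go_terms for a in per_member.values()))
            group_kegg = set().union(*(a.kegg_pathways for a in per_member.values()))
            ogs.append(
                OrthologousGroup(
                    og_id=f"{fam_id}@{clade}",
                    clade=clade,
                    members=members,
                    gene_tree=_plain_newick(pruned),
                    annotation=FunctionalAnnotation(
                        go_terms=group_go,
                        kegg_pathways=group_kegg,
                        cog_category=fam_cog[fam_id],
                    ),
                    per_member_annotations=per_member,
                )
            )

    db = DatabaseBundle(
        taxonomy=taxonomy,
        proteins=proteins,
        ogs=ogs,
        clade_levels=ogdb.derive_clade_levels(taxonomy, ogs),
    )
    return SimResult(
        config=config,
        taxonomy=taxonomy,
        db=db,
        dag=dag,
        part_of_edges=part_of_edges,
        constraints=constraints,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Metagenome simulation
# ---------------------------------------------------------------------------


@dataclass
class MetagenomeSample:
    sample_id: str
    species_abundance: dict[int, float]
    gene_reads: dict[str, float]  # simulated read counts per gene
    gold_profile: "object"  # benchmark.FunctionalProfile


def simulate_metagenome_profile(
    sim: SimResult, rng: np.random.Generator, sample_id: str = "sample1"
) -> MetagenomeSample:
    """One simulated metagenomic sample over a random subset of species.

    Species abundances are log-normal; per-gene read counts are Poisson with
    mean = species abundance x ``reads_per_gene``.  The gold functional
    profile counts, for each GO term, the reads simulated from genes truly
    annotated with that term (ancestor-closed).
    """
    from .benchmark import functional_profile

    config = sim.config
    leaves = sim.taxonomy.leaves()
    n = min(config.n_sample_species, len(leaves))
    species = sorted(int(t) for t in rng.choice(np.array(leaves), size=n, replace=False))
    abundance = {s: float(rng.lognormal(mean=0.0, sigma=1.0)) for s in species}

    gene_reads: dict[str, float] = {}
    for pid in sorted(sim.db.proteins):
        taxid = sim.db.proteins[pid].taxid
        if taxid in abundance:
            reads = float(rng.poisson(abundance[taxid] * config.reads_per_gene))
            if reads > 0:
                gene_reads[pid] = reads
    gold = functional_profile(
        gene_reads, {g: sim.truth.true_terms.get(g, set()) for g in gene_reads}, dag=None,
        sample_id=sample_id,
    )
    return MetagenomeSample(
        sample_id=sample_id,
        species_abundance=abundance,
        gene_reads=gene_reads,
        gold_profile=gold,
    )


# ---------------------------------------------------------------------------
# On-disk emission
# ---------------------------------------------------------------------------


def write_bundle(sim: SimResult, outdir: str | Path) -> Path:
    """Write the database bundle, ontology, constraints, ground truth and a
    manifest recording the full configuration (byte-deterministic)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aux = {
        "ontology": "go.obo",
        "taxon_constraints": "taxon_constraints.tsv",
        "true_pairs": "truth/ortholog_pairs.tsv",
        "true_terms": "truth/true_terms.tsv",
        "true_trees": "truth/gene_trees_events.tsv",
        "evidence": "truth/evidence.tsv",
    }
    manifest_path = ogdb.write_database(
        sim.db,
        outdir,
        extra_manifest={
            "aux_files": aux,
            "sim_config": dataclasses.asdict(sim.config),
            "seed": sim.config.seed,
            "model_organisms": sorted(sim.truth.model_organisms),
        },
    )
    ontology.write_obo(sim.dag, outdir / aux["ontology"], sim.part_of_edges)
    ontology.write_taxon_constraints(sim.constraints, outdir / aux["taxon_constraints"])
    (outdir / "truth").mkdir(exist_ok=True)
    with open(outdir / aux["true_pairs"], "w") as fh:
        for fam_id in sorted(sim.truth.families):
            for a, b, rel in sorted(sim.truth.families[fam_id].pairs):
                fh.write(f"{fam_id}\t{a}\t{b}\t{rel}\n")
    with open(outdir / aux["true_terms"], "w") as fh:
        for pid in sorted(sim.truth.true_terms):
            for term in sorted(sim.truth.true_terms[pid]):
                fh.write(f"{pid}\t{term}\n")
    with open(outdir / aux["true_trees"], "w") as fh:
        for fam_id in sorted(sim.truth.families):
            fh.write(f"{fam_id}\t{sim.truth.families[fam_id].newick}\n")
    with open(outdir / aux["evidence"], "w") as fh:
        for (pid, term), code in sorted(sim.truth.evidence.items()):
            fh.write(f"{pid}\t{term}\t{code}\n")
    return manifest_path


def load_aux(bundle_dir: str | Path) -> dict:
    """Paths of the auxiliary (ontology/constraints/truth) files of a bundle."""
    bundle_dir = Path(bundle_dir)
    with open(bundle_dir / ogdb.MANIFEST_NAME) as fh:
        manifest = json.load(fh)
    return {k: bundle_dir / v for k, v in manifest.get("aux_files", {}).items()}
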