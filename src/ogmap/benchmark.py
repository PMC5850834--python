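"""Evaluation framework for GO annotation transfer.

Each predicted (protein, term) pair is classified against a curated gold
standard:

* **TP** — the term is in the protein's experimentally supported
  (ancestor-closed) term set;
* **FP** — the term violates a curated taxon constraint for the protein's
  taxon (e.g. a never-in-plants process predicted for a plant protein);
* **uncertain** — neither supported nor excludable.

Summary statistics include the strict TP-ratio (TP over *all* assignments,
treating uncertain terms as non-true), the TP:(TP+FP) proportion, proteome
coverage and coverage categories (proteins with only-TP, mixed, or no-TP
assignments), protein-centric F-max in partial mode, and Spearman comparison
of metagenomic GO abundance profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import stats

from .ogdb import TaxonomyTree, taxid_of
from .ontology import GoDag, TaxonConstraint, propagate, violates_taxon_constraint

logger = logging.getLogger(__name__)

TP = "TP"
FP = "FP"
UNCERTAIN = "uncertain"

EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


@dataclass
class GoldStandard:
    """Curated per-protein true-positive term sets plus taxon constraints."""

    tp_terms: dict[str, set[str]]  # protein -> ancestor-closed TP set
    constraints: list[TaxonConstraint] = field(default_factory=list)
    taxids: dict[str, int] = field(default_factory=dict)

    def taxid(self, protein_id: str) -> int:
        return self.taxids.get(protein_id, taxid_of(protein_id))


def build_gold_standard(
    rows: Iterable[tuple[str, str, str]],
    dag: GoDag,
    constraints: Optional[Iterable[TaxonConstraint]] = None,
    evidence_codes: frozenset[str] = EXPERIMENTAL_CODES,
    closed: bool = True,
) -> GoldStandard:
    """Gold standard from (protein, term, evidence) rows.

    Terms whose evidence code is in ``evidence_codes`` become TPs; the sets
    are ancestor-closed by default so that predicting an entailed parent of
    a curated term still counts as true.
    """
    raw: dict[str, set[str]] = {}
    for pid, term, ev in rows:
        if ev in evidence_codes:
            raw.setdefault(pid, set()).add(term)
    tp = {pid: propagate(dag, terms) if closed else set(terms) for pid, terms in raw.items()}
    return GoldStandard(tp_terms=tp, constraints=list(constraints or []))


def load_gold_tsv(path) -> list[tuple[str, str, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pid, term, ev = line.split("\t")
            rows.append((pid, term, ev))
    return rows


# ---------------------------------------------------------------------------
# Classification and summaries
# ---------------------------------------------------------------------------


def classify_terms(
    predictions: Mapping[str, Iterable[str]],
    gold: GoldStandard,
    dag: GoDag,
    taxonomy: TaxonomyTree,
) -> dict[str, dict[str, str]]:
    """Label every predicted (protein, term) as TP / FP / uncertain.

    Proteins absent from the gold standard are treated as having an empty
    TP set (their predictions can still be FP or uncertain).
    """
    out: dict[str, dict[str, str]] = {}
    for pid in sorted(predictions):
        terms = set(predictions[pid])
        tp_set = gold.tp_terms.get(pid)
        if tp_set is None:
            logger.debug("protein %s absent from gold standard; TP set empty", pid)
            tp_set = set()
        taxid = gold.taxid(pid)
        labels = {}
        for term in terms:
            if term in tp_set:
                labels[term] = TP
            elif violates_taxon_constraint(term, taxid, gold.constraints, taxonomy, dag):
                labels[term] = FP
            else:
                labels[term] = UNCERTAIN
        out[pid] = labels
    return out


@dataclass
class EvalSummary:
    n_proteins: int
    n_annotated: int
    mean_tp: float
    mean_fp: float
    mean_uncertain: float
    tp_ratio: Optional[float]  # strict: TP over all assignments
    tp_fp_proportion: Optional[float]  # TP over TP+FP
    coverage: float
    tp_only_fraction: float
    mixed_fraction: float
    no_tp_fraction: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def summarize(classification: Mapping[str, Mapping[str, str]], proteome_size: int) -> EvalSummary:
    """Aggregate a classification into per-proteome evaluation statistics.

    ``tp_ratio`` is the strict ratio (uncertain counts against the
    predictor); ratios are ``None`` when undefined (no assignments at all).
    Category fractions are over the whole proteome, so they sum to coverage.
    """
    if proteome_size <= 0:
        raise ValueError("proteome_size must be positive")
    n_tp = n_fp = n_unc = 0
    annotated = [pid for pid, labels in classification.items() if labels]
    cat_tp_only = cat_mixed = cat_no_tp = 0
    for pid in annotated:
        labels = classification[pid]
        counts = {TP: 0, FP: 0, UNCERTAIN: 0}
        for lab in labels.values():
            counts[lab] += 1
        n_tp += counts[TP]
        n_fp += counts[FP]
        n_unc += counts[UNCERTAIN]
        if counts[TP] == len(labels):
            cat_tp_only += 1
        elif counts[TP] == 0:
            cat_no_tp += 1
        else:
            cat_mixed += 1
    total = n_tp + n_fp + n_unc
    n_ann = len(annotated)
    return EvalSummary(
        n_proteins=proteome_size,
        n_annotated=n_ann,
        mean_tp=n_tp / n_ann if n_ann else 0.0,
        mean_fp=n_fp / n_ann if n_ann else 0.0,
        mean_uncertain=n_unc / n_ann if n_ann else 0.0,
        tp_ratio=n_tp / total if total else None,
        tp_fp_proportion=n_tp / (n_tp + n_fp) if (n_tp + n_fp) else None,
        coverage=n_ann / proteome_size,
        tp_only_fraction=cat_tp_only / proteome_size,
        mixed_fraction=cat_mixed / proteome_size,
        no_tp_fraction=cat_no_tp / proteome_size,
    )


# ---------------------------------------------------------------------------
# F-max (protein-centric, partial mode)
# ---------------------------------------------------------------------------


@dataclass
class FmaxResult:
    fmax: float
    threshold: float
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    mode: str = "partial"


def fmax(
    predictions: Mapping[str, Mapping[str, float]],
    gold_tp: Mapping[str, Iterable[str]],
    thresholds: Optional[np.ndarray] = None,
) -> FmaxResult:
    """Protein-centric F-max over a score-threshold sweep (partial mode).

    At each threshold t, a protein's prediction set is its terms with score
    >= t.  Precision is averaged over proteins predicting at least one term
    at t (partial mode); recall is averaged over every benchmark protein
    with a non-empty gold set.  Unscored predictions should be given score
    1.0 by the caller; scores must lie in [0, 1].
    """
    gold = {pid: set(terms) for pid, terms in gold_tp.items() if terms}
    if not gold:
        raise ValueError("F-max undefined: no protein has a non-empty gold set")
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.001, 0.01), 2)
    for pid, scored in predictions.items():
        for term, score in scored.items():
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"score out of [0,1] for ({pid}, {term}): {score}")

    n_benchmark = len(gold)
    precisions = np.zeros(len(thresholds))
    recalls = np.zeros(len(thresholds))
    for i, t in enumerate(thresholds):
        prec_terms = []
        recall_sum = 0.0
        for pid, scored in predictions.items():
            pred = {term for term, score in scored.items() if score >= t}
            g = gold.get(pid, set())
            if pred:
                prec_terms.append(len(pred & g) / len(pred))
            if g:
                recall_sum += len(pred & g) / len(g)
        precisions[i] = float(np.mean(prec_terms)) if prec_terms else 0.0
        recalls[i] = recall_sum / n_benchmark
    f = np.zeros(len(thresholds))
    nz = (precisions + recalls) > 0
    f[nz] = 2 * precisions[nz] * recalls[nz] / (precisions[nz] + recalls[nz])
    best = int(np.argmax(f))
    return FmaxResult(
        fmax=float(f[best]),
        threshold=float(thresholds[best]),
        thresholds=np.asarray(thresholds),
        precision=precisions,
        recall=recalls,
    )


# ---------------------------------------------------------------------------
# Metagenomic functional profiles
# ---------------------------------------------------------------------------


@dataclass
class FunctionalProfile:
    """GO-term abundance vector for one sample."""

    abundances: dict[str, float]
    sample_id: str = ""

    def __post_init__(self) -> None:
        for term, ab in self.abundances.items():
            if ab < 0:
                raise ValueError(f"negative abundance for {term}: {ab}")


def functional_profile(
    gene_abundances: Mapping[str, float],
    gene_to_go: Mapping[str, Iterable[str]],
    dag: Optional[GoDag] = None,
    sample_id: str = "",
) -> FunctionalProfile:
    """GO abundance profile: each term accumulates the abundance of every
    gene annotated with it (term sets ancestor-closed first if a DAG is given)."""
    out: dict[str, float] = {}
    for gene, abundance in gene_abundances.items():
        if abundance < 0:
            raise ValueError(f"negative abundance for gene {gene}")
        terms = set(gene_to_go.get(gene, ()))
        if dag is not None:
            terms = propagate(dag, terms)
        for term in terms:
            out[term] = out.get(term, 0.0) + abundance
    return FunctionalProfile(abundances=out, sample_id=sample_id)


@dataclass
class ProfileComparison:
    rho: float  # nan when undefined (constant vector)
    p_value: float
    n_terms: int


def compare_profiles(
    a: FunctionalProfile, b: FunctionalProfile, exact: Optional[bool] = None
) -> ProfileComparison:
    """Tie-corrected Spearman correlation over the union of the two term sets.

    Only terms appearing in either profile enter the comparison; a term
    missing from one profile contributes abundance 0 there.  With
    ``exact=True`` (default for n <= 10) the p-value is by permutation.
    """
    keys = sorted(set(a.abundances) | set(b.abundances))
    if len(keys) < 3:
        raise ValueError("profile comparison needs at least 3 terms in the union")
    va = np.array([a.abundances.get(k, 0.0) for k in keys])
    vb = np.array([b.abundances.get(k, 0.0) for k in keys])
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        return ProfileComparison(rho=math.nan, p_value=math.nan, n_terms=len(keys))
    if exact is None:
        exact = len(keys) <= 10
    if exact:
        res = stats.spearmanr(va, vb)
        rho = float(res.statistic)
        perm = stats.permutation_test(
            (va,),
            lambda x: stats.spearmanr(x, vb).statistic,
            permutation_type="pairings",
            n_resamples=math.inf if len(keys) <= 7 else 20000,
            alternative="two-sided",
            random_state=0,
        )
        return ProfileComparison(rho=rho, p_value=float(perm.pvalue), n_terms=len(keys))
    res = stats.spearmanr(va, vb)
    return ProfileComparison(rho=float(res.statistic), p_value=float(res.pvalue), n_terms=len(keys))


def read_profile_tsv(path, sample_id: str = "") -> FunctionalProfile:
    abundances = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, ab = line.split("\t")
            abundances[term] = float(ab)
    return FunctionalProfile(abundances=abundances, sample_id=sample_id)


def write_profile_tsv(profile: FunctionalProfile, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(profile.abundances):
            fh.write(f"{term}\t{profile.abundances[term]:.6g}\n")
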