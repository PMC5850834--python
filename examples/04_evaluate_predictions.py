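"""Evaluate GO predictions against an experimental-evidence gold standard.

Predicted terms are labeled TP (experimentally supported), FP (violating a
curated taxon constraint), or uncertain; the strict TP-ratio counts
uncertain terms against the predictor.  F-max sweeps a score threshold and
reports the best harmonic mean of precision and recall (partial mode:
precision averaged over predicting proteins only).
"""

from ogmap.annotate import ScopeSetting, TransferPolicy, annotate_queries
from ogmap.benchmark import (
    EXPERIMENTAL_CODES,
    GoldStandard,
    classify_terms,
    fmax,
    summarize,
)
from ogmap.ontology import propagate
from ogmap.simdb import SimConfig, simulate_bundle

sim = simulate_bundle(SimConfig(seed=42))
held = sorted(sim.truth.model_organisms)[0]
queries = {pid: rec.sequence for pid, rec in sorted(sim.db.proteins.items())
           if rec.taxid == held}
policy = TransferPolicy(go_evidence="experimental", excluded_taxa={held})
results = annotate_queries(queries, sim.db, sim.dag, ScopeSetting(), policy)

gold = GoldStandard(
    tp_terms={
        pid: propagate(sim.dag, {
            t for t in sim.truth.raw_terms.get(pid, set())
            if sim.truth.evidence[(pid, t)] in EXPERIMENTAL_CODES
        })
        for pid in queries
    },
    constraints=sim.constraints,
)
predictions = {r.query_id: r.go_terms for r in results if r.go_terms}
summary = summarize(classify_terms(predictions, gold, sim.dag, sim.taxonomy),
                    proteome_size=len(queries))
fm = fmax({p: {t: 1.0 for t in ts} for p, ts in predictions.items()}, gold.tp_terms)

print(f"coverage        : {summary.coverage:.1%}")
print(f"mean TP/FP/unc  : {summary.mean_tp:.2f} / {summary.mean_fp:.2f} / "
      f"{summary.mean_uncertain:.2f} per protein")
print(f"strict TP-ratio : {summary.tp_ratio:.1%}")
print(f"TP:(TP+FP)      : {summary.tp_fp_proportion:.1%}")
print(f"categories      : tp_only={summary.tp_only_fraction:.1%} "
      f"mixed={summary.mixed_fraction:.1%} no_tp={summary.no_tp_fraction:.1%}")
print(f"F-max (partial) : {fm.fmax:.3f} at threshold {fm.threshold:.2f}")
# Unscored predictions collapse the threshold sweep to a single operating point.
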