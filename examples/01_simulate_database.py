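"""Generate a synthetic orthology database bundle with ground truth.

The generator evolves gene families along a random species tree
(duplication/loss events recorded per node), mutates protein sequences down
each gene tree, draws a random GO DAG, and annotates proteins with evidence
codes.  Everything is written as plain-text tables plus a manifest.
"""

from ogmap.simdb import SimConfig, simulate_bundle, write_bundle

config = SimConfig(seed=42)  # 20 species, 40 families by default
sim = simulate_bundle(config)
manifest = write_bundle(sim, "scratch/example_bundle")

print(f"species            : {len(sim.taxonomy.leaves())}")
print(f"proteins           : {len(sim.db.proteins)}")
print(f"orthologous groups : {len(sim.db.ogs)} at clade levels {sim.db.clade_levels}")
print(f"GO terms           : {len(sim.dag.terms)}")
print(f"taxon constraints  : {len(sim.constraints)}")
print(f"model organisms    : {sorted(sim.truth.model_organisms)}")
print(f"bundle manifest    : {manifest}")
# The clade levels are the taxonomic depths at which groups are built: the
# root level covers every species; narrower levels support scoped transfer.
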