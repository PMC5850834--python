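"""Label a gene tree by species overlap and extract fine-grained orthologs.

A node whose child subtrees share species is a duplication; everything else
is a speciation.  Orthologs of a seed leaf are the other-species leaves
joined to it through a speciation; same-species leaves joined through a
duplication are its in-paralogs and are excluded from annotation transfer.
"""

from ogmap.treeortho import GeneTree, infer_orthologs, label_events

# human has two in-paralogous copies (h1, h2); mouse and fly have one gene
newick = "(((9606.h1,9606.h2),10090.m1),7227.f1);"
tree = GeneTree.from_newick(newick)
labeling = label_events(tree)  # threshold 0: any shared species => duplication

print(f"tree: {newick}")
for node in tree.internal_nodes():
    leaves = ",".join(sorted(l.name for l in node.leaves()))
    print(f"  node({leaves}) -> {labeling.label(node)}")

for seed in ("9606.h1", "10090.m1"):
    a = infer_orthologs(tree, labeling, seed)
    print(f"seed {seed}: orthologs={sorted(a.orthologs)} inparalogs={sorted(a.inparalogs)}")
# From h1's view the mouse gene is a many2one ortholog (two human copies vs
# one mouse copy); from m1's view the relation transposes to one2many.
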