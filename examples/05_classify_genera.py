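"""Assign genomes to the five genera.

Hallmarks decide first (polB -> gamma, RCRE -> alpha); Rep-carrying genomes
are split into beta vs delta by their placement on the concatenated
ORF7+ORF8 neighbor-joining tree (bootstrap support >= 0.95); hallmark-free
genomes are epsilon when they fall in the epsilon reference clade.
"""

from collections import Counter

from pleomine.markerdb import build_profile, calibrate_threshold, calibration_set_from_sequences
from pleomine.simulate import HALLMARK_FAMILIES, Halovirome, SimulationConfig
from pleomine.taxonomy import (
    align_and_concat, assign_genus, bootstrap_support, detect_hallmarks, distance_matrix,
)
from pleomine.trees import nj_tree

sim = Halovirome.generate(SimulationConfig(seed=42))
profiles = {}
for fam in HALLMARK_FAMILIES:
    tp = sim.calibration_tp(fam)
    if tp:
        p = build_profile(tp, name=fam)
        calibrate_threshold(p, calibration_set_from_sequences(p, tp, sim.calibration_tn()))
        profiles[fam] = p

orf7 = {g.genome_id: g.gene("ORF7").protein for g in sim.genomes}
orf8 = {g.genome_id: g.gene("ORF8").protein for g in sim.genomes}
aln = align_and_concat(orf7, orf8)
labels, D, _ = distance_matrix(aln)
tree = nj_tree(labels, D)
supports = bootstrap_support(aln, n_replicates=100, seed=42)

refs, per = {}, {}
for g in sim.genomes:  # three labeled "isolates" per genus anchor the clades
    if per.get(g.genus, 0) < 3:
        refs[g.genome_id] = g.genus
        per[g.genus] = per.get(g.genus, 0) + 1

calls = {}
for g in sim.genomes:
    if g.genome_id in refs:
        continue
    hm = detect_hallmarks([(x.gene_id, x.protein) for x in g.genes], profiles)
    calls[g.genome_id] = assign_genus(g.genome_id, hm, tree, supports, refs)

truth = {g.genome_id: g.genus for g in sim.genomes}
acc = sum(c.genus == truth[g] for g, c in calls.items()) / len(calls)
print("called genera:", dict(Counter(c.genus for c in calls.values())))
print(f"genus recovery accuracy vs planted truth: {acc:.3f} over {len(calls)} genomes")
# Accuracy near 1.0 shows hallmark precedence plus supported-clade placement
# reproduces the planted five-genus structure.
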