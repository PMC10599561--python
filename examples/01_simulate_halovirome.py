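"""Generate a synthetic halovirome and look at its ground truth.

The generator plants five genera of pleolipovirus-like genomes (conserved
four-gene cassette, genus-specific replication hallmarks, integrase-linked
genome-size inflation), emits each genome as a DTR/ITR/provirus/fragment
contig among decoy host contigs, and builds host CRISPR arrays.
"""

from collections import Counter

from pleomine.simulate import Halovirome, SimulationConfig

config = SimulationConfig(
    seed=42,
    n_genomes_per_genus={"alpha": 10, "beta": 10, "gamma": 4, "delta": 8, "epsilon": 8},
)
sim = Halovirome.generate(config)

print(f"genomes: {len(sim.genomes)}, contigs: {len(sim.contigs)} "
      f"(incl. {sum(1 for c in sim.contigs if c.kind == 'decoy')} decoys)")
print("contig classes:", dict(Counter(
    t.completeness_class for t in sim.truth.viral_contigs())))
with_int = [g.length for g in sim.genomes if g.integrase]
without = [g.length for g in sim.genomes if not g.integrase]
print(f"mean genome length with integrase: {sum(with_int)/len(with_int):.0f} bp, "
      f"without: {sum(without)/len(without):.0f} bp")
# The integrase group should be ~4 kb larger: that is the planted cargo that
# the network/length statistics downstream are expected to detect.
print("planted cassettes equal genomes:",
      sim.truth.n_planted_cassettes == len(sim.genomes))
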