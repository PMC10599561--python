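"""The whole pipeline in one call: simulate -> build marker database ->
screen -> completeness -> dereplicate -> classify -> host calls -> network.

Every stage is scored against the planted truth; the metrics dict is the
scoreboard.
"""

from pleomine import run_pipeline
from pleomine.simulate import SimulationConfig

result = run_pipeline(SimulationConfig(seed=42, p_integrase=0.5), seed=42, n_bootstrap=100)

for key in ("n_contigs", "n_candidates", "n_high_confidence", "n_clusters",
            "cassette_recall", "cassette_precision", "n_false_complete",
            "genus_accuracy", "host_accuracy"):
    print(f"{key}: {result.metrics[key]}")

row = result.association[result.association.analysis == "length~integrase"].iloc[0]
print(f"integrase vs genome length: Wilcoxon p = {row.p_value:.3g}")
# Recall/precision of 1.0 at divergence 0.3 and a tiny p-value for the
# planted length effect mean every stage behaved as specified.
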