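"""End-to-end mining pipeline on a synthetic halovirome.

Stages: simulate -> build calibrated marker database -> screen contigs ->
completeness -> dereplicate -> classify genera -> call hosts -> gene-sharing
network statistics, with every stage scored against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import evaluate
from .dereplicate import SpeciesCluster, cluster_species
from .hostcall import HostCall, SpacerMatch, decide_host, host_range_summary, match_spacers
from .markerdb import (
    CalibrationResult,
    MarkerProfile,
    ProfileSearchEngine,
    build_profile,
    calibrate_threshold,
    calibration_set_from_sequences,
    iterative_expand,
)
from .mining import (
    CompletenessCall,
    ContigScreen,
    ScreenResult,
    call_provirus,
    detect_terminal_repeats,
    integrate_completeness,
    screen_contigs,
)
from .netstats import integrase_association_report, protein_clusters, shared_gene_network
from .simulate import CORE_MARKERS, HALLMARK_FAMILIES, Halovirome, SimulationConfig
from .taxonomy import (
    GenusCall,
    HallmarkProfileCall,
    align_and_concat,
    assign_genus,
    bootstrap_support,
    distance_matrix,
    nj_tree,
)

N_REFERENCES_PER_GENUS = 3


@dataclass
class GenomeRecord:
    """A high-confidence candidate genome and everything decided about it."""

    genome_id: str  # contig id of the mined genome
    length: int
    completeness: CompletenessCall
    hallmarks: HallmarkProfileCall
    cluster_id: int | None = None
    is_representative: bool = False
    genus: str = "unassigned"
    host: str | None = None


@dataclass
class PipelineResult:
    simulation: Halovirome
    profiles: dict[str, MarkerProfile]
    calibration: dict[str, CalibrationResult]
    screen: ScreenResult
    completeness: dict[str, CompletenessCall]
    clusters: list[SpeciesCluster]
    genus_calls: dict[str, GenusCall]
    host_calls: dict[str, HostCall]
    spacer_matches: list[SpacerMatch]
    network: nx.Graph
    association: pd.DataFrame
    records: dict[str, GenomeRecord]
    references: dict[str, str]
    metrics: dict = field(default_factory=dict)


def build_marker_database(
    sim: Halovirome, seed: int, families: tuple[str, ...] | None = None
) -> tuple[dict[str, MarkerProfile], dict[str, CalibrationResult]]:
    """Iteratively expand each seed family against the protein database and
    calibrate the resulting profile on the expanded family (TP) vs decoys (TN)."""
    families = families or (CORE_MARKERS + HALLMARK_FAMILIES)
    db = sim.protein_db()
    tn = sim.calibration_tn()
    profiles: dict[str, MarkerProfile] = {}
    calibration: dict[str, CalibrationResult] = {}
    for fam in families:
        seeds = sim.seed_proteins(fam)
        expansion = iterative_expand(
            seeds, db, engine=ProfileSearchEngine(seed=seed), search_with="family"
        )
        profile = build_profile(expansion.family, name=fam)
        cal_set = calibration_set_from_sequences(profile, expansion.family, tn)
        calibration[fam] = calibrate_threshold(profile, cal_set)
        profiles[fam] = profile
    return profiles, calibration


def assess_completeness(
    screen: ScreenResult,
    external_scores: dict[str, float] | None = None,
    min_tr_len: int = 20,
) -> dict[str, CompletenessCall]:
    """Terminal repeats + provirus rule + optional external score, per candidate."""
    calls: dict[str, CompletenessCall] = {}
    for contig in screen.candidates():
        tr = None
        if contig.length > 2 * min_tr_len:
            seq = _contig_seq(screen, contig)
            tr = detect_terminal_repeats(seq, min_len=min_tr_len) if seq else None
        prov = None
        if contig.cassette is not None:
            viral_keys = {(p.start, p.end, p.strand) for p in contig.placements}
            integrase_keys = {
                (p.start, p.end, p.strand) for p in contig.placements if p.marker == "integrase"
            }
            prov = call_provirus(
                contig.contig_id, contig.cassette, contig.gene_calls, viral_keys, integrase_keys
            )
        ext = (external_scores or {}).get(contig.contig_id)
        calls[contig.contig_id] = integrate_completeness(tr, prov, ext)
    return calls


def _contig_seq(screen: ScreenResult, contig: ContigScreen) -> str | None:
    return getattr(contig, "_seq", None)


def run_pipeline(
    config: SimulationConfig | None = None,
    seed: int = 0,
    n_bootstrap: int = 100,
    outdir: str | Path | None = None,
) -> PipelineResult:
    config = config or SimulationConfig(seed=seed)
    sim = Halovirome.generate(config, seed)
    contig_seqs = {c.contig_id: c.seq for c in sim.contigs}

    # 1. marker database
    profiles, calibration = build_marker_database(sim, seed)

    # 2. tiered screen
    screen = screen_contigs([(c.contig_id, c.seq) for c in sim.contigs], profiles)
    for contig in screen.contigs:  # stash sequences for completeness checks
        contig._seq = contig_seqs[contig.contig_id]

    # 3. completeness
    completeness = assess_completeness(screen)

    # 4. high-confidence genome records
    records: dict[str, GenomeRecord] = {}
    for contig in screen.high_confidence():
        hallmarks = HallmarkProfileCall(
            RCRE="RCRE" in contig.markers,
            Rep="Rep" in contig.markers,
            polB="polB" in contig.markers,
            integrase="integrase" in contig.markers,
        )
        records[contig.contig_id] = GenomeRecord(
            genome_id=contig.contig_id,
            length=contig.length,
            completeness=completeness[contig.contig_id],
            hallmarks=hallmarks,
        )

    # 5. species-rank dereplication
    hc_ids = sorted(records)
    clusters = cluster_species([(cid, contig_seqs[cid]) for cid in hc_ids])
    for cluster in clusters:
        for member in cluster.members:
            records[member].cluster_id = cluster.cluster_id
            records[member].is_representative = member == cluster.representative

    # 6. genus classification on the concatenated ORF7+ORF8 tree
    by_id = screen.by_id()
    orf7: dict[str, str] = {}
    orf8: dict[str, str] = {}
    for cid in hc_ids:
        contig = by_id[cid]
        genes = {g.key: g for g in contig.gene_calls}
        for marker, store in (("ORF7", orf7), ("ORF8", orf8)):
            placement = contig.markers.get(marker)
            if placement is not None:
                gene = genes.get((placement.start, placement.end, placement.strand))
                if gene is not None:
                    store[cid] = gene.protein
    references = _pick_references(sim, hc_ids)
    genus_calls: dict[str, GenusCall] = {}
    tree = None
    supports: dict = {}
    if len(orf7) + len(orf8) >= 3:
        alignment = align_and_concat(orf7, orf8, genomes=hc_ids)
        labels, D, excluded = distance_matrix(alignment)
        tree = nj_tree(labels, D)
        supports = bootstrap_support(alignment, n_bootstrap, seed)
        for cid in hc_ids:
            if cid in references:
                genus_calls[cid] = GenusCall(cid, references[cid], ["reference"])
            else:
                genus_calls[cid] = assign_genus(
                    cid, records[cid].hallmarks, tree, supports, references
                )
            records[cid].genus = genus_calls[cid].genus

    # 7. host calls (CRISPR precedence over integrated scores)
    contig_to_genome = {
        c.contig_id: c.source_genome
        for c in sim.truth.contigs.values()
        if c.source_genome is not None
    }
    score_by_genome: dict[str, dict[str, float]] = {}
    for row in sim.host_scores.itertuples():
        score_by_genome.setdefault(row.genome, {})[row.host] = float(row.score)
    spacer_matches: list[SpacerMatch] = []
    host_calls: dict[str, HostCall] = {}
    for cid in hc_ids:
        matches = match_spacers(sim.spacer_sets.spacers, (cid, contig_seqs[cid]))
        spacer_matches.extend(matches)
        scores = score_by_genome.get(contig_to_genome.get(cid, ""), {})
        host_calls[cid] = decide_host(cid, scores, matches)
        records[cid].host = host_calls[cid].host_id

    # 8. gene-sharing network + association statistics
    proteins = [
        (cid, f"p{i}", g.protein)
        for cid in hc_ids
        for i, g in enumerate(by_id[cid].gene_calls)
    ]
    assignment = protein_clusters(proteins)
    node_attrs = {
        cid: {
            "length": records[cid].length,
            "integrase": records[cid].hallmarks.integrase,
            "genus": records[cid].genus,
        }
        for cid in hc_ids
    }
    network = shared_gene_network(assignment, node_attrs)
    association = integrase_association_report(network) if hc_ids else pd.DataFrame()

    # 9. score against truth
    cass = evaluate.cassette_metrics(screen, sim.truth)
    comp_err = evaluate.completeness_errors(completeness, sim.truth)
    gen_acc, gen_frame = evaluate.genus_accuracy(
        genus_calls, sim.truth, contig_to_genome, exclude=set(references)
    )
    host_acc, host_frame = evaluate.host_accuracy(host_calls, sim.truth, contig_to_genome)
    range_counts, range_hist = host_range_summary(
        spacer_matches, genomes=[c for c in hc_ids]
    )
    metrics = {
        "n_contigs": len(sim.contigs),
        "n_high_confidence": len(hc_ids),
        "n_candidates": len(screen.candidates()),
        "n_clusters": len(clusters),
        "cassette_recall": cass.recall,
        "cassette_precision": cass.precision,
        "n_false_complete": len(comp_err["false_complete"]),
        "n_missed_complete": len(comp_err["missed_complete"]),
        "genus_accuracy": gen_acc,
        "host_accuracy": host_acc,
        "host_range_histogram": dict(range_hist),
        "genus_frame": gen_frame,
        "host_frame": host_frame,
    }

    result = PipelineResult(
        simulation=sim,
        profiles=profiles,
        calibration=calibration,
        screen=screen,
        completeness=completeness,
        clusters=clusters,
        genus_calls=genus_calls,
        host_calls=host_calls,
        spacer_matches=spacer_matches,
        network=network,
        association=association,
        records=records,
        references=references,
        metrics=metrics,
    )
    if outdir is not None:
        write_pipeline_outputs(result, outdir)
    return result


def _pick_references(sim: Halovirome, hc_ids: list[str]) -> dict[str, str]:
    """Designate a few high-confidence contigs per genus as labeled references
    (the analogue of the isolate genomes anchoring the published phylogeny)."""
    refs: dict[str, str] = {}
    per_genus: dict[str, int] = {}
    for cid in hc_ids:
        t = sim.truth.contigs.get(cid)
        if t is None or t.genus is None:
            continue
        if per_genus.get(t.genus, 0) < N_REFERENCES_PER_GENUS:
            refs[cid] = t.genus
            per_genus[t.genus] = per_genus.get(t.genus, 0) + 1
    return refs


def write_pipeline_outputs(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.simulation.write_outputs(outdir / "simulation")
    rows = []
    for cid, rec in sorted(result.records.items()):
        rows.append(
            {
                "genome_id": cid,
                "length": rec.length,
                "completeness": rec.completeness.status,
                "evidence": ",".join(sorted(rec.completeness.evidence)),
                "cluster": rec.cluster_id,
                "representative": rec.is_representative,
                "genus": rec.genus,
                "host": rec.host or "",
                "integrase": rec.hallmarks.integrase,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "genome_records.tsv", sep="\t", index=False)
    result.association.to_csv(outdir / "association_report.tsv", sep="\t", index=False)
    with open(outdir / "screen_log.tsv", "w") as fh:
        fh.write("\n".join(result.screen.log) + "\n")
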