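"""Scoring pipeline stages against the simulation ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mining import CompletenessCall, ScreenResult
from .simulate.truth import TruthTable
from .taxonomy import GenusCall


@dataclass
class CassetteMetrics:
    recall: float
    precision: float
    n_truth: int
    n_detected: int
    false_positives: list[str]
    missed: list[str]


def cassette_metrics(screen: ScreenResult, truth: TruthTable) -> CassetteMetrics:
    """Recall over contigs whose planted cassette is intact; precision over
    all cassette detections (a detection on a decoy or cassette-free contig
    is a false positive)."""
    detected = {c.contig_id for c in screen.contigs if c.cassette is not None}
    intact = {c.contig_id for c in truth.contigs.values() if c.cassette_complete}
    viral = {c.contig_id for c in truth.contigs.values() if c.source_genome is not None}
    tp = detected & intact
    false_pos = sorted(detected - viral)
    recall = len(tp) / len(intact) if intact else float("nan")
    true_detections = detected & viral
    precision = len(true_detections) / len(detected) if detected else float("nan")
    return CassetteMetrics(
        recall=recall,
        precision=precision,
        n_truth=len(intact),
        n_detected=len(detected),
        false_positives=false_pos,
        missed=sorted(intact - detected),
    )


def completeness_confusion(
    calls: dict[str, CompletenessCall], truth: TruthTable
) -> pd.DataFrame:
    """Rows: truth class; columns: complete/incomplete call counts."""
    rows: dict[str, dict[str, int]] = {}
    for contig_id, call in calls.items():
        t = truth.contigs.get(contig_id)
        cls = t.completeness_class if t else "unknown"
        rows.setdefault(cls, {"complete": 0, "incomplete": 0})
        rows[cls][call.status] += 1
    out = pd.DataFrame(rows).T.fillna(0).astype(int)
    return out.sort_index()


def completeness_errors(calls: dict[str, CompletenessCall], truth: TruthTable) -> dict:
    """False 'complete' calls (truth fragment/decoy) and missed complete classes."""
    false_complete = []
    missed_complete = []
    for contig_id, call in calls.items():
        t = truth.contigs.get(contig_id)
        if t is None:
            continue
        truly_complete = t.completeness_class.startswith("complete")
        if call.status == "complete" and not truly_complete:
            false_complete.append(contig_id)
        if call.status == "incomplete" and truly_complete:
            missed_complete.append(contig_id)
    return {"false_complete": sorted(false_complete), "missed_complete": sorted(missed_complete)}


def genus_accuracy(
    calls: dict[str, GenusCall],
    truth: TruthTable,
    contig_to_genome: dict[str, str],
    exclude: set[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of genomes whose genus call matches the planted genus."""
    rows = []
    exclude = exclude or set()
    for contig_id, call in calls.items():
        if contig_id in exclude:
            continue
        genome_id = contig_to_genome.get(contig_id)
        if genome_id is None or genome_id not in truth.genomes:
            continue
        rows.append(
            {
                "contig_id": contig_id,
                "called": call.genus,
                "truth": truth.genomes[genome_id].genus,
                "correct": call.genus == truth.genomes[genome_id].genus,
            }
        )
    frame = pd.DataFrame(rows)
    acc = float(frame["correct"].mean()) if len(frame) else float("nan")
    return acc, frame


def host_accuracy(
    calls: dict[str, object], truth: TruthTable, contig_to_genome: dict[str, str]
) -> tuple[float, pd.DataFrame]:
    """Fraction of viral genomes assigned their true host."""
    rows = []
    for contig_id, call in calls.items():
        genome_id = contig_to_genome.get(contig_id)
        if genome_id is None or genome_id not in truth.genomes:
            continue
        rows.append(
            {
                "contig_id": contig_id,
                "called": call.host_id or "",
                "basis": call.basis,
                "truth": truth.genomes[genome_id].host,
                "correct": call.host_id == truth.genomes[genome_id].host,
            }
        )
    frame = pd.DataFrame(rows)
    acc = float(frame["correct"].mean()) if len(frame) else float("nan")
    return acc, frame
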