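"""End-to-end orchestration: files in, score/enrichment tables out."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from gims.annotation import (
    DEFAULT_AUTOSOMES,
    build_coding_sites,
    parse_annotation,
    select_longest_transcript,
)
from gims.enrichment import combined_meta_score, enrich, read_gene_sets
from gims.io import (
    read_score_table,
    reconcile_chrom_names,
    write_enrichment_table,
    write_score_table,
)
from gims.metrics import (
    ConservationTrack,
    FunctionalScoreTable,
    compute_unit_metrics,
    load_variants,
)
from gims.scoring import compute_scores

log = logging.getLogger(__name__)

__all__ = [
    "score_units_from_paths",
    "run_score_genes",
    "run_score_transcripts",
    "run_enrich",
    "run_combine",
]


def _open_genome(fasta):
    from pyfaidx import Fasta

    return Fasta(str(fasta), sequence_always_upper=True)


def score_units_from_paths(
    gtf,
    fasta,
    vcf,
    conservation,
    functional,
    level: str = "gene",
    min_cds: int = 100,
    maf_threshold: float = 0.005,
    autosomes=DEFAULT_AUTOSOMES,
) -> pd.DataFrame:
    """Score all units from input files; the library core of the CLI.

    ``level="gene"`` applies the longest-transcript rule and reports one
    row per gene (unit_id = gene_id, the GIMS convention); ``"transcript"``
    scores every transcript independently (TIMS).  Chromosome naming
    across inputs is reconciled to the genome's naming for the
    "chr"-prefix case only.
    """
    if level not in ("gene", "transcript"):
        raise ValueError(f"unknown scoring level {level!r}")
    genome = _open_genome(fasta)
    genome_chroms = set(genome.keys())

    transcripts = parse_annotation(gtf, min_cds=min_cds, autosomes=autosomes)
    if not transcripts:
        raise ValueError("no transcripts pass the CDS-length/chromosome filters")
    tx_chroms = {t.chrom for t in transcripts}
    tx_map = reconcile_chrom_names(genome_chroms, tx_chroms)
    if tx_map:
        transcripts = [
            t.__class__(
                t.gene_id,
                t.transcript_id,
                tx_map.get(t.chrom, t.chrom),
                t.strand,
                t.cds_intervals,
                t.cds_length,
            )
            for t in transcripts
        ]

    track = ConservationTrack.from_tsv(conservation)
    track.rename_chroms(reconcile_chrom_names(genome_chroms, track.chroms()))
    ftable = FunctionalScoreTable.from_tsv(functional)
    ftable.rename_chroms(reconcile_chrom_names(genome_chroms, ftable.chroms()))
    variants = load_variants(vcf)
    var_map = reconcile_chrom_names(genome_chroms, set(variants["chrom"]))
    if var_map:
        variants["chrom"] = variants["chrom"].map(lambda c: var_map.get(c, c))

    if level == "gene":
        chosen = select_longest_transcript(transcripts)
        units = [
            (t.gene_id, t)
            for t in transcripts
            if chosen[t.gene_id] == t.transcript_id
        ]
    else:
        units = [(t.transcript_id, t) for t in transcripts]

    metrics = []
    n_excluded = 0
    for unit_id, t in units:
        sites = build_coding_sites(t, genome)
        gm = compute_unit_metrics(
            t,
            sites,
            track,
            ftable,
            variants,
            maf_threshold=maf_threshold,
            unit_id=unit_id,
        )
        if gm is None:
            n_excluded += 1
            continue
        metrics.append(gm)
    log.info(
        "scoring %d %s units (%d excluded for zero ndCDS sites)",
        len(metrics),
        level,
        n_excluded,
    )
    return compute_scores(metrics)


def run_score_genes(out, config: dict | None = None, **paths) -> pd.DataFrame:
    """Score genes (GIMS) and write the table with provenance headers."""
    scores = score_units_from_paths(level="gene", **paths)
    write_score_table(scores, out, {"level": "gene", **(config or {})})
    return scores


def run_score_transcripts(out, config: dict | None = None, **paths) -> pd.DataFrame:
    """Score transcripts (TIMS) and write the table with provenance headers."""
    scores = score_units_from_paths(level="transcript", **paths)
    write_score_table(scores, out, {"level": "transcript", **(config or {})})
    return scores


def run_enrich(scores_path, sets_path, out, mode: str = "vs_complement"):
    """Enrich every gene set in ``sets_path`` against a written score table."""
    scores = read_score_table(scores_path)
    results = [enrich(gs, scores, mode=mode) for gs in read_gene_sets(sets_path)]
    write_enrichment_table(results, out, {"mode": mode, "sets": str(sets_path)})
    return results


def run_combine(primary_path, secondary_path, out) -> pd.DataFrame:
    """Meta-combine two written score tables into a joint quantile table."""
    primary = read_score_table(primary_path)
    secondary = read_score_table(secondary_path)
    combined = combined_meta_score(primary, secondary)
    n_shared = len(combined)
    log.info("combined score over %d shared genes", n_shared)
    write_score_table(
        combined,
        out,
        {"primary": str(primary_path), "secondary": str(secondary_path)},
    )
    return combined
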