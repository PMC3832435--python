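"""Toy genome / annotation / track / variant simulator with a known
per-gene selection-strength gradient.

Each gene ``i`` carries a latent selection strength ``s_i`` in [0, 1] that
shifts all four raw metrics in the directions stronger purifying selection
produces in real data:

* conservation scores rise (Normal, mean ``base + uplift * s``);
* functional-damage scores shift toward 1 (Beta with s-dependent shape);
* per-site SNV probability falls (fewer segregating sites);
* the allele-frequency spectrum shifts toward rare alleles.

MAFs are drawn from a log-uniform (density proportional to 1/x) spectrum,
split into a rare and a common band whose mixture weight moves toward the
rare band as ``s`` grows — a simple controllable stand-in for the site
frequency spectrum under selection, not a population-genetics simulator.

Randomness: one root seed spawns an independent child stream per gene
(NumPy ``SeedSequence``), consumed in a documented order (gene layout,
codons, then per-site conservation / functional / variant draws along the
CDS), so adding genes to a configuration never perturbs earlier genes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gims.annotation import (
    STANDARD_CODE,
    TranscriptModel,
    build_coding_sites,
    revcomp,
)

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_genome_annotation",
    "simulate_tracks_and_variants",
    "simulate",
    "end_to_end_recovery",
]

_STOPS = frozenset(c for c, aa in STANDARD_CODE.items() if aa == "*")


@dataclass(frozen=True)
class SimulationConfig:
    """Fully serialisable description of one simulated dataset.

    Effect-size fields tie the latent per-gene selection strength ``s`` to
    the four observable metrics; setting the four slope/decline/shift
    fields to zero gives a null dataset with no signal.
    """

    seed: int
    n_genes: int = 200
    transcripts_per_gene: tuple[int, int] = (1, 2)
    cds_length_range: tuple[int, int] = (150, 300)  # nt, >= 100
    gc_content: float = 0.45
    chrom: str = "chr1"
    #: explicit per-gene strengths; None = even gradient over [0, 1]
    selection_strengths: tuple[float, ...] | None = None
    # conservation model: Normal(base + uplift * s, sd)
    conservation_base: float = 0.0
    conservation_sd: float = 1.5
    conservation_uplift: float = 4.0
    # functional model: Beta(alpha0 + alpha_slope * s, beta0 - beta_slope * s)
    functional_alpha0: float = 1.0
    functional_alpha_slope: float = 4.0
    functional_beta0: float = 5.0
    functional_beta_slope: float = 4.0
    # mutation model: per-ndCDS-site SNV probability snv_prob * (1 - decline * s)
    snv_prob: float = 0.12
    snv_decline: float = 0.8
    # frequency model: P(common) = common_frac * (1 - rare_shift * s)
    common_frac: float = 0.6
    rare_shift: float = 0.85
    maf_min: float = 1e-4
    maf_split: float = 0.005  # rare/common band boundary
    maf_max: float = 0.5
    intron_length_range: tuple[int, int] = (20, 60)
    intergenic_range: tuple[int, int] = (30, 80)
    minus_strand_fraction: float = 0.5

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        lo, hi = self.cds_length_range
        if lo < 100 or hi < lo:
            raise ValueError("cds_length_range must satisfy 100 <= lo <= hi")
        if self.selection_strengths is not None and len(
            self.selection_strengths
        ) != self.n_genes:
            raise ValueError("selection_strengths length must equal n_genes")

    def strengths(self) -> np.ndarray:
        if self.selection_strengths is not None:
            return np.asarray(self.selection_strengths, dtype=float)
        if self.n_genes == 1:
            return np.array([0.5])
        return np.linspace(0.0, 1.0, self.n_genes)

    @classmethod
    def null(cls, seed: int, **kwargs) -> "SimulationConfig":
        """A configuration with all selection effects switched off."""
        kwargs.setdefault("conservation_uplift", 0.0)
        kwargs.setdefault("functional_alpha_slope", 0.0)
        kwargs.setdefault("functional_beta_slope", 0.0)
        kwargs.setdefault("snv_decline", 0.0)
        kwargs.setdefault("rare_shift", 0.0)
        return cls(seed=seed, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown simulation config key {k!r}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(
        rng.choice(
            np.array(list("ACGT")),
            size=n,
            p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2],
        )
    )


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Coding sequence free of stop codons (codon-wise rejection sampling)."""
    codons = []
    while len(codons) < n_codons:
        codon = _random_seq(rng, 3, gc)
        if codon not in _STOPS:
            codons.append(codon)
    return "".join(codons)


def _slice_spliced(
    intervals: list[tuple[int, int]], strand: str, length: int
) -> list[tuple[int, int]]:
    """First ``length`` spliced nucleotides of transcription-ordered intervals."""
    out = []
    remaining = length
    for start, end in intervals:
        if remaining <= 0:
            break
        take = min(remaining, end - start)
        if strand == "+":
            out.append((start, start + take))
        else:
            out.append((end - take, end))
        remaining -= take
    return out


@dataclass
class _Gene:
    gene_id: str
    strength: float
    transcripts: list[TranscriptModel]


def simulate_genome_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[TranscriptModel], pd.DataFrame]:
    """Build the toy genome and annotation.

    Returns ``(genome, transcripts, truth)`` where genome maps chromosome
    name -> plus-strand sequence, transcripts are in genomic order, and
    truth is a DataFrame ``gene_id, s`` with the latent strengths.

    Genes are laid out left to right on a single contig, non-overlapping,
    each with 1-3 CDS chunks separated by introns.  When a gene has a
    second transcript it is a 5' prefix of the first (a truncated isoform),
    so its coding sites are a subset of the longest transcript's.
    """
    strengths = config.strengths()
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_genes)
    chrom_parts: list[str] = []
    cursor = 0
    transcripts: list[TranscriptModel] = []
    truth_rows = []
    for i in range(config.n_genes):
        rng = np.random.default_rng(children[i])
        gid = f"G{i + 1:04d}"
        s = float(strengths[i])
        truth_rows.append((gid, s))

        gap = int(rng.integers(*config.intergenic_range, endpoint=True))
        chrom_parts.append(_random_seq(rng, gap, config.gc_content))
        cursor += gap

        lo, hi = config.cds_length_range
        n_codons = int(rng.integers(lo // 3, hi // 3, endpoint=True))
        cds = _random_cds(rng, n_codons, config.gc_content)
        n_exons = int(rng.integers(1, 3, endpoint=True))
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"

        # split the CDS into exon chunks (each >= 10 nt)
        cuts = sorted(
            int(c)
            for c in rng.choice(
                np.arange(10, len(cds) - 10), size=n_exons - 1, replace=False
            )
        ) if n_exons > 1 else []
        bounds = [0, *cuts, len(cds)]
        chunks = [cds[a:b] for a, b in zip(bounds, bounds[1:])]
        introns = [
            _random_seq(
                rng,
                int(rng.integers(*config.intron_length_range, endpoint=True)),
                config.gc_content,
            )
            for _ in range(len(chunks) - 1)
        ]

        # genomic layout: plus strand writes chunks 5'->3' left to right;
        # minus strand writes reverse-complemented chunks right to left
        tx_intervals: list[tuple[int, int]] = []  # transcription order
        if strand == "+":
            pos = cursor
            for k, chunk in enumerate(chunks):
                chrom_parts.append(chunk)
                tx_intervals.append((pos, pos + len(chunk)))
                pos += len(chunk)
                if k < len(introns):
                    chrom_parts.append(introns[k])
                    pos += len(introns[k])
            cursor = pos
        else:
            pos = cursor
            genomic_intervals = []
            for k, chunk in enumerate(reversed(chunks)):
                chrom_parts.append(revcomp(chunk))
                genomic_intervals.append((pos, pos + len(chunk)))
                pos += len(chunk)
                if k < len(introns):
                    chrom_parts.append(introns[k])
                    pos += len(introns[k])
            cursor = pos
            tx_intervals = genomic_intervals[::-1]  # descending = transcription order

        n_tx = int(
            rng.integers(*config.transcripts_per_gene, endpoint=True)
        )
        t1 = TranscriptModel(
            gene_id=gid,
            transcript_id=f"{gid}.T1",
            chrom=config.chrom,
            strand=strand,
            cds_intervals=tuple(tx_intervals),
            cds_length=len(cds),
        )
        transcripts.append(t1)
        if n_tx >= 2 and len(cds) >= 240:
            # truncated isoform: first 40..(n-10) codons, always >= 120 nt
            n_keep = int(rng.integers(40, len(cds) // 3 - 10, endpoint=True)) * 3
            sub = _slice_spliced(list(tx_intervals), strand, n_keep)
            transcripts.append(
                TranscriptModel(
                    gene_id=gid,
                    transcript_id=f"{gid}.T2",
                    chrom=config.chrom,
                    strand=strand,
                    cds_intervals=tuple(sub),
                    cds_length=n_keep,
                )
            )

    genome = {config.chrom: "".join(chrom_parts)}
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "s"])
    return genome, transcripts, truth


def simulate_tracks_and_variants(
    config: SimulationConfig,
    genome: dict[str, str],
    transcripts: list[TranscriptModel],
    truth: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw conservation, functional scores and variants over the annotation.

    Returns ``(conservation, functional, variants)`` DataFrames:
    conservation covers *all* coding positions of every gene
    (chrom, pos, score); functional covers every possible substitution at
    those positions (chrom, pos, ref, alt, score); variants are biallelic
    SNVs at non-degenerate sites (chrom, pos, ref, alt, maf).

    Draws re-use each gene's child stream, taken after the layout draws,
    walking the longest transcript's sites in CDS order.
    """
    strengths = dict(zip(truth["gene_id"], truth["s"]))
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_genes)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)

    cons_rows, func_rows, var_rows = [], [], []
    for i, gid in enumerate(sorted(by_gene)):
        # independent track substream: same child entropy, different stream key
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=children[i].entropy, spawn_key=(i, 1)
            )
        )
        s = strengths[gid]
        longest = max(by_gene[gid], key=lambda t: (t.cds_length, t.transcript_id))
        sites = build_coding_sites(longest, genome)

        alpha = config.functional_alpha0 + config.functional_alpha_slope * s
        beta = max(
            0.25, config.functional_beta0 - config.functional_beta_slope * s
        )
        p_snv = config.snv_prob * (1.0 - config.snv_decline * s)
        p_common = config.common_frac * (1.0 - config.rare_shift * s)

        for row in sites.itertuples(index=False):
            pos = int(row.genomic_pos)
            score = rng.normal(
                config.conservation_base + config.conservation_uplift * s,
                config.conservation_sd,
            )
            cons_rows.append((row.chrom, pos, round(float(score), 4)))
            for alt in "ACGT":
                if alt == row.ref_plus:
                    continue
                v = rng.beta(alpha, beta)
                func_rows.append(
                    (row.chrom, pos, row.ref_plus, alt, round(float(v), 4))
                )
            if row.is_nondegenerate and rng.random() < p_snv:
                alts = [b for b in "ACGT" if b != row.ref_plus]
                alt = alts[int(rng.integers(0, 3))]
                if rng.random() < p_common:
                    lo, hi = np.log(config.maf_split), np.log(config.maf_max)
                else:
                    lo, hi = np.log(config.maf_min), np.log(config.maf_split)
                maf = float(np.exp(rng.uniform(lo, hi)))
                var_rows.append(
                    (row.chrom, pos, row.ref_plus, alt, round(maf, 6))
                )

    conservation = pd.DataFrame(cons_rows, columns=["chrom", "pos", "score"])
    functional = pd.DataFrame(
        func_rows, columns=["chrom", "pos", "ref", "alt", "score"]
    )
    variants = pd.DataFrame(
        var_rows, columns=["chrom", "pos", "ref", "alt", "maf"]
    )
    for df in (conservation, functional, variants):
        df.sort_values(["chrom", "pos"], kind="stable", inplace=True)
        df.reset_index(drop=True, inplace=True)
    return conservation, functional, variants


def _write_fasta(genome: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_gtf(transcripts: list[TranscriptModel], path: Path) -> None:
    rows = []
    for t in transcripts:
        for start0, end0 in sorted(t.cds_intervals):
            rows.append(
                (
                    t.chrom,
                    start0,
                    f"{t.chrom}\tsim\tCDS\t{start0 + 1}\t{end0}\t.\t{t.strand}\t0\t"
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";',
                )
            )
    rows.sort()
    with open(path, "w") as fh:
        for _, _, line in rows:
            fh.write(line + "\n")


def _write_vcf(
    variants: pd.DataFrame, genome: dict[str, str], path: Path
) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">')
    for chrom, seq in genome.items():
        header.contigs.add(chrom, length=len(seq))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for row in variants.itertuples(index=False):
            rec = out.new_record(
                contig=row.chrom,
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(row.ref, row.alt),
            )
            rec.info["AF"] = float(row.maf)
            out.write(rec)


def simulate(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Run the full simulation and write every artifact to ``outdir``.

    Writes ``genome.fa``, ``annotation.gtf``, ``conservation.tsv``,
    ``functional.tsv``, ``variants.vcf`` and ``truth.tsv`` (gene_id, s);
    returns a dict of paths keyed by short names.  Deterministic: the same
    config (including seed) yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, transcripts, truth = simulate_genome_annotation(config)
    conservation, functional, variants = simulate_tracks_and_variants(
        config, genome, transcripts, truth
    )
    paths = {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "conservation": outdir / "conservation.tsv",
        "functional": outdir / "functional.tsv",
        "vcf": outdir / "variants.vcf",
        "truth": outdir / "truth.tsv",
    }
    _write_fasta(genome, paths["fasta"])
    _write_gtf(transcripts, paths["gtf"])
    conservation.to_csv(paths["conservation"], sep="\t", index=False)
    functional.to_csv(paths["functional"], sep="\t", index=False)
    _write_vcf(variants, genome, paths["vcf"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    log.info(
        "simulated %d genes / %d transcripts / %d variants into %s",
        config.n_genes,
        len(transcripts),
        len(variants),
        outdir,
    )
    return paths


def end_to_end_recovery(config: SimulationConfig, workdir=None) -> dict:
    """Simulate, score, and correlate recovered quantiles with the truth.

    Runs the full file-based pipeline (so every emitted format passes
    through the package's own readers) and returns a dict with the Spearman
    correlation between the latent strength ``s`` and the gene-level
    quantile (negative = stronger selection ranks lower, as designed),
    its p-value, and the number of genes scored.
    """
    import tempfile

    from scipy.stats import spearmanr

    from gims.pipeline import score_units_from_paths

    def _run(outdir) -> dict:
        paths = simulate(config, outdir)
        scores = score_units_from_paths(
            gtf=paths["gtf"],
            fasta=paths["fasta"],
            vcf=paths["vcf"],
            conservation=paths["conservation"],
            functional=paths["functional"],
            level="gene",
        )
        truth = pd.read_csv(paths["truth"], sep="\t")
        merged = truth.merge(
            scores[["unit_id", "gims_quantile"]],
            left_on="gene_id",
            right_on="unit_id",
        ).dropna(subset=["gims_quantile"])
        rho, p = spearmanr(merged["s"], merged["gims_quantile"])
        return {"spearman": float(rho), "p_value": float(p), "n": len(merged)}

    if workdir is not None:
        return _run(workdir)
    with tempfile.TemporaryDirectory() as tmp:
        return _run(tmp)
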