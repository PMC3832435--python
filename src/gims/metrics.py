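"""The four raw per-unit selection metrics over non-degenerate coding sites.

Per scoring unit (gene or transcript) and per CpG stratum:

* mean conservation — arithmetic mean of per-position constraint scores
  (GERP++-like rejected-substitution scale) over ndCDS positions;
* mean functional score — mean predicted damage (PolyPhen2-like, in [0,1])
  pooled over *all possible* single-nucleotide substitutions at ndCDS
  positions (up to 3 per position), not a per-site mean of means;
* SNV density — observed segregating SNVs per kilobase of ndCDS;
* %RARE — fraction of observed SNVs with minor allele frequency <= 0.5%
  ("common" means MAF strictly > 0.5%).

All four are simple averages or ratios, never length-dependent test
statistics, so gene length does not confound the ranking.  Missing slots
(no sites, no coverage, no observed SNVs) stay missing and are excluded
from the downstream combination rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from gims.annotation import TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "STRATA",
    "ConservationTrack",
    "FunctionalScoreTable",
    "GeneMetrics",
    "load_variants",
    "mean_conservation",
    "mean_functional",
    "snv_density",
    "fraction_rare",
    "match_variants",
    "compute_unit_metrics",
]

#: CpG stratum labels, in canonical order
STRATA = ("cpg", "noncpg")

MAF_THRESHOLD = 0.005  # "common" is MAF strictly above this


class ConservationTrack:
    """Per-position conservation scores keyed by (chrom, 1-based pos).

    Lookups at unlisted positions return ``None`` (missing), never zero:
    an unscored site carries no evidence, a zero score does.
    """

    def __init__(self, scores: dict[tuple[str, int], float] | None = None):
        self._scores = dict(scores or {})

    @classmethod
    def from_tsv(cls, path) -> "ConservationTrack":
        """Load a tab-delimited track with header ``chrom  pos  score``."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
        df.columns = [c.lower() for c in df.columns]
        return cls(
            {
                (row.chrom, int(row.pos)): float(row.score)
                for row in df.itertuples(index=False)
            }
        )

    def get(self, chrom: str, pos: int) -> float | None:
        return self._scores.get((chrom, pos))

    def __len__(self) -> int:
        return len(self._scores)

    def chroms(self) -> set[str]:
        return {c for c, _ in self._scores}

    def rename_chroms(self, mapping: dict[str, str]) -> None:
        self._scores = {
            (mapping.get(c, c), p): v for (c, p), v in self._scores.items()
        }


class FunctionalScoreTable:
    """Per-substitution functional scores keyed by (chrom, pos, ref, alt).

    Scores live in [0, 1] (higher = more damaging); out-of-range values are
    clamped on load with a warning.
    """

    def __init__(self, scores: dict[tuple[str, int, str, str], float] | None = None):
        clamped = 0
        self._scores = {}
        for key, v in (scores or {}).items():
            chrom, pos, ref, alt = key
            if ref == alt:
                raise ValueError(f"ref == alt at {chrom}:{pos} ({ref})")
            if v < 0.0 or v > 1.0:
                clamped += 1
                v = min(1.0, max(0.0, v))
            self._scores[(chrom, int(pos), ref, alt)] = float(v)
        if clamped:
            log.warning("clamped %d functional scores to [0, 1]", clamped)

    @classmethod
    def from_tsv(cls, path) -> "FunctionalScoreTable":
        """Load a tab-delimited table with header ``chrom pos ref alt score``."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
        df.columns = [c.lower() for c in df.columns]
        return cls(
            {
                (row.chrom, int(row.pos), row.ref, row.alt): float(row.score)
                for row in df.itertuples(index=False)
            }
        )

    def get(self, chrom: str, pos: int, ref: str, alt: str) -> float | None:
        return self._scores.get((chrom, pos, ref, alt))

    def __len__(self) -> int:
        return len(self._scores)

    def chroms(self) -> set[str]:
        return {c for c, _, _, _ in self._scores}

    def rename_chroms(self, mapping: dict[str, str]) -> None:
        self._scores = {
            (mapping.get(c, c), p, r, a): v
            for (c, p, r, a), v in self._scores.items()
        }


def load_variants(vcf_path) -> pd.DataFrame:
    """Read biallelic SNVs with minor allele frequencies from a VCF.

    Multi-allelic records are split into one row per alternate allele.
    MAF source priority per record: INFO/AF; else INFO AC/AN; else genotype
    allele counts.  A record with none of the three raises ``ValueError``.
    Non-SNV alleles (indels, symbolic) are skipped with a counter.

    Returns a DataFrame with columns ``chrom, pos`` (1-based), ``ref, alt,
    maf`` where ``maf = min(af, 1 - af)``.
    """
    from cyvcf2 import VCF

    rows = []
    n_non_snv = 0
    vcf = VCF(str(vcf_path))
    for variant in vcf:
        alts = variant.ALT
        afs = _allele_freqs(variant, len(alts))
        for alt, af in zip(alts, afs):
            if len(variant.REF) != 1 or len(alt) != 1 or alt not in "ACGT":
                n_non_snv += 1
                continue
            maf = min(af, 1.0 - af)
            rows.append((variant.CHROM, variant.POS, variant.REF, alt, maf))
    vcf.close()
    if n_non_snv:
        log.info("skipped %d non-SNV alternate alleles", n_non_snv)
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "maf"])


def _allele_freqs(variant, n_alt: int) -> list[float]:
    af = variant.INFO.get("AF")
    if af is not None:
        return [float(a) for a in np.atleast_1d(af)]
    ac = variant.INFO.get("AC")
    an = variant.INFO.get("AN")
    if ac is not None and an is not None and float(an) > 0:
        return [float(a) / float(an) for a in np.atleast_1d(ac)]
    # genotype-derived frequency
    genotypes = variant.genotypes
    if genotypes:
        alleles = np.asarray([g[:2] for g in genotypes], dtype=int)
        called = alleles[alleles >= 0]
        if called.size:
            return [
                float(np.sum(called == i + 1)) / called.size for i in range(n_alt)
            ]
    raise ValueError(
        f"variant {variant.CHROM}:{variant.POS} carries no AF, AC/AN or genotypes"
    )


@dataclass
class GeneMetrics:
    """The four raw metrics for one scoring unit, per CpG stratum.

    Every per-stratum dict is keyed by :data:`STRATA`; ``None`` marks a
    missing slot (no sites, no score coverage, or no observed SNVs).
    """

    unit_id: str
    gene_id: str
    n_nd_sites: dict[str, int] = field(default_factory=dict)
    mean_conservation: dict[str, float | None] = field(default_factory=dict)
    conservation_coverage: dict[str, float | None] = field(default_factory=dict)
    mean_functional: dict[str, float | None] = field(default_factory=dict)
    n_snvs: dict[str, int] = field(default_factory=dict)
    snv_per_kb: dict[str, float | None] = field(default_factory=dict)
    n_common: dict[str, int] = field(default_factory=dict)
    frac_rare: dict[str, float | None] = field(default_factory=dict)


def mean_conservation(
    sites: pd.DataFrame, track: ConservationTrack
) -> tuple[float | None, float | None]:
    """Mean conservation over the given sites, skipping unscored positions.

    Returns ``(mean, coverage)`` where coverage is the scored fraction;
    both ``None`` when the site set is empty or nothing is scored.
    """
    if len(sites) == 0:
        return None, None
    scores = [
        v
        for chrom, pos in zip(sites["chrom"], sites["genomic_pos"])
        if (v := track.get(chrom, int(pos))) is not None
    ]
    coverage = len(scores) / len(sites)
    if not scores:
        return None, coverage
    return float(np.mean(scores)), coverage


def mean_functional(
    sites: pd.DataFrame, table: FunctionalScoreTable
) -> float | None:
    """Mean functional score pooled over all scored substitutions.

    Every possible single-nucleotide substitution (up to 3 per position,
    looked up by plus-strand ref/alt) contributes one observation; the mean
    is over substitutions, not a per-position mean of means.
    """
    scores = []
    for chrom, pos, ref_plus in zip(
        sites["chrom"], sites["genomic_pos"], sites["ref_plus"]
    ):
        for alt in "ACGT":
            if alt == ref_plus:
                continue
            v = table.get(chrom, int(pos), ref_plus, alt)
            if v is not None:
                scores.append(v)
    if not scores:
        return None
    return float(np.mean(scores))


def match_variants(sites: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Variants falling on the given site positions with a matching ref base.

    Records whose REF disagrees with the genome at that position are skipped
    with a warning (dialect-drift guard).  Split multi-allelic records count
    once per alternate allele.
    """
    if len(variants) == 0 or len(sites) == 0:
        return variants.iloc[0:0]
    site_ref = {
        (c, int(p)): r
        for c, p, r in zip(sites["chrom"], sites["genomic_pos"], sites["ref_plus"])
    }
    keep = []
    n_mismatch = 0
    for idx, (chrom, pos, ref) in enumerate(
        zip(variants["chrom"], variants["pos"], variants["ref"])
    ):
        expected = site_ref.get((chrom, int(pos)))
        if expected is None:
            continue
        if ref != expected:
            n_mismatch += 1
            continue
        keep.append(idx)
    if n_mismatch:
        log.warning(
            "skipped %d variant records whose REF disagrees with the genome",
            n_mismatch,
        )
    return variants.iloc[keep]


def snv_density(
    sites: pd.DataFrame, variants: pd.DataFrame
) -> tuple[float | None, int]:
    """Observed SNVs per kilobase of the given sites.

    Counts segregating sites (occurrences after multi-allelic splitting),
    not allele copies.  Returns ``(density, n_snvs)``; density is ``None``
    when the site set is empty.
    """
    matched = match_variants(sites, variants)
    n = len(matched)
    if len(sites) == 0:
        return None, n
    return 1000.0 * n / len(sites), n


def fraction_rare(
    mafs: Iterable[float], threshold: float = MAF_THRESHOLD
) -> tuple[float | None, int]:
    """Fraction of observed SNVs that are rare (MAF <= threshold).

    "Common" requires MAF strictly greater than the threshold, so a MAF of
    exactly 0.5% counts as rare.  Higher fraction = stronger depletion of
    common alleles = stronger selection.  Returns ``(frac_rare, n_common)``;
    the fraction is ``None`` with no observed SNVs.
    """
    mafs = np.asarray(list(mafs), dtype=float)
    if mafs.size == 0:
        return None, 0
    n_common = int(np.sum(mafs > threshold))
    return 1.0 - n_common / mafs.size, n_common


def compute_unit_metrics(
    unit: TranscriptModel,
    sites: pd.DataFrame,
    track: ConservationTrack,
    ftable: FunctionalScoreTable,
    variants: pd.DataFrame,
    maf_threshold: float = MAF_THRESHOLD,
    unit_id: str | None = None,
) -> GeneMetrics | None:
    """Fill all eight stratified metric slots for one scoring unit.

    ``sites`` is the unit's coding-site table; only non-degenerate positions
    are used.  Returns ``None`` (with a logged reason) for units with zero
    ndCDS sites in both strata — such units are excluded from scoring.
    """
    nd = sites[sites["is_nondegenerate"]]
    gm = GeneMetrics(
        unit_id=unit_id if unit_id is not None else unit.transcript_id,
        gene_id=unit.gene_id,
    )
    if len(nd) == 0:
        log.info(
            "unit %s excluded: no non-degenerate coding sites", gm.unit_id
        )
        return None
    for stratum in STRATA:
        mask = nd["is_cpg"] if stratum == "cpg" else ~nd["is_cpg"]
        snd = nd[mask]
        gm.n_nd_sites[stratum] = len(snd)
        mean_c, cov = mean_conservation(snd, track)
        gm.mean_conservation[stratum] = mean_c
        gm.conservation_coverage[stratum] = cov
        gm.mean_functional[stratum] = mean_functional(snd, ftable)
        matched = match_variants(snd, variants)
        gm.n_snvs[stratum] = len(matched)
        if len(snd) > 0:
            gm.snv_per_kb[stratum] = 1000.0 * len(matched) / len(snd)
        else:
            gm.snv_per_kb[stratum] = None
        frac, n_common = fraction_rare(matched["maf"], maf_threshold)
        gm.frac_rare[stratum] = frac
        gm.n_common[stratum] = n_common
    return gm
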