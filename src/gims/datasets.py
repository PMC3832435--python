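"""Small reference datasets bundled with the package.

The Mendelian FSGS (focal segmental glomerulosclerosis) gene panels below
carry the published genome-wide GIMS quantile of each gene, stratified by
mode of inheritance.  They serve as worked examples for the gene-set
summary machinery: the dominant panel sits well below the genome-wide
median (strong negative selection), the recessive panel does not.
"""

from __future__ import annotations

from gims.enrichment import GeneSet

__all__ = [
    "FSGS_DOMINANT_GIMS",
    "FSGS_RECESSIVE_GIMS",
    "fsgs_dominant_set",
    "fsgs_recessive_set",
]

#: autosomal-dominant FSGS genes with their published GIMS quantiles
FSGS_DOMINANT_GIMS: dict[str, float] = {
    "WT1": 0.05,
    "TRPC6": 0.06,
    "MYH9": 0.14,
    "ACTN4": 0.29,
    "LMX1B": 0.32,
    "ARHGAP24": 0.33,
    "CD2AP": 0.41,
    "INF2": 0.64,
}

#: autosomal-recessive FSGS genes with their published GIMS quantiles
FSGS_RECESSIVE_GIMS: dict[str, float] = {
    "MYO1E": 0.005,
    "PTPRO": 0.04,
    "ITGB4": 0.29,
    "PLCE1": 0.47,
    "LAMB2": 0.51,
    "SCARB2": 0.56,
    "COQ6": 0.67,
    "NPHS2": 0.68,
    "NPHS1": 0.70,
    "SMARCAL1": 0.86,
}


def fsgs_dominant_set() -> GeneSet:
    """The 8 autosomal-dominant FSGS genes as a :class:`GeneSet`."""
    return GeneSet.from_ids("FSGS-Dominant", FSGS_DOMINANT_GIMS)


def fsgs_recessive_set() -> GeneSet:
    """The 10 autosomal-recessive FSGS genes as a :class:`GeneSet`."""
    return GeneSet.from_ids("FSGS-Recessive", FSGS_RECESSIVE_GIMS)
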