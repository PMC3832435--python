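"""Coding-sequence models: GTF parsing, degeneracy classification, CpG context.

Coordinates are 1-based inclusive in GTF and in all user-facing output;
internally CDS intervals are stored 0-based half-open, in transcription order
(ascending genomic for ``+`` transcripts, descending for ``-``).

A coding position is *non-degenerate* (0-fold) when every single-nucleotide
substitution at that position changes the encoded amino acid; substitutions
that create a stop codon count as amino-acid-changing.  The set of such
positions (the ndCDS) is where all downstream selection metrics are measured,
because synonymous-capable sites dilute the signal of protein-level
constraint.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio.Data import CodonTable

log = logging.getLogger(__name__)

__all__ = [
    "TranscriptModel",
    "AnnotationParseError",
    "parse_annotation",
    "select_longest_transcript",
    "classify_degeneracy",
    "flag_cpg",
    "build_coding_sites",
    "revcomp",
    "DEFAULT_AUTOSOMES",
    "STANDARD_CODE",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: autosome names accepted by default in the pipeline, with and without "chr"
DEFAULT_AUTOSOMES = frozenset(
    [f"chr{i}" for i in range(1, 23)] + [str(i) for i in range(1, 23)]
)


def _standard_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


#: codon -> one-letter amino acid, '*' for stop (standard genetic code)
STANDARD_CODE: Mapping[str, str] = _standard_code()


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationParseError(ValueError):
    """Malformed annotation input; message carries the offending line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """Spliced CDS structure of one transcript.

    ``cds_intervals`` are 0-based half-open genomic intervals in transcription
    order; ``cds_length`` is the spliced length after trimming any trailing
    partial codon, i.e. always a multiple of 3.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    cds_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.cds_length != sum(e - s for s, e in self.cds_intervals):
            raise ValueError("cds_length inconsistent with cds_intervals")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    for required in ("gene_id", "transcript_id"):
        if required not in attrs:
            raise AnnotationParseError(
                f"line {lineno}: missing required attribute {required!r}"
            )
    return attrs


def parse_annotation(
    source,
    min_cds: int = 100,
    autosomes: Iterable[str] | None = None,
) -> list[TranscriptModel]:
    """Parse GTF ``CDS`` features into :class:`TranscriptModel` objects.

    Parameters
    ----------
    source
        Path to a GTF file, an open text handle, or an iterable of lines.
        Only ``CDS`` feature lines are used; attributes must follow the
        GenCODE ``key "value"`` dialect and carry ``gene_id`` and
        ``transcript_id``.
    min_cds
        Minimum spliced CDS length (nt, after trailing-partial-codon trim)
        for a transcript to be retained.  Default 100.
    autosomes
        Optional chromosome whitelist; records on other chromosomes are
        dropped.  ``None`` disables the filter.

    Returns
    -------
    list of TranscriptModel, ordered by (gene_id, transcript_id).
    """
    close = False
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        handle = open(source, "rt")
        close = True
    elif isinstance(source, io.TextIOBase):
        handle = source
    else:
        handle = iter(source)

    whitelist = frozenset(autosomes) if autosomes is not None else None
    # transcript_id -> (gene_id, chrom, strand, [(start0, end0), ...])
    raw: dict[str, tuple[str, str, str, list[tuple[int, int]]]] = {}
    n_dropped_chrom = 0
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"line {lineno}: expected 9 tab-separated GTF fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame = fields[:8]
            if feature != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"line {lineno}: non-integer coordinates "
                    f"{start_s!r}/{end_s!r}"
                ) from exc
            if end < start:
                raise AnnotationParseError(
                    f"line {lineno}: CDS interval end {end} < start {start}"
                )
            if strand not in ("+", "-"):
                raise AnnotationParseError(
                    f"line {lineno}: invalid strand {strand!r}"
                )
            if whitelist is not None and chrom not in whitelist:
                n_dropped_chrom += 1
                continue
            attrs = _parse_attributes(fields[8], lineno)
            tid = attrs["transcript_id"]
            gid = attrs["gene_id"]
            entry = raw.setdefault(tid, (gid, chrom, strand, []))
            if entry[0] != gid or entry[1] != chrom or entry[2] != strand:
                raise AnnotationParseError(
                    f"line {lineno}: transcript {tid} has inconsistent "
                    "gene/chrom/strand across CDS lines"
                )
            entry[3].append((start - 1, end))  # to 0-based half-open
    finally:
        if close:
            handle.close()

    if n_dropped_chrom:
        log.info("dropped %d CDS records outside chromosome whitelist", n_dropped_chrom)

    models: list[TranscriptModel] = []
    for tid, (gid, chrom, strand, intervals) in raw.items():
        intervals.sort()  # ascending genomic
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise AnnotationParseError(
                    f"transcript {tid}: overlapping CDS intervals "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        if strand == "-":
            intervals = intervals[::-1]  # transcription order
        annotated = sum(e - s for s, e in intervals)
        if annotated < min_cds:  # filter on the length as annotated
            continue
        intervals = _trim_3prime(intervals, strand, annotated % 3, tid)
        length = sum(e - s for s, e in intervals)
        models.append(
            TranscriptModel(gid, tid, chrom, strand, tuple(intervals), length)
        )
    models.sort(key=lambda t: (t.gene_id, t.transcript_id))
    return models


def _trim_3prime(
    intervals: list[tuple[int, int]], strand: str, n: int, transcript_id: str
) -> list[tuple[int, int]]:
    """Remove ``n`` nucleotides from the 3' end of transcription-ordered intervals."""
    if n == 0:
        return intervals
    log.warning(
        "transcript %s: trimming %d nt trailing partial codon", transcript_id, n
    )
    out = list(intervals)
    while n > 0:
        start, end = out[-1]
        take = min(n, end - start)
        if strand == "+":
            end -= take
        else:
            start += take
        n -= take
        if end > start:
            out[-1] = (start, end)
        else:
            out.pop()
    return out


def select_longest_transcript(
    transcripts: Iterable[TranscriptModel],
) -> dict[str, str]:
    """Pick one representative transcript per gene: maximal CDS length,
    ties broken by lexicographically smallest transcript_id."""
    best: dict[str, TranscriptModel] = {}
    n = 0
    for t in transcripts:
        n += 1
        cur = best.get(t.gene_id)
        if (
            cur is None
            or t.cds_length > cur.cds_length
            or (t.cds_length == cur.cds_length and t.transcript_id < cur.transcript_id)
        ):
            best[t.gene_id] = t
    if n == 0:
        raise ValueError("no transcripts supplied")
    return {gid: t.transcript_id for gid, t in best.items()}


def classify_degeneracy(
    codon: str,
    pos_in_codon: int,
    genetic_code: Mapping[str, str] = STANDARD_CODE,
) -> int:
    """Degeneracy fold of one codon position: 0, 2, 3 or 4.

    The fold is the number of nucleotides at ``pos_in_codon`` (1-3, including
    the reference base) that encode the same amino acid as the reference
    codon; a count of 1 (no synonymous alternative) is reported as fold 0,
    following the 0/2/3/4-fold convention.  Stop codons translate to ``'*'``,
    so substitutions to or from a stop are amino-acid-changing.
    """
    codon = codon.upper()
    if pos_in_codon not in (1, 2, 3):
        raise ValueError(f"pos_in_codon must be 1, 2 or 3, got {pos_in_codon}")
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"cannot classify ambiguous codon {codon!r}")
    aa_ref = genetic_code[codon]
    i = pos_in_codon - 1
    same = sum(
        1
        for base in "ACGT"
        if genetic_code[codon[:i] + base + codon[i + 1 :]] == aa_ref
    )
    return 0 if same == 1 else same


def _fetch(genome, chrom: str, start0: int, end0: int) -> str:
    """Plus-strand sequence [start0, end0) from a pyfaidx.Fasta or a mapping
    of chromosome name -> string."""
    seq = genome[chrom]
    return str(seq[start0:end0]).upper()


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def flag_cpg(genome, chrom: str, pos: int) -> bool:
    """Is 1-based ``pos`` part of a CG dinucleotide on the plus strand?

    True iff the reference base is C with G immediately 3', or G with C
    immediately 5', always evaluated on the plus strand.  Neighbour lookups
    that fall off the chromosome are treated as non-CpG.
    """
    base = _fetch(genome, chrom, pos - 1, pos)
    if base == "C":
        if pos >= _chrom_length(genome, chrom):
            return False
        return _fetch(genome, chrom, pos, pos + 1) == "G"
    if base == "G":
        if pos <= 1:
            return False
        return _fetch(genome, chrom, pos - 2, pos - 1) == "C"
    return False


def build_coding_sites(transcript: TranscriptModel, genome) -> pd.DataFrame:
    """Per-position codon context, degeneracy fold and CpG flag for one CDS.

    Returns a DataFrame with one row per coding position, columns:
    ``chrom, genomic_pos`` (1-based), ``cds_index`` (0-based offset in the
    spliced CDS), ``codon, pos_in_codon, degeneracy_fold`` (nullable Int64;
    NA when the codon contains an ambiguous base), ``is_nondegenerate,
    is_cpg, ref_base`` (coding orientation), ``ref_plus`` (plus strand).

    For minus-strand transcripts codons are read on the reverse complement
    while the CpG flag is still evaluated on the plus strand.  A terminal
    stop codon, if present, is trimmed; internal stops are reported with a
    warning and downstream codons still processed.
    """
    if not transcript.cds_intervals:
        raise ValueError(
            f"transcript {transcript.transcript_id}: empty CDS interval list"
        )
    # genomic positions (1-based) in transcription order, and the spliced
    # coding sequence read in coding orientation
    positions: list[int] = []
    pieces: list[str] = []
    for start0, end0 in transcript.cds_intervals:
        plus = _fetch(genome, transcript.chrom, start0, end0)
        if transcript.strand == "+":
            positions.extend(range(start0 + 1, end0 + 1))
            pieces.append(plus)
        else:
            positions.extend(range(end0, start0, -1))
            pieces.append(revcomp(plus))
    coding = "".join(pieces)

    excess = len(coding) % 3
    if excess:
        log.warning(
            "transcript %s: trimming %d nt trailing partial codon at site build",
            transcript.transcript_id,
            excess,
        )
        coding = coding[: len(coding) - excess]
        positions = positions[: len(positions) - excess]
    if len(coding) % 3 != 0:
        raise ValueError(
            f"transcript {transcript.transcript_id}: CDS length not a "
            "multiple of 3 after trim"
        )
    # GenCODE CDS excludes the terminal stop; trim one if supplied anyway
    if len(coding) >= 3 and STANDARD_CODE.get(coding[-3:]) == "*":
        log.info(
            "transcript %s: trimming terminal stop codon", transcript.transcript_id
        )
        coding = coding[:-3]
        positions = positions[:-3]

    rows = []
    for codon_idx in range(len(coding) // 3):
        codon = coding[codon_idx * 3 : codon_idx * 3 + 3]
        ambiguous = any(b not in "ACGT" for b in codon)
        if not ambiguous and STANDARD_CODE[codon] == "*":
            log.warning(
                "transcript %s: internal stop codon %s at codon %d",
                transcript.transcript_id,
                codon,
                codon_idx + 1,
            )
        for offset in range(3):
            cds_index = codon_idx * 3 + offset
            pos = positions[cds_index]
            fold = (
                None if ambiguous else classify_degeneracy(codon, offset + 1)
            )
            ref_coding = codon[offset]
            ref_plus = (
                ref_coding if transcript.strand == "+" else revcomp(ref_coding)
            )
            rows.append(
                (
                    transcript.chrom,
                    pos,
                    cds_index,
                    codon,
                    offset + 1,
                    fold,
                    fold == 0,
                    flag_cpg(genome, transcript.chrom, pos),
                    ref_coding,
                    ref_plus,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "genomic_pos",
            "cds_index",
            "codon",
            "pos_in_codon",
            "degeneracy_fold",
            "is_nondegenerate",
            "is_cpg",
            "ref_base",
            "ref_plus",
        ],
    )
    df["degeneracy_fold"] = df["degeneracy_fold"].astype("Int64")
    return df
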