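"""Score-table readers/writers, provenance headers, chromosome reconciliation."""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

import gims

log = logging.getLogger(__name__)

__all__ = [
    "write_score_table",
    "read_score_table",
    "write_enrichment_table",
    "reconcile_chrom_names",
]


def _provenance_lines(config: dict | None) -> list[str]:
    lines = [f"# gims {gims.__version__}"]
    for key in sorted(config or {}):
        lines.append(f"# config: {key}={config[key]}")
    return lines


def write_score_table(df: pd.DataFrame, path, config: dict | None = None) -> None:
    """Write a TSV with '#'-prefixed provenance lines, atomically.

    The table is written to a temporary sibling and renamed into place, so
    a failure never leaves a partial output file behind.
    """
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    try:
        with open(tmp, "w") as fh:
            for line in _provenance_lines(config):
                fh.write(line + "\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
        tmp.replace(path)
    finally:
        tmp.unlink(missing_ok=True)


def read_score_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_score_table` ('#' lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_enrichment_table(results, path, config: dict | None = None) -> None:
    """Write enrichment results (iterable of EnrichmentResult) as a TSV."""
    rows = [
        {
            "set_name": r.name,
            "n_scored": r.n_scored,
            "median": r.median,
            "q25": r.q25,
            "q75": r.q75,
            "p_value": r.p_value,
            "comparison": r.comparison,
            "n_unresolved": r.n_unresolved,
        }
        for r in results
    ]
    write_score_table(pd.DataFrame(rows), path, config)


def reconcile_chrom_names(
    reference_names: set[str], names: set[str]
) -> dict[str, str]:
    """Map chromosome names onto the reference naming ("chr1" <-> "1" only).

    Returns a rename mapping for every name resolvable by adding or
    stripping a "chr" prefix; raises ``ValueError`` listing names that
    cannot be reconciled.
    """
    mapping: dict[str, str] = {}
    unresolved = []
    for name in names:
        if name in reference_names:
            continue
        flipped = name[3:] if name.startswith("chr") else f"chr{name}"
        if flipped in reference_names:
            mapping[name] = flipped
        else:
            unresolved.append(name)
    if unresolved:
        raise ValueError(
            "chromosome names not reconcilable with the genome: "
            + ", ".join(sorted(unresolved))
        )
    if mapping:
        log.info("reconciled chromosome names: %s", mapping)
    return mapping
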