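"""Gene-set enrichment of selection quantiles and two-score meta-combination.

A gene set's location in the genome-wide GIMS quantile distribution is
summarised by its median and interquartile range and tested against a
reference group (the complement of the set, or all scored genes) with the
two-sided Wilcoxon rank-sum test.  Because GIMS quantiles are uniform over
all genes by construction, a median well below 0.5 indicates enrichment of
negative selection in the set.

``combined_meta_score`` merges two per-gene quantile rankings (e.g. a
selection score and a cell-type expression-prediction score) by z-score
meta-analysis: each ranking is inverse-normal transformed (lower quantile =
stronger), Stouffer-combined unweighted, and re-expressed as a quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from gims.scoring import rank_to_z, requantile, _rowwise_stouffer

log = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "read_gene_sets",
    "wilcoxon_rank_sum",
    "set_summary",
    "enrich",
    "combined_meta_score",
]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (de-duplicated, order kept)."""

    name: str
    members: tuple[str, ...]

    @classmethod
    def from_ids(cls, name: str, ids: Iterable[str]) -> "GeneSet":
        seen: dict[str, None] = {}
        for g in ids:
            g = g.strip()
            if g:
                seen.setdefault(g, None)
        return cls(name, tuple(seen))


def read_gene_sets(path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members per line) or a
    plain one-ID-per-line list (one set, named after the file stem)."""
    path = Path(path)
    lines = [
        ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()
    ]
    if any("\t" in ln for ln in lines):
        sets = []
        for ln in lines:
            fields = ln.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: GMT line needs name, description and >=1 member"
                )
            sets.append(GeneSet.from_ids(fields[0], fields[2:]))
        return sets
    return [GeneSet.from_ids(path.stem, lines)]


@dataclass(frozen=True)
class EnrichmentResult:
    """Summary of one gene set's quantile distribution vs a reference."""

    name: str
    n_scored: int
    median: float
    q25: float
    q75: float
    p_value: float | None
    comparison: str
    n_unresolved: int = 0


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments.

    Average ranks are used, so ties are handled; p = min(1, 2 * min(P(T <=
    t_obs), P(T >= t_obs))) where T is the rank sum of a random subset of
    size len(x) from the pooled sample.
    """
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    n1 = len(x)
    t_obs = float(ranks[:n1].sum())
    total = 0
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for idx in combinations(range(len(pooled)), n1):
        t = float(ranks[list(idx)].sum())
        total += 1
        if t <= t_obs + eps:
            n_le += 1
        if t >= t_obs - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def wilcoxon_rank_sum(
    set_scores: Iterable[float],
    other_scores: Iterable[float],
    exact_max_n: int = 20,
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the pooled sample has at most ``exact_max_n``
    observations (handles ties via average ranks); otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(list(set_scores), dtype=float)
    y = np.asarray(list(other_scores), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size <= exact_max_n:
        return _exact_rank_sum_p(x, y)
    res = mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def _as_series(scores) -> pd.Series:
    """Normalise a score table to a Series gene_id -> quantile."""
    if isinstance(scores, pd.Series):
        return scores.astype(float)
    if isinstance(scores, pd.DataFrame):
        id_col = "unit_id" if "unit_id" in scores.columns else "gene_id"
        s = scores.set_index(id_col)["gims_quantile"].astype(float)
        return s[s.notna()]
    if isinstance(scores, Mapping):
        return pd.Series({k: float(v) for k, v in scores.items()})
    raise TypeError(f"unsupported score table type {type(scores)!r}")


def set_summary(gene_set: GeneSet, scores) -> EnrichmentResult:
    """Median and quartiles (linear-interpolation convention) of the set's
    quantiles; unresolved member IDs are counted and reported.

    Raises ``ValueError`` listing the unresolved IDs when no member
    resolves against the score table.
    """
    table = _as_series(scores)
    resolved = [g for g in gene_set.members if g in table.index]
    unresolved = [g for g in gene_set.members if g not in table.index]
    if not resolved:
        raise ValueError(
            f"gene set {gene_set.name!r}: no member resolves against the "
            f"score table (unresolved: {', '.join(unresolved)})"
        )
    if unresolved:
        log.warning(
            "gene set %s: %d unresolved member IDs (e.g. %s)",
            gene_set.name,
            len(unresolved),
            unresolved[0],
        )
    vals = table.loc[resolved].to_numpy(dtype=float)
    q25, med, q75 = np.percentile(vals, [25, 50, 75])  # linear interpolation
    return EnrichmentResult(
        name=gene_set.name,
        n_scored=len(resolved),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        p_value=None,
        comparison="none",
        n_unresolved=len(unresolved),
    )


def enrich(
    gene_set: GeneSet,
    scores,
    mode: str = "vs_complement",
    exact_max_n: int = 20,
) -> EnrichmentResult:
    """Gene-set enrichment: summary plus a two-sided rank-sum p-value.

    ``mode="vs_complement"`` tests member quantiles against all other
    scored genes; ``mode="vs_all"`` tests them against the full score table
    (members included, matching an "all genes as reference" convention).
    """
    if mode not in ("vs_complement", "vs_all"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    table = _as_series(scores)
    summary = set_summary(gene_set, scores)
    member_ids = [g for g in gene_set.members if g in table.index]
    member_scores = table.loc[member_ids].to_numpy(dtype=float)
    if mode == "vs_complement":
        other = table.drop(index=member_ids).to_numpy(dtype=float)
        if other.size == 0:
            raise ValueError(
                f"gene set {gene_set.name!r} covers every scored gene; "
                "vs_complement comparison is empty"
            )
    else:
        other = table.to_numpy(dtype=float)
    p = wilcoxon_rank_sum(member_scores, other, exact_max_n=exact_max_n)
    return EnrichmentResult(
        name=summary.name,
        n_scored=summary.n_scored,
        median=summary.median,
        q25=summary.q25,
        q75=summary.q75,
        p_value=p,
        comparison=mode,
        n_unresolved=summary.n_unresolved,
    )


def combined_meta_score(primary, secondary) -> pd.DataFrame:
    """Combine two per-gene quantile rankings by z-score meta-analysis.

    Genes missing either score are excluded.  Each surviving ranking is
    rank_to_z-transformed (lower quantile = stronger), the two z-scores are
    Stouffer-combined unweighted, and the combined z re-quantile-normalised.
    Returns a DataFrame with ``gene_id, z_combined, combined_quantile``
    (lower = jointly stronger), sorted by gene_id.  Symmetric in its two
    inputs.
    """
    p = _as_series(primary)
    s = _as_series(secondary)
    shared = sorted(set(p.index) & set(s.index))
    if len(shared) < 2:
        raise ValueError(
            f"need >= 2 genes scored by both tables, got {len(shared)}"
        )
    dropped = (len(p.index) - len(shared)) + (len(s.index) - len(shared))
    if dropped:
        log.info(
            "combined score: %d shared genes, %d table entries dropped",
            len(shared),
            dropped,
        )
    z1 = rank_to_z(p.loc[shared].to_numpy(), higher_is_stronger=False)
    z2 = rank_to_z(s.loc[shared].to_numpy(), higher_is_stronger=False)
    z = _rowwise_stouffer(
        np.column_stack([z1, z2]), np.ones((len(shared), 2))
    )
    z_norm = requantile(z)
    ranks = rankdata(z_norm, method="average")
    quant = (ranks - 0.5) / len(shared)
    return pd.DataFrame(
        {"gene_id": shared, "z_combined": z_norm, "combined_quantile": quant}
    )
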