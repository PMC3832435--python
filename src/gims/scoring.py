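"""Rank-based hierarchical Stouffer combination into GIMS/TIMS quantiles.

Every metric is converted to a standard-normal z-score via its rank:
units are ordered so that rank 1 = strongest selection, the quantile
``q = (rank - 0.5) / N`` is taken over non-missing units (half-offset grid,
so no unit maps to 0 or 1 and the inverse normal CDF stays finite), and
``z = Phi^{-1}(q)``.  More negative z therefore always means stronger
selection, and ties share their average rank.

The hierarchy:

1. each of the four metrics is rank-normalised *within* each CpG stratum,
   the two stratum z-scores are Stouffer-combined per unit with
   sqrt(site-count) weights, and the result re-quantile-normalised —
   removing the CpG-content confound before metrics are mixed;
2. conservation + functional -> "functional genomic" branch z;
3. SNV density + rare fraction -> "population genetic" branch z;
4. the two branch z-scores -> final z, whose rank quantile is the
   GIMS (per gene) or TIMS (per transcript) score.

Each combination step is followed by re-quantile-normalisation, so every
level is again exactly standard-normal in rank distribution.  A unit
missing one branch entirely is scored from the surviving branch alone
(single-entry Stouffer) and flagged incomplete.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from gims.metrics import STRATA, GeneMetrics

log = logging.getLogger(__name__)

__all__ = [
    "METRIC_DIRECTIONS",
    "rank_to_z",
    "stouffer",
    "requantile",
    "combine_strata",
    "compute_scores",
    "compute_gims",
    "compute_tims",
]

#: metric -> does a larger raw value mean stronger selection?
METRIC_DIRECTIONS = {
    "conservation": True,  # more conserved
    "functional": True,  # more damaging substitutions available
    "density": False,  # depleted segregating sites
    "frac_rare": True,  # rarer frequency spectrum
}


def _as_float_array(values: Iterable) -> np.ndarray:
    arr = np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    return arr


def rank_to_z(values: Iterable, higher_is_stronger: bool) -> np.ndarray:
    """Rank-quantile-z transform with missing passthrough.

    ``values`` may contain ``None``/NaN (missing stays missing).  Units are
    ranked so rank 1 = strongest selection, ties get average ranks, and
    ``z = Phi^{-1}((rank - 0.5) / N)`` over the N non-missing units.
    Raises ``ValueError`` with fewer than 2 non-missing values.
    """
    arr = _as_float_array(values)
    mask = np.isfinite(arr)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"need >= 2 non-missing values to rank, got {n}")
    effective = -arr[mask] if higher_is_stronger else arr[mask]
    ranks = rankdata(effective, method="average")
    q = (ranks - 0.5) / n
    # evaluate the inverse CDF on the lower tail and mirror, so that
    # Phi^{-1}(1-q) == -Phi^{-1}(q) exactly and symmetric combinations of
    # tied ranks cancel to exactly zero
    zq = np.where(q <= 0.5, ndtri(np.minimum(q, 0.5)), -ndtri(1.0 - np.maximum(q, 0.5)))
    z = np.full(arr.shape, np.nan)
    z[mask] = zq
    return z


def requantile(z: Iterable) -> np.ndarray:
    """Re-quantile-normalise combined z-scores (lower z = stronger)."""
    return rank_to_z(z, higher_is_stronger=False)


def stouffer(
    z_list: Iterable, weights: Iterable | None = None
) -> float:
    """Stouffer's weighted z combination: sum(w*z) / sqrt(sum(w^2)).

    Missing entries (None/NaN) are dropped together with their weights; a
    single surviving entry returns itself.  Returns NaN when everything is
    missing.  Weights must be non-negative with at least one positive among
    the surviving entries.
    """
    z = _as_float_array(z_list)
    w = (
        np.ones_like(z)
        if weights is None
        else _as_float_array(weights)
    )
    if w.shape != z.shape:
        raise ValueError("weights and z-scores differ in length")
    if np.any(w[np.isfinite(w)] < 0):
        raise ValueError("weights must be non-negative")
    mask = np.isfinite(z) & np.isfinite(w) & (w > 0)
    if not mask.any():
        return float("nan")
    zs, ws = z[mask], w[mask]
    return float(np.sum(ws * zs) / np.sqrt(np.sum(ws**2)))


def _rowwise_stouffer(z_cols: np.ndarray, w_cols: np.ndarray) -> np.ndarray:
    """Vectorised per-row Stouffer over columns; all-missing rows give NaN."""
    mask = np.isfinite(z_cols) & np.isfinite(w_cols) & (w_cols > 0)
    zs = np.where(mask, z_cols, 0.0)
    ws = np.where(mask, w_cols, 0.0)
    denom = np.sqrt(np.sum(ws**2, axis=1))
    out = np.full(z_cols.shape[0], np.nan)
    ok = denom > 0
    out[ok] = np.sum(ws * zs, axis=1)[ok] / denom[ok]
    return out


def combine_strata(
    values_by_stratum: dict[str, Iterable],
    counts_by_stratum: dict[str, Iterable],
    higher_is_stronger: bool,
    stratum_weighting: str = "sqrt_sites",
) -> np.ndarray:
    """CpG-stratified rank combination of one metric across units.

    Each stratum's raw values are first rank_to_z-normalised across units
    *within that stratum*, then per unit the stratum z-scores are
    Stouffer-combined (weights: sqrt of the stratum's site count, or equal
    under ``stratum_weighting="equal"``), and the combined values are
    re-quantile-normalised across units.  Units missing both strata stay
    missing.
    """
    strata = list(values_by_stratum)
    z_cols, w_cols = [], []
    for s in strata:
        vals = _as_float_array(values_by_stratum[s])
        counts = _as_float_array(counts_by_stratum[s])
        if np.isfinite(vals).sum() >= 2:
            z_cols.append(rank_to_z(vals, higher_is_stronger))
        else:
            # a stratum with <2 scored units carries no rankable signal
            z_cols.append(np.full(vals.shape, np.nan))
        if stratum_weighting == "sqrt_sites":
            w_cols.append(np.sqrt(np.where(np.isfinite(counts), counts, 0.0)))
        elif stratum_weighting == "equal":
            w_cols.append(np.ones_like(vals))
        else:
            raise ValueError(f"unknown stratum_weighting {stratum_weighting!r}")
    combined = _rowwise_stouffer(
        np.column_stack(z_cols), np.column_stack(w_cols)
    )
    if np.isfinite(combined).sum() < 2:
        return combined
    return requantile(combined)


def compute_scores(
    metrics: Sequence[GeneMetrics],
    stratum_weighting: str = "sqrt_sites",
    branch_weights: tuple[float, float] = (1.0, 1.0),
) -> pd.DataFrame:
    """Run the full hierarchy on a set of scoring units.

    Returns a DataFrame sorted by ``unit_id`` with the raw stratified
    metrics, the per-metric combined z-scores, the two branch z-scores
    (``z_funcgen``, ``z_popgen``), ``z_final`` and ``gims_quantile``
    (the (rank - 0.5)/N quantile of ``z_final``; lower = stronger
    selection), plus completeness flags for each branch.
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 scorable units")
    metrics = sorted(metrics, key=lambda m: m.unit_id)
    ids = [m.unit_id for m in metrics]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit_ids in metrics")

    counts = {
        s: [m.n_nd_sites.get(s, 0) for m in metrics] for s in STRATA
    }
    raw = {
        "conservation": {
            s: [m.mean_conservation.get(s) for m in metrics] for s in STRATA
        },
        "functional": {
            s: [m.mean_functional.get(s) for m in metrics] for s in STRATA
        },
        "density": {
            s: [m.snv_per_kb.get(s) for m in metrics] for s in STRATA
        },
        "frac_rare": {
            s: [m.frac_rare.get(s) for m in metrics] for s in STRATA
        },
    }

    z_metric = {
        name: combine_strata(
            raw[name], counts, METRIC_DIRECTIONS[name], stratum_weighting
        )
        for name in raw
    }

    w1, w2 = branch_weights
    z_funcgen = _branch(
        z_metric["conservation"], z_metric["functional"], w1, w2
    )
    z_popgen = _branch(z_metric["density"], z_metric["frac_rare"], w1, w2)
    z_final = _branch(z_funcgen, z_popgen, w1, w2)

    quantile = np.full(len(ids), np.nan)
    mask = np.isfinite(z_final)
    if mask.sum() >= 1:
        ranks = rankdata(z_final[mask], method="average")
        quantile[mask] = (ranks - 0.5) / mask.sum()

    out = pd.DataFrame({"unit_id": ids, "gene_id": [m.gene_id for m in metrics]})
    for s in STRATA:
        out[f"n_nd_sites_{s}"] = counts[s]
    for name, source in (
        ("mean_conservation", "conservation"),
        ("mean_functional", "functional"),
        ("snv_per_kb", "density"),
        ("frac_rare", "frac_rare"),
    ):
        for s in STRATA:
            out[f"{name}_{s}"] = _as_float_array(raw[source][s])
    out["z_conservation"] = z_metric["conservation"]
    out["z_functional"] = z_metric["functional"]
    out["z_density"] = z_metric["density"]
    out["z_rare"] = z_metric["frac_rare"]
    out["z_funcgen"] = z_funcgen
    out["z_popgen"] = z_popgen
    out["z_final"] = z_final
    out["gims_quantile"] = quantile
    out["complete_funcgen"] = np.isfinite(z_metric["conservation"]) & np.isfinite(
        z_metric["functional"]
    )
    out["complete_popgen"] = np.isfinite(z_metric["density"]) & np.isfinite(
        z_metric["frac_rare"]
    )
    n_unscored = int((~np.isfinite(z_final)).sum())
    if n_unscored:
        log.info("%d units left unscored (all metrics missing)", n_unscored)
    return out


def _branch(za: np.ndarray, zb: np.ndarray, wa: float, wb: float) -> np.ndarray:
    combined = _rowwise_stouffer(
        np.column_stack([za, zb]),
        np.column_stack(
            [np.full_like(za, float(wa)), np.full_like(zb, float(wb))]
        ),
    )
    if np.isfinite(combined).sum() < 2:
        return combined
    return requantile(combined)


def compute_gims(metrics: Sequence[GeneMetrics], **kwargs) -> pd.DataFrame:
    """Gene-level scores: call with one metrics record per gene (the gene's
    longest transcript as its scoring unit, ``unit_id`` = gene id)."""
    return compute_scores(metrics, **kwargs)


def compute_tims(metrics: Sequence[GeneMetrics], **kwargs) -> pd.DataFrame:
    """Transcript-level scores: identical machinery with transcripts as
    units (no longest-transcript collapsing)."""
    return compute_scores(metrics, **kwargs)
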