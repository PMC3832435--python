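"""Independent brute-force oracles used only by the tests.

Everything here is deliberately written without gims.scoring's tools:
ranking by explicit pairwise comparison counts, the inverse normal CDF by
bisecting an erf-based CDF, and the score hierarchy as plain loops.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq


def inv_norm_cdf(q: float) -> float:
    """Phi^{-1}(q) by root-finding on the erf-based normal CDF.

    Evaluated on the lower tail and mirrored, so Phi^{-1}(1-q) is exactly
    -Phi^{-1}(q): analytically tied symmetric combinations must cancel
    exactly rather than leave sign-arbitrary rounding residue.
    """
    if q == 0.5:
        return 0.0
    if q > 0.5:
        return -inv_norm_cdf(1.0 - q)
    return brentq(
        lambda x: 0.5 * (1.0 + math.erf(x / math.sqrt(2.0))) - q,
        -10.0,
        0.0,
        xtol=1e-15,
    )


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def bf_rank_to_z(values, higher_is_stronger: bool) -> list[float]:
    """Average-rank quantile-z transform by explicit comparison counting."""
    idx = [i for i, v in enumerate(values) if not _is_missing(v)]
    eff = [(-values[i] if higher_is_stronger else values[i]) for i in idx]
    n = len(eff)
    out = [math.nan] * len(values)
    for k, a in enumerate(eff):
        less = sum(1 for b in eff if b < a)
        equal = sum(1 for b in eff if b == a)
        rank = less + (equal + 1) / 2.0
        out[idx[k]] = inv_norm_cdf((rank - 0.5) / n)
    return out


def bf_stouffer(zs, ws) -> float:
    pairs = [(z, w) for z, w in zip(zs, ws) if not _is_missing(z) and w > 0]
    if not pairs:
        return math.nan
    num = sum(w * z for z, w in pairs)
    den = math.sqrt(sum(w * w for _, w in pairs))
    return num / den


def bf_requantile(zs) -> list[float]:
    return bf_rank_to_z(zs, higher_is_stronger=False)


def bf_pipeline(metrics) -> dict[str, float]:
    """Full hierarchy on a list of GeneMetrics, as plain loops.

    Mirrors the published procedure: per-metric within-stratum rank-z,
    sqrt(site-count)-weighted Stouffer across CpG strata + renormalise,
    branch combinations (unweighted) + renormalise, final quantile grid.
    Returns unit_id -> quantile.
    """
    metrics = sorted(metrics, key=lambda m: m.unit_id)
    strata = ("cpg", "noncpg")
    directions = {
        "mean_conservation": True,
        "mean_functional": True,
        "snv_per_kb": False,
        "frac_rare": True,
    }
    z_metric = {}
    for name, higher in directions.items():
        z_by_stratum = {}
        for s in strata:
            vals = [getattr(m, name).get(s) for m in metrics]
            n_ok = sum(0 if _is_missing(v) else 1 for v in vals)
            if n_ok >= 2:
                z_by_stratum[s] = bf_rank_to_z(vals, higher)
            else:
                z_by_stratum[s] = [math.nan] * len(vals)
        combined = []
        for i, m in enumerate(metrics):
            zs = [z_by_stratum[s][i] for s in strata]
            ws = [math.sqrt(m.n_nd_sites.get(s, 0)) for s in strata]
            combined.append(bf_stouffer(zs, ws))
        z_metric[name] = bf_requantile(combined)

    def branch(a, b):
        merged = [
            bf_stouffer([a[i], b[i]], [1.0, 1.0]) for i in range(len(metrics))
        ]
        return bf_requantile(merged)

    z_funcgen = branch(z_metric["mean_conservation"], z_metric["mean_functional"])
    z_popgen = branch(z_metric["snv_per_kb"], z_metric["frac_rare"])
    z_final = branch(z_funcgen, z_popgen)

    idx = [i for i, z in enumerate(z_final) if not _is_missing(z)]
    n = len(idx)
    quantiles = {}
    for k in idx:
        less = sum(1 for j in idx if z_final[j] < z_final[k])
        equal = sum(1 for j in idx if z_final[j] == z_final[k])
        rank = less + (equal + 1) / 2.0
        quantiles[metrics[k].unit_id] = (rank - 0.5) / n
    return quantiles


#: the standard genetic code, written out literally for oracle independence
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def bf_degeneracy(codon: str, pos_in_codon: int) -> int:
    """Degeneracy fold by translating all three substitutions."""
    i = pos_in_codon - 1
    aa = CODON_TABLE[codon]
    same = 1
    for base in "ACGT":
        if base == codon[i]:
            continue
        mutant = codon[:i] + base + codon[i + 1 :]
        if CODON_TABLE[mutant] == aa:
            same += 1
    return 0 if same == 1 else same
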