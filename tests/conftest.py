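import numpy as np
import pandas as pd
import pytest

from gims.annotation import TranscriptModel, build_coding_sites
from gims.metrics import GeneMetrics, STRATA


@pytest.fixture
def toy_genome():
    """12 nt plus-strand toy chromosome: ATG TGG CGA AAA.

    The CG dinucleotide at positions 7-8 makes position 8 the single
    CpG non-degenerate site; positions 1-6, 10, 11 are non-CpG
    non-degenerate; position 7 is 2-fold, 9 is 4-fold, 12 is 2-fold.
    """
    return {"chrT": "ATGTGGCGAAAA"}


@pytest.fixture
def toy_transcript():
    return TranscriptModel(
        gene_id="GTOY",
        transcript_id="GTOY.T1",
        chrom="chrT",
        strand="+",
        cds_intervals=((0, 12),),
        cds_length=12,
    )


@pytest.fixture
def toy_sites(toy_transcript, toy_genome):
    return build_coding_sites(toy_transcript, toy_genome)


def make_metrics(unit_id, cons, func, dens, rare, n_cpg=50, n_noncpg=200,
                 gene_id=None):
    """GeneMetrics with the same raw value in both strata (test helper)."""
    return GeneMetrics(
        unit_id=unit_id,
        gene_id=gene_id or unit_id,
        n_nd_sites={"cpg": n_cpg, "noncpg": n_noncpg},
        mean_conservation={s: cons for s in STRATA},
        conservation_coverage={s: 1.0 for s in STRATA},
        mean_functional={s: func for s in STRATA},
        n_snvs={s: 10 for s in STRATA},
        snv_per_kb={s: dens for s in STRATA},
        n_common={s: 5 for s in STRATA},
        frac_rare={s: rare for s in STRATA},
    )


def random_metrics(n_units, rng, missing_rate=0.0):
    """Random, tie-free GeneMetrics for property tests."""
    out = []
    for i in range(n_units):
        def slot():
            return {
                s: (None if rng.random() < missing_rate else float(rng.normal()))
                for s in STRATA
            }
        frac = {
            s: (None if rng.random() < missing_rate else float(rng.random()))
            for s in STRATA
        }
        dens = {
            s: (None if rng.random() < missing_rate else float(10 * rng.random()))
            for s in STRATA
        }
        out.append(
            GeneMetrics(
                unit_id=f"U{i:04d}",
                gene_id=f"U{i:04d}",
                n_nd_sites={"cpg": int(rng.integers(5, 80)),
                            "noncpg": int(rng.integers(50, 400))},
                mean_conservation=slot(),
                conservation_coverage={s: 1.0 for s in STRATA},
                mean_functional={
                    s: (None if rng.random() < missing_rate else float(rng.random()))
                    for s in STRATA
                },
                n_snvs={s: 10 for s in STRATA},
                snv_per_kb=dens,
                n_common={s: 5 for s in STRATA},
                frac_rare=frac,
            )
        )
    return out


@pytest.fixture(scope="session")
def small_simulation(tmp_path_factory):
    """A 40-gene simulated dataset shared across file-based tests."""
    from gims.simulate import SimulationConfig, simulate

    outdir = tmp_path_factory.mktemp("sim40")
    config = SimulationConfig(seed=11, n_genes=40)
    paths = simulate(config, outdir)
    return config, paths
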