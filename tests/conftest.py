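"""Shared fixtures: one calibrated population and one HMM fit per session.

The full-size population (7 generations, 836 animals, 2 x 100 Mb
chromosomes, ~2,200 QC-passed SNPs) and its cluster-HMM fit are expensive,
so they are built once and shared by every test that needs study-scale
data; small helper populations are built inline by the tests that use them.
"""

import numpy as np
import pytest

import pedgwas as pg


@pytest.fixture(scope="session")
def population():
    """Calibrated 836-animal population after QC, with kinship pieces."""
    ped, raw = pg.simulate_population(seed=11)
    kept, report = pg.qc_filter(raw)
    rel = pg.relationship_and_inbreeding(ped)
    pos = {a: i for i, a in enumerate(ped.ids)}
    amap = np.asarray([pos[a] for a in kept.animal_ids])
    A = rel.A[np.ix_(amap, amap)]
    eig = pg.eigendecompose(A)
    return {
        "pedigree": ped,
        "raw": raw,
        "panel": kept,
        "report": report,
        "rel": rel,
        "amap": amap,
        "A": A,
        "eig": eig,
    }


@pytest.fixture(scope="session")
def hmm(population):
    """Cluster-HMM fit (K=20) of the session panel; 12 EM sweeps."""
    model, dosages, imputed = pg.fit_haplotype_hmm(
        population["panel"], K=20, n_em_iter=12, seed=0
    )
    return {"model": model, "dosages": dosages, "imputed": imputed}


@pytest.fixture(scope="session")
def small_population():
    """Three-generation, ~100-animal population for cheap integration tests."""
    sizes = ((8, 12), (10, 15), (20, 30))
    ped, raw = pg.simulate_population(
        seed=5, generation_sizes=sizes, snps_per_chrom=120,
        chrom_length_bp=20_000_000,
    )
    kept, _ = pg.qc_filter(raw)
    rel = pg.relationship_and_inbreeding(ped)
    pos = {a: i for i, a in enumerate(ped.ids)}
    amap = np.asarray([pos[a] for a in kept.animal_ids])
    A = rel.A[np.ix_(amap, amap)]
    return {
        "pedigree": ped,
        "panel": kept,
        "rel": rel,
        "amap": amap,
        "A": A,
        "eig": pg.eigendecompose(A),
    }
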