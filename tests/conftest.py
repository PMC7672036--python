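import numpy as np
import pandas as pd
import pytest

from pghaplo import SimulationConfig, SnpTable, TargetLocus, simulate_family


def make_table(positions, calls, depths=None, ref="G", alt="A"):
    """Build a small SnpTable; calls maps sample -> list of genotype tuples.

    Roles default to father/mother/reference by those names, everything else
    an embryo.  Depths default to 30 everywhere.
    """
    n = len(positions)
    sites = pd.DataFrame(
        {"chrom": "chrX", "pos": positions, "ref": [ref] * n, "alt": [alt] * n}
    )
    if depths is None:
        depths = {s: np.full(n, 30, dtype=np.int64) for s in calls}
    roles = {}
    for s in calls:
        roles[s] = s if s in ("father", "mother", "reference") else "embryo"
    return SnpTable(sites=sites, calls=calls, depths=depths, roles=roles)


@pytest.fixture(scope="session")
def toy_locus():
    return TargetLocus(
        chrom="chrX",
        gene_start=1_000_000,
        gene_end=1_010_000,
        mutation_pos=1_005_000,
        mutation_ref="G",
        mutation_alt="A",
        window_flank=1_000_000,
        reference_status="affected",
    )


@pytest.fixture(scope="session")
def clean_family():
    """Noise-free simulated family: no ADO/ADI/failure/recombination."""
    cfg = SimulationConfig(
        n_snps=120,
        ado_rate=0.0,
        adi_rate=0.0,
        sample_fail_rate=0.0,
        recomb_rate_per_mb=0.0,
        n_embryos=6,
        seed=11,
    )
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def noisy_family():
    """Family under the default study conditions (seeded)."""
    cfg = SimulationConfig(seed=23)
    return simulate_family(cfg)
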