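import numpy as np
import pandas as pd
import pytest

from hybridgs import SimConfig, build_model_kernels, simulate_study
from hybridgs.genotypes import ParentPanel


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study shared by read-only tests."""
    cfg = SimConfig(
        n_females=10,
        n_males=10,
        n_loci=240,
        n_chromosomes=4,
        n_crosses=60,
        n_envs=3,
        seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def obs_crosses(small_study):
    d = small_study.design.crosses
    return list(zip(d["female_id"], d["male_id"]))


@pytest.fixture(scope="session")
def small_kernels(small_study, obs_crosses):
    return build_model_kernels(
        small_study.females,
        small_study.males,
        obs_crosses,
        pathway_mask=small_study.truth.pathway_mask,
    )


def make_panel(alleles, role="female", chrom=None, prefix="P"):
    """Hand-built panel helper for unit tests."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n, L = alleles.shape
    loci = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["Chr01"] * L,
            "pos": np.arange(1, L + 1) * 100,
            "id": [f"s{j}" for j in range(L)],
        }
    )
    ids = [f"{prefix}{i + 1}" for i in range(n)]
    return ParentPanel(ids, role, alleles, loci)
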