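import numpy as np
import pandas as pd
import pytest

from snpdisparity.io import PairedArrayData
from snpdisparity.simulate import SimulationConfig, simulate


def make_paired(
    blood_baf,
    tumour_baf=None,
    blood_lrr=None,
    tumour_lrr=None,
    chromosomes=None,
    positions=None,
    genes=None,
    cytobands=None,
    sample_ids=None,
    locus_ids=None,
) -> PairedArrayData:
    """Build a PairedArrayData from plain nested lists (NaN for missing)."""
    blood_baf = np.asarray(blood_baf, dtype=float)
    r, c = blood_baf.shape
    locus_ids = locus_ids or [f"rs{i:04d}" for i in range(r)]
    sample_ids = sample_ids or [f"s{j:02d}" for j in range(c)]
    idx = pd.Index(locus_ids, name="locus_id")

    def mat(values, default):
        if values is None:
            values = np.full((r, c), default, dtype=float)
        return pd.DataFrame(np.asarray(values, dtype=float), index=idx, columns=sample_ids)

    loci = pd.DataFrame(
        {
            "chromosome": chromosomes or ["1"] * r,
            "position": positions or [1000 * (i + 1) for i in range(r)],
            "allele_a": ["A"] * r,
            "allele_b": ["G"] * r,
            "gene": genes or [None] * r,
            "cytoband": cytobands or [None] * r,
        },
        index=idx,
    )
    data = PairedArrayData(
        loci=loci,
        blood_baf=mat(blood_baf, 0.5),
        tumour_baf=mat(tumour_baf if tumour_baf is not None else blood_baf.copy(), 0.5),
        blood_lrr=mat(blood_lrr, 0.0),
        tumour_lrr=mat(tumour_lrr, 0.0),
    ).sorted()
    data.validate()
    return data


@pytest.fixture(scope="session")
def sim_cohort():
    """A small seeded cohort with planted shifts and CNA segments."""
    config = SimulationConfig(n_loci=1200, n_samples=60, n_chromosomes=6, seed=11)
    return simulate(config)


@pytest.fixture(scope="session")
def sim_null_cohort():
    """A seeded cohort with no planted events (null conditions)."""
    config = SimulationConfig(
        n_loci=1500, n_samples=80, n_chromosomes=6,
        disparity_fraction=0.0, cna_segments=[], missing_rate=0.0, seed=23,
    )
    return simulate(config)
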