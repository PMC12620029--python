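import numpy as np
import pandas as pd
import pytest

from haplopop.core import GenotypeMatrix, SampleSheet, SHEET_COLUMNS


def make_gm(dosages, ploidy, positions=None, contigs=None, compartment="nuclear",
            depth=None, ad_ref=None, ad_alt=None, haploid_het=None, samples=None):
    """Small genotype matrices for tests from plain lists."""
    dosages = np.asarray(dosages, dtype=np.int16)
    n_samples, n_loci = dosages.shape
    if positions is None:
        positions = np.arange(1, n_loci + 1) * 10
    if contigs is None:
        contigs = ["ctg1"] * n_loci
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    return GenotypeMatrix(
        samples=samples,
        contigs=np.array(contigs, dtype=object),
        positions=np.asarray(positions),
        ref=np.array(["A"] * n_loci, dtype=object),
        alt=np.array(["T"] * n_loci, dtype=object),
        dosages=dosages,
        ploidy=np.asarray(ploidy, dtype=np.int8),
        compartment=compartment,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        ad_ref=None if ad_ref is None else np.asarray(ad_ref, dtype=np.int32),
        ad_alt=None if ad_alt is None else np.asarray(ad_alt, dtype=np.int32),
        haploid_het=None if haploid_het is None else np.asarray(haploid_het, dtype=bool),
    )


def make_sheet(samples, populations, ploidy=None, source_pool=None, lat=None, lon=None):
    n = len(samples)
    table = pd.DataFrame({
        "sample": samples,
        "population": populations,
        "region": ["r"] * n,
        "source_pool": source_pool if source_pool is not None else ["-"] * n,
        "lat": lat if lat is not None else [50.0] * n,
        "lon": lon if lon is not None else [10.0] * n,
        "ploidy": ploidy if ploidy is not None else [2] * n,
    })
    return SampleSheet(table[SHEET_COLUMNS])


@pytest.fixture
def gm_factory():
    return make_gm


@pytest.fixture
def sheet_factory():
    return make_sheet
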