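import numpy as np
import pytest

from pfda_audit import refdata
from pfda_audit.datasets import ClassRule, Dataset, TaxonRecord, partition


@pytest.fixture(scope="session")
def diver_subset():
    return refdata.femoral_diver_subset()


def _terrestrial_records(n=12, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        recs.append(
            TaxonRecord(
                taxon_id=f"terr_{i}",
                md_mm=float(np.exp(rng.normal(2.5, 0.5))),
                cg=float(rng.uniform(0.4, 0.8)),
                fly_code="0",
                dive_code="0",
                status="extant",
            )
        )
    return recs


@pytest.fixture
def mixed_dataset(diver_subset):
    """Small two-class dataset: a few real divers plus synthetic terrestrials."""
    recs = list(diver_subset.records[:12]) + _terrestrial_records()
    return Dataset("mixed", recs)


@pytest.fixture
def mixed_partition(mixed_dataset):
    return partition(mixed_dataset, ClassRule("F0D0_vs_F0D2"))
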