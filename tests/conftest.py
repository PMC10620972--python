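import numpy as np
import pandas as pd
import pytest

from fblmm.io import GenotypeMatrix, Pedigree, PedigreeRecord


def make_genotypes(dosages, sample_prefix="s", variant_prefix="v"):
    """GenotypeMatrix from a plain array, synthetic metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    ids = [f"{variant_prefix}{j}" for j in range(p)]
    variants = pd.DataFrame(
        {"chrom": ["1"] * p, "pos": np.arange(1, p + 1),
         "a1": ["A"] * p, "a2": ["G"] * p},
        index=pd.Index(ids, name="variant"),
    )
    samples = [f"{sample_prefix}{i}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


@pytest.fixture
def trio_pedigree():
    return Pedigree(records=[
        PedigreeRecord("dad", "F1", None, None),
        PedigreeRecord("mum", "F1", None, None),
        PedigreeRecord("kid", "F1", "dad", "mum"),
    ])


@pytest.fixture
def two_family_pedigree():
    """A nuclear-2 family and an MZ twin family."""
    recs = []
    for fam, mz in (("F1", None), ("F2", "tw")):
        recs += [
            PedigreeRecord(f"{fam}_f", fam, None, None),
            PedigreeRecord(f"{fam}_m", fam, None, None),
            PedigreeRecord(f"{fam}_c1", fam, f"{fam}_f", f"{fam}_m", mz_group=mz),
            PedigreeRecord(f"{fam}_c2", fam, f"{fam}_f", f"{fam}_m", mz_group=mz),
        ]
    return Pedigree(records=recs)
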