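import numpy as np
import pandas as pd
import pytest

from germdiv.io_formats import MarkerGenotypes, PhenotypeTrial


@pytest.fixture
def tiny_trial() -> PhenotypeTrial:
    """3 genotypes x 2 blocks, one trait, with known sums of squares
    (SS_g = 4, SS_b = 6, SS_e = 0)."""
    rows = [
        ("g1", "b1", "t1", 1.0),
        ("g1", "b2", "t1", 3.0),
        ("g2", "b1", "t1", 2.0),
        ("g2", "b2", "t1", 4.0),
        ("g3", "b1", "t1", 3.0),
        ("g3", "b2", "t1", 5.0),
    ]
    return PhenotypeTrial(pd.DataFrame(rows, columns=["genotype", "block", "trait", "value"]))


@pytest.fixture
def het_hom_pair() -> MarkerGenotypes:
    """Two individuals at one locus: one 160/260 heterozygote and one
    160/160 homozygote (allele freqs 0.75 / 0.25)."""
    calls = np.array([[[160, 260]], [[160, 160]]])
    return MarkerGenotypes(["ind1", "ind2"], ["popA", "popA"], ["HK5"], calls)


@pytest.fixture
def fixed_difference_pops() -> MarkerGenotypes:
    """2 populations x 3 individuals x 1 locus with population-fixed
    alternative homozygotes: all variation lies among populations."""
    calls = np.zeros((6, 1, 2), dtype=int)
    calls[:3] = [[100, 100]]
    calls[3:] = [[102, 102]]
    ids = [f"i{k}" for k in range(6)]
    return MarkerGenotypes(ids, ["A"] * 3 + ["B"] * 3, ["L1"], calls)
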