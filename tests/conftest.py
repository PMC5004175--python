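import numpy as np
import pytest

from pgpkit import phylo, pk


@pytest.fixture
def verapamil_group_params() -> pk.PKParams:
    """One-compartment parameters of the inhibitor-co-treatment group."""
    return pk.PKParams(ka=2.08, ke=0.25, v_f=1.96)


@pytest.fixture
def oral_dose() -> pk.DoseRegimen:
    return pk.DoseRegimen(dose=10.0)


@pytest.fixture
def additive_4taxon() -> phylo.DistanceMatrix:
    """Additive distances from the tree ((A:2,B:3):4,C:3,D:4) — NJ must
    recover it exactly."""
    d = np.array([[0, 5, 9, 10],
                  [5, 0, 10, 11],
                  [9, 10, 0, 7],
                  [10, 11, 7, 0]], dtype=float)
    return phylo.DistanceMatrix(("A", "B", "C", "D"), d)


@pytest.fixture
def two_clade_alignment() -> phylo.MultipleAlignment:
    """Two internally identical clades differing at 40% of sites."""
    return phylo.MultipleAlignment(
        ("A", "B", "C", "D"),
        ("AAAAAAAAAA", "AAAAAAAAAA", "TTTTAAAAAA", "TTTTAAAAAA"))
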