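import numpy as np
import pytest

from phrkit import synthetic
from phrkit.records import Msa


@pytest.fixture(scope="session")
def reference():
    return synthetic.synthetic_phrsph98_reference()


@pytest.fixture(scope="session")
def planted_family(reference):
    """The 55-homolog / 94-decoy family mirroring the published screen size."""
    design = synthetic.FamilyDesign(reference=reference, n_true=55, n_decoy=94,
                                    substitution_rate=0.05, seed=1)
    records, labels = synthetic.gen_protein_family(design)
    return design, records, labels


@pytest.fixture(scope="session")
def family_msa(reference, planted_family):
    _, records, _ = planted_family
    return Msa([reference.id] + [r.id for r in records],
               [reference.sequence] + [r.sequence for r in records])


@pytest.fixture(scope="session")
def operon_truth():
    design = synthetic.OperonDesign(seed=11)
    seq, truth = synthetic.gen_operon_sequence(design)
    return design, seq, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
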