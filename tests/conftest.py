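import numpy as np
import pytest

from tcemrep.sequence_io import AA20, RepertoireDataset, SequenceRecord

#: Background alphabet without W: planted motifs carrying W can then never
#: arise by chance from background residues.
ALPHABET_NO_W = AA20.replace("W", "")


def random_record(rng, rec_id, length, alphabet=AA20, **kwargs):
    residues = "".join(rng.choice(list(alphabet), size=length))
    return SequenceRecord(id=rec_id, residues=residues, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240541)


@pytest.fixture
def toy_dataset(rng):
    """Small random repertoire (12 records x 40 residues) for oracle tests."""
    records = [random_record(rng, f"rec{i}", 40) for i in range(12)]
    return RepertoireDataset(records=records)


@pytest.fixture
def worked_example_pair():
    """The co-centred worked-example peptide pair (single S->T difference)."""
    return "FSNYAIHWVRQAPGQ", "FTNYAIHWVRQAPGQ"


@pytest.fixture
def small_repertoire():
    """Simulated repertoire with ground truth, shared across tests."""
    from tcemrep.synthetic_repertoire import (
        SHMParameters,
        make_germline_library,
        simulate_repertoire,
    )

    library = make_germline_library(6, length=130, n_families=2, seed=11)
    params = SHMParameters(base_rate=0.05, seed=11)
    return simulate_repertoire(library, 40, params)
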