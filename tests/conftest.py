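import numpy as np
import pytest
from hypothesis import settings

from sirnadeep.records_io import SiRNARecord, reverse_complement
from sirnadeep.synthetic_data import SyntheticSpec, generate
from sirnadeep.thermo import NNParameterTable, load_default_params

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nn_params():
    return load_default_params()


@pytest.fixture(scope="session")
def placeholder_params():
    """Flat parameter table with a single distinguishable AA step value."""
    step_dg = {a + b: 0.0 for a in "ACGU" for b in "ACGU"}
    step_dg["AA"] = -0.9
    return NNParameterTable(step_dg=step_dg, init_dg=0.0)


def make_record(rid="r1", binding="AUGCAUGCAUGCAUGCAUGCA", flank_up="", flank_down="", efficacy=0.5):
    context = flank_up + binding + flank_down
    return SiRNARecord(
        id=rid,
        guide_seq=reverse_complement(binding),
        target_context=context,
        binding_offset=len(flank_up),
        efficacy=efficacy,
    )


@pytest.fixture
def simple_record():
    return make_record()


@pytest.fixture(scope="session")
def small_synth(nn_params):
    """120 records with planted motif + thermo signal; flanks of 10 nt."""
    spec = SyntheticSpec(n_records=120, flank_n=10, motif="GCGAUC", seed=42)
    records, truth = generate(spec, nn_params)
    return records, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
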