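import pytest

from curlikin import ChargeEnvelope, SpeciesDefinition


@pytest.fixture
def monomer():
    return SpeciesDefinition("monomer", 13000.0, 1)


@pytest.fixture
def dimer():
    return SpeciesDefinition("dimer", 26000.0, 2, ("monomer", "monomer"))


@pytest.fixture
def clean_envelopes():
    """Monomer/dimer envelopes with no m/z coincidences.

    A dimer charge 2z collides with the monomer at z; these ranges keep
    {z/2 : z even in dimer range} disjoint from the monomer range so every
    peak is unambiguous.
    """
    return {
        "monomer": ChargeEnvelope(z_min=12, z_max=16, z_mode=14, width=2.0),
        "dimer": ChargeEnvelope(z_min=19, z_max=23, z_mode=21, width=1.5),
    }
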