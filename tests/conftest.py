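import pytest

from chromlip import (
    compute_descriptors,
    descriptor_sheet,
    experimental_logp_inputs,
    load_tlc_standards,
    load_triazole_panel,
    parse_structure,
)


@pytest.fixture(scope="session")
def panel():
    """(compound_id, smiles) pairs for the fifteen triazole-aniline
    derivatives."""
    return load_triazole_panel()


@pytest.fixture(scope="session")
def panel_mols(panel):
    return {cid: parse_structure(smi, cid) for cid, smi in panel}


@pytest.fixture(scope="session")
def panel_descs(panel):
    """Descriptor sets for the panel with the experimental logP attached
    (one Open Babel batch call for the whole session)."""
    return descriptor_sheet(panel, logp_inputs=experimental_logp_inputs())


@pytest.fixture(scope="session")
def standards():
    return load_tlc_standards()
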