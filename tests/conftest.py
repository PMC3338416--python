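import pandas as pd
import pytest

from diviss.io import load_oncoscore_reference
from diviss.simulate import CampaignConfig, generate_library, pad_annotation_panel


@pytest.fixture(scope="session")
def oncoscore_reference():
    """The published 42-protein high-OncoScore panel with regulation flags."""
    return load_oncoscore_reference()


@pytest.fixture(scope="session")
def target_panel_115(oncoscore_reference):
    """The 42-protein reference padded with synthetic low-score targets to
    the 115-protein size of a tumor-unique list."""
    return pad_annotation_panel(oncoscore_reference, 115, seed=11)


@pytest.fixture(scope="session")
def small_campaign():
    """A small but complete synthetic campaign shared across tests."""
    config = CampaignConfig(n_compounds=300, seed=42)
    library, truth = generate_library(config)
    return config, library, truth


def smiles_table(path, rows):
    """Write a compound TSV from (id, smiles) pairs; returns the path."""
    pd.DataFrame(rows, columns=["id", "smiles"]).to_csv(path, sep="\t", index=False)
    return path
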