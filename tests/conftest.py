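import numpy as np
import pytest

from coloscreen.stains import load_reference_estimate
from coloscreen.synthetic import TissuePhenotype, render_tissue


@pytest.fixture(scope="session")
def reference_estimate():
    return load_reference_estimate()


@pytest.fixture(scope="session")
def negative_tissue():
    """A benign mucosa rendering: thin-rimmed glands, no atypia."""
    phen = TissuePhenotype(
        class_label="negative",
        gland_count=10,
        rim_thickness_nuclei=1.2,
        stratification=0.0,
        dissociated_cell_density=0.0,
        nuclear_size_um=7.0,
        seed=7,
    )
    return render_tissue(phen)


@pytest.fixture(scope="session")
def signet_tissue():
    """Gland-free dissociated-cell carcinoma rendering."""
    phen = TissuePhenotype(
        class_label="carcinoma",
        gland_count=0,
        rim_thickness_nuclei=1.0,
        stratification=0.0,
        dissociated_cell_density=1.0,
        nuclear_size_um=10.0,
        seed=8,
    )
    return render_tissue(phen)
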