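import logging

import pyfaidx
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# arm-length warnings from oligo assembly are expected on synthetic panels
logging.getLogger("mipseq.panel").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sim_reference(tmp_path_factory):
    """Small 3-gene synthetic reference + exon BED, loaded via pyfaidx."""
    from mipseq.simulate import make_reference

    out = tmp_path_factory.mktemp("ref")
    fa, bed = make_reference(
        str(out), n_genes=3, exons_per_gene=2, exon_len_range=(150, 260), seed=2
    )
    return pyfaidx.Fasta(fa), bed


@pytest.fixture(scope="session")
def sim_panel(sim_reference):
    """Designed panel + padded targets over the session reference."""
    from mipseq.panel import DesignParams, design_panel, load_targets

    ref, bed = sim_reference
    targets = load_targets(bed, pad=20, reference=ref)
    panel, rejections = design_panel(ref, targets, DesignParams())
    assert not rejections
    return panel, targets
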