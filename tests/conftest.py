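import numpy as np
import pytest

import blineage as bl


@pytest.fixture(scope="session")
def reference_config():
    return bl.ReferenceConfig(cells_per_population=200, seed=42)


@pytest.fixture(scope="session")
def healthy_reference(reference_config):
    return bl.generate_reference_bm(reference_config)


@pytest.fixture(scope="session")
def fitted_classifier(healthy_reference):
    return bl.DevClassifier().fit(healthy_reference)


@pytest.fixture(scope="session")
def toy_gene():
    from blineage.synthetic import default_toy_gene

    return default_toy_gene()


@pytest.fixture
def twelve_read_fixture(toy_gene):
    """Hand-constructed reads around intron 0 (400, 700) of the toy gene.

    Expected tally for intron 0: I = overlap = 4 (r4, r5, r6, r12),
    S = 2 (r3, r10), flanking-exon = 3 (r1, r2, r11); r7, r8, r9 are
    deliberately uninformative edge cases for intron 0.
    """
    reads = [
        ("r1", ((150, 200),)),                 # inside exon 0 -> flank
        ("r2", ((800, 850),)),                 # inside exon 1 -> flank
        ("r3", ((350, 400), (700, 750))),      # exact junction -> S
        ("r4", ((380, 430),)),                 # crosses left boundary -> I
        ("r5", ((500, 550),)),                 # inside intron -> I
        ("r6", ((650, 720),)),                 # crosses right boundary -> I
        ("r7", ((200, 250), (800, 850))),      # gap covers intron, not exact
        ("r8", ((900, 1000), (1400, 1450))),   # exact junction of intron 1
        ("r9", ((1100, 1150),)),               # inside intron 1
        ("r10", ((350, 400), (700, 750))),     # second exact junction -> S
        ("r11", ((100, 150),)),                # inside exon 0 -> flank
        ("r12", ((395, 420),)),                # crosses left boundary -> I
    ]
    return bl.AlignmentSet(reads=reads, sample_id="hand12", reference_length=2500)
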