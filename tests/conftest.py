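import pytest

from lupusgrs import GenotypeCounts

# Genotype counts from the reference cohort analysis (hom-ref, het, hom-alt).
SLE_COUNTS = (109, 111, 26)
CONTROL_COUNTS = (119, 82, 15)
# gnomAD non-Finnish European genotype proportions at the same locus.
GNOMAD_NFE = (0.533, 0.394, 0.073)


@pytest.fixture
def sle_counts() -> GenotypeCounts:
    return GenotypeCounts(*SLE_COUNTS)


@pytest.fixture
def control_counts() -> GenotypeCounts:
    return GenotypeCounts(*CONTROL_COUNTS)
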