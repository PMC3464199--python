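import pytest

from tetradgc import load_reference_data


@pytest.fixture(scope="session")
def reference():
    """Bundled alleles and counts of the genome-wide screen."""
    alleles, counts = load_reference_data()
    return {
        "alleles": {a.allele_name: a for a in alleles},
        "counts": {c.label: c for c in counts},
        "counts_list": counts,
        "panel": [c for c in counts if c.genome_panel],
    }
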