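import pytest

from mitocirc import (
    GeneratorConfig,
    build_gene_table,
    generate_genome,
    reference_annotation,
    reference_codon_counts,
)


@pytest.fixture(scope="session")
def ref_annotation():
    """The shipped vulture-mitogenome annotation (coordinates only)."""
    return reference_annotation()


@pytest.fixture(scope="session")
def ref_rows(ref_annotation):
    return build_gene_table(ref_annotation)


@pytest.fixture(scope="session")
def ref_counts():
    """The shipped 64-codon counts of the reference mitogenome PCGs."""
    return reference_codon_counts()


@pytest.fixture(scope="session")
def default_genome():
    """One synthetic raptor-arrangement genome with its planted truth."""
    return generate_genome(GeneratorConfig(seed=11))
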