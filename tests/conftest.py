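import pytest

from venus import CohortSpec, ProteinContext, generate_patient
from venus.synthetic import CODONS_BY_AA


def make_cds(protein: str, stop: str = "TAA") -> str:
    """Back-translate a protein with each residue's first codon."""
    return "".join(CODONS_BY_AA[aa][0] for aa in protein) + stop


def make_context(protein: str, transcript_id: str = "TX1") -> ProteinContext:
    return ProteinContext(
        transcript_id=transcript_id, protein_seq=protein, cds_seq=make_cds(protein)
    )


@pytest.fixture(scope="session")
def small_bundle():
    """One modest synthetic patient shared across integration tests."""
    spec = CohortSpec(seed=11, n_variants_per_patient=60, n_implanted_true=3)
    return generate_patient(spec, 0)
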