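import pytest

from gofish.iupac import revcomp
from gofish.refpanel import Alignment, ReferencePanel, ReferenceSequence
from gofish.synth import MIFISH_U_F, MIFISH_U_R, SynthPanelSpec, generate_panel


@pytest.fixture
def toy_panel() -> ReferencePanel:
    """Two hand-built references carrying the broad-range primer sites."""
    return ReferencePanel(
        [
            ReferenceSequence(
                id="R1",
                taxon="Pomatomus saltatrix",
                common_name="bluefish",
                group="bony_fish",
                sequence=MIFISH_U_F + "ACGTAC" * 10 + revcomp(MIFISH_U_R),
            ),
            ReferenceSequence(
                id="R2",
                taxon="Morone saxatilis",
                common_name="striped bass",
                group="bony_fish",
                sequence=MIFISH_U_F + "TTGCAA" * 10 + revcomp(MIFISH_U_R),
            ),
        ]
    )


@pytest.fixture(scope="session")
def synth_default():
    """The seeded default synthetic panel (12 species + 1 twin pair)."""
    spec = SynthPanelSpec(seed=7)
    panel, aln, truth = generate_panel(spec)
    return spec, panel, aln, truth


@pytest.fixture
def toy_alignment() -> Alignment:
    return Alignment(
        {
            "a": "ACGTACGTAC",
            "b": "ACGTACGTAC",
            "c": "ACGTTCGTAC",
            "d": "ACGTTCGAAC",
        }
    )
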