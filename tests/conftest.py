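import pytest

from milkstone import default_panel
from milkstone.panel import ProteinRecord, ReferencePanel


@pytest.fixture(scope="session")
def panel():
    """Bundled synthetic six-species BLG panel (session-cached; its
    peptidome build is the expensive part)."""
    return default_panel()


@pytest.fixture(scope="session")
def toy_records():
    """Three species on a three-level taxonomy with hand-built sequences:
    SPAAR/SPBBR shared by the CladeA pair, SPCCR only in Sp3, GGGWWK
    everywhere, and one private peptide per species."""
    mk = lambda acc, sp, clade, seq: ProteinRecord(
        acc, sp, ("Root", clade, sp), seq
    )
    return [
        mk("T1", "Sp1", "CladeA", "GGGWWKSPAARFFFYYK"),
        mk("T2", "Sp2", "CladeA", "GGGWWKSPAARHHHSSK"),
        mk("T3", "Sp3", "CladeB", "GGGWWKSPCCRMMMTTK"),
    ]


@pytest.fixture(scope="session")
def toy_panel(toy_records):
    return ReferencePanel(
        toy_records, min_len=5, max_len=20, min_mass=100.0, max_mass=5000.0
    )
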