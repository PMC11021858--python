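import numpy as np
import pytest

from scatdna.config import RunConfig
from scatdna.io import ReferenceRecord


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def refdb() -> list[ReferenceRecord]:
    """Tiny reference database with distinguishable taxa.

    Sequences are built on a shared 60-nt backbone with taxon-specific
    blocks so identities between different species fall well below 90%,
    except the two deer which are identical (a genus-level ambiguity) and a
    near-wolf variant one substitution away.
    """
    rng = np.random.default_rng(1234)

    def random_seq(n=60):
        return "".join(rng.choice(list("ACGT"), size=n))

    wolf = random_seq()
    deer = random_seq()
    otter = random_seq()
    return [
        ReferenceRecord("r1", wolf, "Canis lupus", "Canis", "Canidae"),
        ReferenceRecord("r2", otter, "Enhydra lutris", "Enhydra", "Mustelidae"),
        ReferenceRecord("r3", deer, "Odocoileus hemionus", "Odocoileus", "Cervidae"),
        ReferenceRecord("r4", deer, "Odocoileus virginianus", "Odocoileus", "Cervidae"),
        ReferenceRecord("r5", random_seq(), "Microtus pennsylvanicus",
                        "Microtus", "Cricetidae"),
    ]
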