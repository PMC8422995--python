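import numpy as np
import pytest

from discrimsc import (
    MeltingParams,
    PromoterRecord,
    SynthConfig,
    TranscriptionParams,
    generate_promoters,
)

# fixed non-repetitive context so bubble edits are the only variable
_CONTEXT = "ACGTTGCAGATCCATGGTACCAGTCGACTTAGGCATCGTAAGCTTGGATCCACGTGCAGTCCTAGACGTTA"


@pytest.fixture
def mp() -> MeltingParams:
    return MeltingParams()


@pytest.fixture
def tp() -> TranscriptionParams:
    return TranscriptionParams()


def build_promoter(
    bubble: str | None = None,
    disc: str | None = None,
    pid: str = "P",
    up: int = 50,
    down: int = 20,
    minus10_offset: int = -12,
) -> PromoterRecord:
    """Promoter with a fixed context and a chosen bubble or discriminator.

    ``bubble`` replaces the 14 bases at internal offsets
    [minus10_offset, minus10_offset+13]; ``disc`` replaces the 5 bases at
    internal offsets [-4, 0].
    """
    seq = list((_CONTEXT * ((up + down) // len(_CONTEXT) + 2))[: up + down + 1])
    seq[minus10_offset + up : minus10_offset + up + 6] = "TATAAT"
    if bubble is not None:
        assert len(bubble) == 14
        seq[minus10_offset + up : minus10_offset + up + 14] = bubble
    if disc is not None:
        assert len(disc) == 5
        seq[up - 4 : up + 1] = disc
    return PromoterRecord(
        id=pid, seq="".join(seq), up=up, minus10_offset=minus10_offset
    )


@pytest.fixture(scope="session")
def default_promoters():
    """A mid-sized draw from the default generator conditions."""
    return generate_promoters(SynthConfig(n_promoters=400, seed=5))


@pytest.fixture(scope="session")
def random_bubble_promoters():
    """1000 promoters with uniformly random 14-mer bubbles."""
    rng = np.random.default_rng(42)
    proms = []
    for i in range(1000):
        bubble = "".join(rng.choice(list("ACGT"), size=14))
        proms.append(build_promoter(bubble=bubble, pid=f"R{i:04d}"))
    return proms
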