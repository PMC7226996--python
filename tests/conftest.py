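"""Shared fixtures: the documented study-condition seed and tRNA reference builders."""

import numpy as np
import pytest

from ripte.editing import TrnaReference

#: fixed documented seed used for all study-condition checks
SEED = 20200410


@pytest.fixture(scope="session")
def seed() -> int:
    return SEED


def make_trna_reference(
    name: str, anticodon: str, length: int = 76, wobble: int = 34, rng_seed: int = 7
) -> TrnaReference:
    """Synthetic tRNA-like reference with the anticodon placed at the wobble offset.

    The first anticodon base (position ``wobble``) must be A for an ADAT
    substrate; sequence context is random but reproducible.
    """
    rng = np.random.default_rng(rng_seed)
    seq = list(rng.choice(list("ACGT"), size=length))
    seq[wobble - 1 : wobble + 2] = list(anticodon)
    return TrnaReference(name, "".join(seq), wobble)


@pytest.fixture(scope="session")
def trna_refs() -> list[TrnaReference]:
    """Two ADAT-substrate references (Ser-AGA, Val-AAC) with distinct contexts."""
    return [
        make_trna_reference("tRNASerAGA", "AGA", rng_seed=7),
        make_trna_reference("tRNAValAAC", "AAC", rng_seed=11),
    ]
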