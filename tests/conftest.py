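from __future__ import annotations

import numpy as np
import pytest

from genicmark.io_formats import SpeciesPanel, TranscriptSeq

BASES = "ACGT"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def four_species_panel() -> SpeciesPanel:
    return SpeciesPanel(
        {"INC_1": "INC", "AET_1": "AET", "MEL_1": "MEL", "TOR_1": "TOR"}
    )


@pytest.fixture
def transcript_factory():
    def make(seq: str, tid: str = "T1") -> TranscriptSeq:
        return TranscriptSeq(id=tid, seq=seq)

    return make
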