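import numpy as np
import pytest

from m6apipe.coverage import TranscriptModel
from m6apipe.simulate import generate_transcriptome, plant_peaks


@pytest.fixture(scope="session")
def small_transcriptome():
    """20 transcripts with RRACH peaks planted near stop codons."""
    models, seqs = generate_transcriptome(20, (300, 2000), seed=7)
    truth, seqs = plant_peaks(models, seqs, peak_rate=1.0, motif="RRACH",
                              stop_bias=0.8, peak_width=150, gamma=8.0, seed=7)
    return models, seqs, truth


@pytest.fixture
def toy_model():
    """300 nt leader + 600 nt CDS + 300 nt UTR."""
    return TranscriptModel("TOY.1", 1200, 300, 900, gene_id="TOY")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
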