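import pytest

from g4rep.seq_io import LabeledSequence, SequenceDataset


@pytest.fixture
def toy_dataset():
    return SequenceDataset(
        [
            LabeledSequence("p1", "RGGRGGRGGYFS", label=1),
            LabeledSequence("p2", "ACDEFGHIKLMN", label=0),
            LabeledSequence("p3", "MKVLAWHEDTNC", label=0),
        ]
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """A small seeded synthetic dataset shared by several test modules."""
    from g4rep.synthetic import SynthConfig, generate_dataset

    return generate_dataset(SynthConfig(n_pos=30, n_neg=30, length_range=(60, 120), seed=7))
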