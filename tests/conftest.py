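import numpy as np
import pytest

from cytosuc import EventTable, PanelConfig, asinh_transform

CHANNELS = [
    "Ir191", "Ir193",
    "Pd104", "Pd106", "Pd108", "Pd110",
    "panAkt", "totalERK",
    "m1", "m2", "m3", "m4",
]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def panel():
    return PanelConfig(
        dna_channels=["Ir191", "Ir193"],
        barcode_channels=["Pd104", "Pd106", "Pd108", "Pd110"],
        n_top_barcodes=2,
        antibody_suc_markers=["panAkt", "totalERK"],
        markers_to_correct=["m1", "m2", "m3", "m4"],
        sample_column="sample",
        asinh_cofactor=5.0,
    )


def make_raw_table(rng, n_per_sample=150, samples=("lineA", "lineB")):
    """Raw table whose markers genuinely covary with a latent size factor."""
    n = n_per_sample * len(samples)
    size = rng.lognormal(0.0, 0.4, n)
    cols = []
    for i, name in enumerate(CHANNELS):
        base = rng.lognormal(1.5 + 0.1 * i, 0.3, n)
        cols.append(base * size ** (0.5 + 0.1 * (i % 4)))
    values = np.column_stack(cols)
    labels = np.array([s for s in samples for _ in range(n_per_sample)], dtype=object)
    return EventTable(values, list(CHANNELS), labels, transform_state="raw")


@pytest.fixture
def raw_table(rng):
    return make_raw_table(rng)


@pytest.fixture
def asinh_table(raw_table):
    return asinh_transform(raw_table, 5.0)
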