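import numpy as np
import pandas as pd
import pytest

from menzerath import CallTable


def make_table(sequences, context="c", individual="ind1"):
    """Build a CallTable from {sequence_id: [durations]} (positions 1..n).

    ``sequences`` may also map to (individual_id, [durations]) tuples.
    """
    rows = {k: [] for k in ("context", "individual_id", "sequence_id", "position", "duration_s")}
    for seq_id, val in sequences.items():
        ind, durs = val if isinstance(val, tuple) else (individual, val)
        for i, d in enumerate(durs, start=1):
            rows["context"].append(context)
            rows["individual_id"].append(ind)
            rows["sequence_id"].append(str(seq_id))
            rows["position"].append(i)
            rows["duration_s"].append(float(d))
    return CallTable(pd.DataFrame(rows))


@pytest.fixture
def tiny_table():
    return make_table({"s1": [0.2, 0.25, 0.18], "s2": [0.3, 0.22], "s3": [0.27]})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
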