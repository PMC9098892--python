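import numpy as np
import pandas as pd
import pytest

SESSIONS = ["B1", "B2", "3d", "6d", "9d", "12d", "15d", "18d"]
BASELINES = ["B1", "B2"]


def make_table(codes: dict[str, list[int]], sessions=None, length_um=60.0,
               morph="mushroom", dendrite_id="d0") -> pd.DataFrame:
    """Build a long-format spine table from explicit presence codes.

    ``codes`` maps spine_id -> binary vector over ``sessions``. Rows are
    emitted from each spine's first 1 onward, as the trackers would record.
    """
    sessions = sessions or SESSIONS
    rows = []
    for spine_id, code in codes.items():
        ones = [i for i, v in enumerate(code) if v]
        start = ones[0] if ones else 0
        for i in range(start, len(code)):
            rows.append(
                {
                    "animal_id": "a1",
                    "dendrite_id": dendrite_id,
                    "dendrite_length_um": length_um,
                    "spine_id": spine_id,
                    "session": sessions[i],
                    "present": int(code[i]),
                    "morph_type": morph if code[i] else np.nan,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def sessions():
    return list(SESSIONS)


@pytest.fixture
def baselines():
    return list(BASELINES)
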