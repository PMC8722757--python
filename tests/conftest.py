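import numpy as np
import pandas as pd
import pytest

from splicediversity import ExpressionTable, SampleGroups, TranscriptGeneMap


@pytest.fixture
def small_expression():
    """Three genes: two isoforms (one all-zero in sample s2), a
    single-isoform gene, and a three-isoform gene."""
    values = pd.DataFrame(
        {
            "s1": [10.0, 10.0, 5.0, 1.0, 1.0, 2.0],
            "s2": [0.0, 0.0, 7.0, 3.0, 3.0, 3.0],
        },
        index=pd.Index(
            ["g1-t1", "g1-t2", "g2-t1", "g3-t1", "g3-t2", "g3-t3"],
            name="transcript_id",
        ),
    )
    return ExpressionTable(values=values, unit="TPM")


@pytest.fixture
def small_txmap():
    return TranscriptGeneMap(
        pd.Series(
            ["g1", "g1", "g2", "g3", "g3", "g3"],
            index=["g1-t1", "g1-t2", "g2-t1", "g3-t1", "g3-t2", "g3-t3"],
        )
    )


@pytest.fixture
def two_groups():
    return SampleGroups(
        assignment=pd.Series(
            ["A", "A", "A", "B", "B", "B"],
            index=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
    )
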