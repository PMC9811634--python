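import numpy as np
import pandas as pd
import pytest

from reefcontests.encounters import COLUMNS


def enc(
    focal="sp_a",
    partner="sp_b",
    *,
    period="before",
    prox=1,
    outcome="passive",
    dist=np.nan,
    fid="f1",
    reef="r1",
    region="R1",
):
    """One encounter row with convenient defaults."""
    return (region, reef, period, fid, focal, partner, prox, outcome, dist)


def make_records(rows) -> pd.DataFrame:
    """Assemble encounter tuples (see :func:`enc`) into a canonical DataFrame."""
    return pd.DataFrame(list(rows), columns=COLUMNS)


def pair_block(a, b, n, *, start_id=0, period="before", reef="r1", distinct_ids=None, **kw):
    """n encounters of pair (a, b); ``distinct_ids`` controls how many focal fish."""
    ids = distinct_ids if distinct_ids is not None else n
    return [
        enc(a, b, fid=f"{a}-{b}-i{start_id + (j % ids)}", period=period, reef=reef, **kw)
        for j in range(n)
    ]


@pytest.fixture
def toy_records():
    """Small mixed table: one chase, one signal, passives, two periods."""
    rows = [
        enc("sp_a", "sp_a", prox=1, outcome="passive", fid="f1"),
        enc("sp_a", "sp_b", prox=2, outcome="signal", fid="f1"),
        enc("sp_a", "sp_b", prox=3, outcome="chase", dist=2.5, fid="f2"),
        enc("sp_b", "sp_b", prox=4, outcome="passive", fid="f3", period="after"),
    ]
    return make_records(rows)
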