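import numpy as np
import pytest

from rsinet.cohort import ITEM_LABELS, CohortTable
from rsinet.synthetic import SyntheticSpec


@pytest.fixture
def tiny_csv(tmp_path):
    """Three complete participants plus one with a missing Q5."""
    header = "participant_id," + ",".join(ITEM_LABELS) + ",return_status"
    rows = [
        "a1," + ",".join(["60"] * 12) + ',"Yes, at the same or higher level compared to before injury"',
        "a2," + ",".join(["80"] * 12) + ',"No"',
        "a3," + ",".join(["40"] * 12) + ',"Yes, training only"',
    ]
    incomplete = ["a4"] + ["50"] * 12 + ['"No"']
    incomplete[5] = ""  # Q5 empty
    path = tmp_path / "cohort.csv"
    path.write_text("\n".join([header] + rows + [",".join(incomplete)]) + "\n")
    return path


def small_spec(p=4, n_A=60, n_B=60, edges=None, edges_B=None, seed=0,
               mean=60.0, sd=20.0, round_scores=True):
    """Compact synthetic spec for fast tests: p items, flat marginals."""
    P_A = np.zeros((p, p))
    for (i, j), w in (edges or {}).items():
        P_A[i, j] = P_A[j, i] = w
    if edges_B is None:
        P_B = P_A.copy()
    else:
        P_B = np.zeros((p, p))
        for (i, j), w in edges_B.items():
            P_B[i, j] = P_B[j, i] = w
    labels = tuple(f"Q{i + 1}" for i in range(p))
    m = np.full(p, mean)
    s = np.full(p, sd)
    return SyntheticSpec(
        p=p, n_A=n_A, n_B=n_B, P_A=P_A, P_B=P_B,
        means_A=m, sds_A=s, means_B=m, sds_B=s,
        seed=seed, item_labels=labels, round_scores=round_scores,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(items, returned=None, labels=None):
    items = np.asarray(items, dtype=float)
    n, p = items.shape
    if returned is None:
        returned = np.zeros(n, dtype=bool)
    if labels is None:
        labels = tuple(f"Q{i + 1}" for i in range(p))
    return CohortTable(items=items, returned=np.asarray(returned, bool),
                       item_labels=labels)
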