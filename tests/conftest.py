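import numpy as np
import pandas as pd
import pytest

from hapshift.containers import ASVTable


def make_table(counts: dict, samples: dict, sequences: dict | None = None) -> ASVTable:
    """Build a small ASVTable from dict-of-dicts counts and sample metadata.

    ``counts[asv][sample]`` -> count; ``samples[sample]`` -> (site, replicate,
    is_negative).  Sequences default to arbitrary distinct 60-mers.
    """
    sample_ids = list(samples)
    df = pd.DataFrame(
        {s: {a: counts[a].get(s, 0) for a in counts} for s in sample_ids}
    ).T.T
    df = df[sample_ids].astype(int)
    meta = pd.DataFrame(
        [
            {
                "site_id": site,
                "replicate": rep,
                "is_negative_control": neg,
                "marker": "COI",
            }
            for site, rep, neg in samples.values()
        ],
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if sequences is None:
        rng = np.random.default_rng(0)
        sequences = {
            a: "".join("ACGT"[i] for i in rng.integers(0, 4, 60)) for a in counts
        }
    return ASVTable(counts=df, sequences=sequences, samples=meta)


@pytest.fixture
def three_site_table() -> ASVTable:
    """3 sites x 3 replicates + 2 negatives, 4 ASVs with varied patterns."""
    samples = {}
    for s in ("A", "B", "C"):
        for r in (1, 2, 3):
            samples[f"{s}{r}"] = (s, r, False)
    samples["N1"] = ("NEG", 1, True)
    samples["N2"] = ("NEG", 2, True)
    counts = {
        # present in >=2 replicates of site A
        "asv1": {"A1": 50, "A2": 40, "B1": 5},
        # one replicate per site everywhere
        "asv2": {"A1": 9, "B2": 7, "C3": 4},
        # in 2 replicates of C, also in negatives
        "asv3": {"C1": 12, "C2": 30, "N1": 3, "N2": 5},
        # negatives only
        "asv4": {"N1": 8},
    }
    return make_table(counts, samples)
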