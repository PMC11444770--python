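import numpy as np
import pandas as pd
import pytest

from nucint.synthetic import ApmsSimConfig, ImageSimConfig, generate_apms_counts


def make_observations(rows):
    """Build an observation table from (protein_id, tag, rep, ip, nac, cov) tuples."""
    return pd.DataFrame(
        [(p, t, r, "nuclear", ip, nac, cov) for p, t, r, ip, nac, cov in rows],
        columns=["protein_id", "tag", "replicate", "fraction",
                 "ip_peptide_count", "nac_peptide_count", "ip_coverage_pct"],
    )


@pytest.fixture
def six_sample_table():
    """Bait + two preys observed across the full 2-tag x 3-replicate design."""
    rows = []
    for tag in ("GFP", "HA"):
        for rep in (1, 2, 3):
            rows.append(("Moesin", tag, rep, 60, 4, 55.0))
            rows.append(("preyA", tag, rep, 10, 5, 50.0))
            rows.append(("preyB", tag, rep, 2, 2, 20.0))
    return make_observations(rows)


@pytest.fixture(scope="session")
def noiseless_apms():
    config = ApmsSimConfig(deterministic=True, dropout_prob=0.0, seed=11)
    return config, *generate_apms_counts(config)


def match_calls_to_truth(cells, truth):
    """Per-truth-cell call by nearest detected nucleus centroid."""
    calls = []
    for rec in truth.cell_labels:
        d = np.hypot(cells["centroid_row"] - rec["row"],
                     cells["centroid_col"] - rec["col"])
        calls.append((rec["label"], cells.iloc[int(d.idxmin())]["call"]))
    return calls
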