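import pytest

from hbugkit.qc import TranscriptRecord
from hbugkit.synthetic import (
    SimConfig,
    gen_alignment_table,
    gen_counts,
    gen_transcripts,
    vector_matches_from_truth,
)


@pytest.fixture(scope="session")
def sim_config():
    """Study-condition fixture configuration: four samples, mixed tiers,
    planted fold changes (incl. zero-expression sentinel cases)."""
    return SimConfig(
        seed=11,
        n_transcripts=200,
        polyA_prob=0.5,
        vector_prob=0.2,
        tier_mix=(0.3, 0.3, 0.3, 0.1),
        zero_expr_frac=0.05,
        de_spec=(
            (0, 4.0, "female:male"),
            (1, 4.0, "adults:nymphs"),
            (2, 0.25, "4th:2nd"),
            (3, 8.0, "female:male"),
        ),
    )


@pytest.fixture(scope="session")
def fixture_set(sim_config):
    """One fully generated fixture bundle shared across tests."""
    records, truth = gen_transcripts(sim_config)
    hits = gen_alignment_table(truth, sim_config)
    counts, lengths = gen_counts(truth, sim_config)
    return {
        "config": sim_config,
        "records": [TranscriptRecord(i, s) for i, s in records],
        "truth": truth,
        "matches": vector_matches_from_truth(truth),
        "hits": hits,
        "counts": counts,
        "lengths": lengths,
    }
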