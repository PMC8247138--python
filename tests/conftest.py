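import numpy as np
import pytest

from microdyn import (AnalysisConfig, LongitudinalCountTable, SampleRecord,
                      SyntheticDesign, generate, filter_rare, scale_counts,
                      wisconsin_sqrt, within_subject_series)


def make_table(counts, subjects, days, diets=None, phases=None, asv_ids=None):
    """Small hand-built LongitudinalCountTable."""
    counts = np.asarray(counts)
    n_asv, n_s = counts.shape
    asv_ids = asv_ids or [f"ASV{i}" for i in range(n_asv)]
    diets = diets or ["FV"] * n_s
    phases = phases or ["outbound"] * n_s
    samples = [SampleRecord(sample_id=f"{s}_d{d}", subject_id=s, day=d,
                            diet=diet, phase=ph)
               for s, d, diet, ph in zip(subjects, days, diets, phases)]
    return LongitudinalCountTable(asv_ids, samples, counts)


@pytest.fixture
def tiny_table():
    # 3 ASVs x 4 samples: 2 subjects x 2 days
    return make_table(
        [[10, 0, 5, 1], [0, 20, 5, 2], [3, 3, 0, 7]],
        subjects=["s1", "s1", "s2", "s2"], days=[1, 30, 1, 30])


@pytest.fixture(scope="session")
def default_design():
    return SyntheticDesign(seed=11)


@pytest.fixture(scope="session")
def default_run(default_design):
    """One default synthetic draw with the standard preprocessing applied,
    shared across tests (generation is deterministic)."""
    table, tree = generate(default_design)
    filtered = filter_rare(table)
    transformed = wisconsin_sqrt(scale_counts(filtered))
    within = within_subject_series(transformed, "bray_curtis")
    return {"table": table, "tree": tree, "filtered": filtered,
            "transformed": transformed, "within": within}


@pytest.fixture(scope="session")
def small_design():
    """Reduced universe for plumbing tests where only structure matters."""
    return SyntheticDesign(n_stable_asvs=40, n_transient_asvs=80,
                           n_driver_asvs=3, seed=4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
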