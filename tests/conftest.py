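import numpy as np
import pytest

from clonotrack.clonotypes import merge_replicates
from clonotrack.simulate import CohortConfig, generate_cohort, generate_sc_dataset
from clonotrack.types import BetaKey, Repertoire


def make_repertoire(counts: dict, **labels) -> Repertoire:
    """Repertoire from {name: count}; names become minimal beta keys."""
    rep = Repertoire(**labels)
    for name, count in counts.items():
        key = name if isinstance(name, BetaKey) else BetaKey(str(name), "TRBV1", "TRBJ1")
        rep.clonotypes[key] = count
    return rep


def merged_samples(repertoires):
    """Merge technical replicates; keyed by (donor, subset, timepoint)."""
    groups = {}
    for r in repertoires:
        groups.setdefault((r.donor, r.subset, r.timepoint), []).append(r)
    out = {}
    for key, members in groups.items():
        m = members[0]
        for other in members[1:]:
            m = merge_replicates(m, other)
        out[key] = m
    return out


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down cohort for mechanics tests (fast, 2 donors, 2 timepoints)."""
    return CohortConfig(
        n_donors=2,
        clones_per_subset=150,
        timepoints=("T0", "T1"),
        bulk_depth=6000,
        cells_per_cluster=40,
        n_genes=150,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_sc(small_cfg, small_cohort):
    return generate_sc_dataset(small_cfg, small_cohort)


@pytest.fixture(scope="session")
def study_cfg():
    """The study-design defaults used for synthetic-recovery checks."""
    return CohortConfig(seed=11)


@pytest.fixture(scope="session")
def study_cohort(study_cfg):
    return generate_cohort(study_cfg)


@pytest.fixture(scope="session")
def study_sc(study_cfg, study_cohort):
    return generate_sc_dataset(study_cfg, study_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
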