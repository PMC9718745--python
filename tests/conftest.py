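import pytest
from hypothesis import HealthCheck, settings

from cisvelem.synthetic_data import CohortSpec, generate_study_set

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """The default 252-gene synthetic study set at seed 42, with its
    on-disk files (promoters.fasta, genes.tsv, truth tables)."""
    out = tmp_path_factory.mktemp("cohort42")
    spec = CohortSpec(seed=42)
    records, expr, truths = generate_study_set(spec, out_dir=out)
    return {
        "spec": spec,
        "dir": out,
        "records": records,
        "expr": expr,
        "truths": truths,
        "truth_by_id": {t.gene_id: t for t in truths},
    }


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 30-gene cohort for fast end-to-end tests."""
    out = tmp_path_factory.mktemp("cohort_small")
    spec = CohortSpec(seed=5, n_genes=30)
    records, expr, truths = generate_study_set(spec, out_dir=out)
    return {
        "spec": spec,
        "dir": out,
        "records": records,
        "expr": expr,
        "truths": truths,
        "truth_by_id": {t.gene_id: t for t in truths},
    }
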