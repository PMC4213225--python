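import pytest

import amivalid as av


@pytest.fixture(scope="session")
def study_cohort():
    """Deterministic reconstruction of the published study's margins."""
    return av.study_flow_cohort(seed=0)


@pytest.fixture(scope="session")
def study_summary(study_cohort, tmp_path_factory):
    """Full pipeline summary computed once over the study-shaped cohort."""
    outdir = tmp_path_factory.mktemp("study_run")
    return av.run_stages(study_cohort.claims, study_cohort.charts, outdir)


@pytest.fixture(scope="session")
def recovery_cohort():
    """One large generated cohort shared by the stochastic-recovery tests."""
    config = av.GeneratorConfig(n_patients=20000, seed=20260926)
    return config, av.generate_cohort(config)
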