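import pytest

from phenostat import RunConfig, SyntheticConfig, generate_project, load_project, run_wizard


@pytest.fixture(scope="session")
def small_config():
    # Small factorial chamber design: 3 cultivars x 2 treatments x 2 replicates
    # over 2 blocks, five scan waves, two technical scans per wave.
    return SyntheticConfig(
        n_cultivars=3,
        n_treatments=2,
        n_replicates=2,
        n_blocks=2,
        scans_per_wave=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def project_dir(tmp_path_factory, small_config):
    d = tmp_path_factory.mktemp("project")
    generate_project(small_config, d)
    return d


@pytest.fixture(scope="session")
def loaded_project(project_dir):
    project, report = load_project(project_dir)
    assert report.ok
    return project


@pytest.fixture(scope="session")
def processed_project(project_dir):
    cfg = RunConfig(project_dir=str(project_dir))
    return run_wizard(cfg, use_cache=False).project
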