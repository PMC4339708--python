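import pytest

from bhlhkit.pipeline import RunConfig, run_pipeline
from bhlhkit.simulate import GeneratorConfig, generate_proteome, write_bundle

SMALL_CFG = dict(seed=17, n_bhlh=30, n_decoys=30, n_internal_stop=2, n_truncated=2)


def make_run_config(paths, out_dir, seed=17, **overrides) -> RunConfig:
    base = dict(
        proteome=str(paths["proteome"]),
        training_alignment=str(paths["training_alignment"]),
        out_dir=str(out_dir),
        seed=seed,
        gff3=str(paths["gff3"]),
        cds=str(paths["cds"]),
        family_references=str(paths["family_references"]),
        motif_alignments=[str(paths["motif40"])],
        homeolog_evidence=str(paths["evidence"]),
        expression=str(paths["expression"]),
        calibration_shuffles=100,
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    cfg = GeneratorConfig(**SMALL_CFG)
    bundle = generate_proteome(cfg)
    paths = write_bundle(bundle, tmp_path_factory.mktemp("bundle_small"))
    return bundle, paths


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    bundle, paths = small_bundle
    out = tmp_path_factory.mktemp("run_small")
    result = run_pipeline(make_run_config(paths, out))
    return bundle, result, out


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The default study conditions: 200 bHLH genes + 300 decoys, seed 17."""
    cfg = GeneratorConfig(seed=17)
    bundle = generate_proteome(cfg)
    paths = write_bundle(bundle, tmp_path_factory.mktemp("bundle_default"))
    return bundle, paths


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    bundle, paths = default_bundle
    out = tmp_path_factory.mktemp("run_default")
    result = run_pipeline(make_run_config(paths, out, calibration_shuffles=200))
    return bundle, result, out
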