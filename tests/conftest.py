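import pytest

from holoquant import GeneratorConfig, generate_database, simulate_psm_table


def small_config(seed: int = 11, **overrides) -> GeneratorConfig:
    """A fast desk-scale fixture configuration for unit tests."""
    defaults = dict(
        n_host_proteins=20,
        n_symbiont_proteins=12,
        n_variant_families=4,
        variant_identity=0.95,
        protein_length_range=(120, 260),
        conditions=[("fresh", 0.295), ("starved", 0.187)],
        n_replicates=3,
        spectra_per_sample=3_000,
        replicate_noise_sd=0.03,
        decoy_fraction_of_matches=0.05,
        rng_seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_fixture():
    """(config, database, truth, psms, design) for a fast synthetic run."""
    cfg = small_config()
    database, truth = generate_database(cfg)
    psms, design = simulate_psm_table(database, truth, cfg)
    return cfg, database, truth, psms, design
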