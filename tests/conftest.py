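import numpy as np
import pandas as pd
import pytest

from splicescreen import synthetic_fixtures as sf
from splicescreen.panel_store import mask_low_coverage
from splicescreen.screening import ScreenConfig, run_screens


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("toy_genome")
    return sf.generate_toy_genome(outdir)


@pytest.fixture(scope="session")
def toy_models(toy_genome):
    from splicescreen.junction_translation import load_gene_models
    return load_gene_models(toy_genome["gtf"])


@pytest.fixture(scope="session")
def toy_fasta(toy_genome):
    from splicescreen.junction_translation import load_genome
    return load_genome(toy_genome["fasta"])


@pytest.fixture(scope="session")
def small_spec():
    return sf.SyntheticSpec(n_normal_groups=4, samples_per_group=6,
                            n_tumor_samples=8, n_events=40,
                            n_planted_associated=3, n_planted_specific=3,
                            seed=11)


@pytest.fixture(scope="session")
def small_panel(small_spec):
    panel, truth = sf.generate_panel_with_cohort(small_spec)
    return panel, truth


@pytest.fixture(scope="session")
def planted_run():
    """The default-shape run: 11 normal groups x 20, 23 tumor samples,
    20 planted tumor-specific events among 500 nulls, seed 7."""
    spec = sf.SyntheticSpec(n_events=520, n_planted_specific=20, seed=7)
    panel, truth = sf.generate_panel_with_cohort(spec)
    masked = mask_low_coverage(panel)
    records, table = run_screens(panel, masked, "TUMOR", ScreenConfig(),
                                 with_recurrence=False)
    return panel, truth, records, table


@pytest.fixture(scope="session")
def null_run():
    """Seeded null panel: no planted events, defaults otherwise."""
    spec = sf.SyntheticSpec(n_events=500, seed=1)
    panel, truth = sf.generate_panel_with_cohort(spec)
    masked = mask_low_coverage(panel)
    records, table = run_screens(panel, masked, "TUMOR", ScreenConfig(),
                                 with_cpm=False, with_recurrence=False)
    return panel, records, table
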