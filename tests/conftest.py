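import numpy as np
import pytest

from gluhap.pipeline import RunConfig, run_pipeline
from gluhap.synthetic_data import fixture_config, simulate_panel
from gluhap.variant_core import GenotypeMatrix, VariantSite

FIXTURE_SEED = 11


def make_matrix(calls, samples=None, regions="coding-x", chrom="chr1D", start=1000, quals=None):
    """Small GenotypeMatrix from a (n_sites, n_samples) array of call codes.

    ``regions`` may be a single tag or one tag per site; positions are
    consecutive from ``start``.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    if isinstance(regions, str):
        regions = [regions] * n_sites
    if quals is None:
        quals = [60.0] * n_sites
    sites = [
        VariantSite(chrom, start + i, "A", "G", quals[i], regions[i]) for i in range(n_sites)
    ]
    return GenotypeMatrix(sites, list(samples), calls)


@pytest.fixture(scope="session")
def fixture_panel():
    """The bundled zero-noise panel with planted truth."""
    return simulate_panel(fixture_config(FIXTURE_SEED))


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """One full pipeline run over the bundled panel."""
    out = tmp_path_factory.mktemp("fixture_run")
    cfg = RunConfig(panel=fixture_config(FIXTURE_SEED), seed=FIXTURE_SEED)
    summary = run_pipeline(cfg, out)
    return out, summary
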