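"""Shared fixtures: one session-scoped synthetic dataset with planted truth.

The standard fixture plants 10 hairpins (8 of which emit miRNA* reads)
in a 15 kb genome with decoy features and simulates 2 control + 2
water-stress libraries of 50,000 reads each.
"""

import warnings

import pytest

from srnakit.annotate import ReferenceSet, annotate_waterfall, length_filter
from srnakit.simulate import SimConfig, generate_genome, simulate_libraries


@pytest.fixture(scope="session")
def sim10():
    cfg = SimConfig(
        n_hairpins=10,
        n_families=10,
        n_decoy_ncrna=6,
        n_decoy_mrna=6,
        genome_length=15_000,
        library_depth=50_000,
        n_star_hairpins=8,
        seed=3,
    )
    refs, truth = generate_genome(cfg)
    libraries = simulate_libraries(refs, truth, cfg)
    return cfg, refs, truth, libraries


@pytest.fixture(scope="session")
def annotated10(sim10):
    """Length-filtered libraries annotated WITHOUT the mature catalog,
    the novel-discovery scenario (planted hairpins are unknown)."""
    _cfg, refs, truth, libraries = sim10
    refs_nocat = ReferenceSet(
        genome=refs.genome,
        structural_ncrna=refs.structural_ncrna,
        repeats_mrna=refs.repeats_mrna,
        mature_catalog={},
    )
    filtered, results = [], {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lib in libraries:
            flib, _ = length_filter(lib)
            filtered.append(flib)
            results[lib.library_id] = annotate_waterfall(flib, refs_nocat)
    return filtered, results


@pytest.fixture(scope="session")
def annotated10_catalog(sim10):
    """Annotation with the full mature catalog (quantification scenario)."""
    _cfg, refs, _truth, libraries = sim10
    filtered, results = [], {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lib in libraries:
            flib, _ = length_filter(lib)
            filtered.append(flib)
            results[lib.library_id] = annotate_waterfall(flib, refs)
    return filtered, results
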