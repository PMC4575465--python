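"""Shared fixtures: the default synthetic study, processed end to end.

The expensive fixtures are session-scoped so the full-depth study (50 kb
genome, 5 planted hairpins, 100k reads per library, 3 replicates per
condition) is simulated and processed exactly once per test run.
"""

from __future__ import annotations

import pytest

from pollensnc import annotate, preprocess, synthetic

DEFAULT_FIXTURE = dict(length_bp=50_000, n_genes=20, n_trna=8, n_snorna=3,
                       n_hairpins=5, seed=1)
DEPTH = 100_000
REPLICATES = 3


@pytest.fixture(scope="session")
def study():
    genome, features, truth = synthetic.make_genome(**DEFAULT_FIXTURE)
    return genome, features, truth


@pytest.fixture(scope="session")
def processed_libraries(study):
    """All six libraries collapsed, trimmed, and deduplicated."""
    _genome, _features, truth = study
    libs = {}
    for cond in ("control", "heat"):
        for rep in range(1, REPLICATES + 1):
            raw = synthetic.simulate_sncrna_library(truth, cond, rep, DEPTH)
            collapsed, _ = preprocess.collapse_pcr_duplicates(raw)
            trimmed = preprocess.trim_adapters(collapsed, truth.adapter3,
                                               truth.adapter5)
            libs[f"{cond}_{rep}"] = preprocess.build_library(
                trimmed, f"{cond}_{rep}", cond)
    return libs


@pytest.fixture(scope="session")
def annotated_libraries(study, processed_libraries):
    genome, features, _truth = study
    index = annotate.build_index(genome, k=12)
    ann = annotate.AnnotationIndex(features)
    return {sample: annotate.annotate_library(lib, index, ann)
            for sample, lib in processed_libraries.items()}
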