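import numpy as np
import pandas as pd
import pytest

from tnscreen.annotation import GeneAnnotation, GeneRecord
from tnscreen.peaks import process_peak_tables
from tnscreen.simulate import (
    PlantedEffect,
    SimulationConfig,
    default_effects,
    gen_annotation,
    gen_growth,
    gen_insertions,
    gen_peak_data,
)


@pytest.fixture
def toy_annotation() -> GeneAnnotation:
    """Hand-placed genes on a 10 kb circular genome for mapping tests."""
    return GeneAnnotation(
        10_000,
        [
            GeneRecord("genA", 100, 200, "+", "enzyme A"),
            GeneRecord("genB", 500, 900, "-", "hypothetical protein",
                       hypothetical=True, operon_id="op1"),
            GeneRecord("genC", 1000, 1400, "+", "enzyme C", operon_id="op1",
                       investigated=True),
            GeneRecord("genD", 5000, 6000, "-", "enzyme D"),
        ],
    )


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        genome_length=200_000,
        n_genes=200,
        n_mutants=20,
        n_experiments=2,
        qc_per_experiment=3,
        n_metabolites=20,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Small full study: annotation, mutants, growth, peak bundle."""
    annotation = gen_annotation(small_config)
    mutants = gen_insertions(annotation, small_config)
    growth = gen_growth(mutants, small_config)
    effects = [
        PlantedEffect(mutants["mutant_id"].iloc[0], "glutamine", 3.0),
        PlantedEffect(mutants["mutant_id"].iloc[1], "succinate", 0.3),
    ]
    bundle = gen_peak_data(annotation, mutants, effects, small_config, growth=growth)
    return {
        "config": small_config,
        "annotation": annotation,
        "mutants": mutants,
        "growth": growth,
        "effects": effects,
        "bundle": bundle,
    }


@pytest.fixture(scope="session")
def small_matrix(small_study):
    """Fully processed metabolite matrix of the small study."""
    bundle = small_study["bundle"]
    return process_peak_tables(bundle.peaks, bundle.sample_meta, bundle.derivative_map)
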