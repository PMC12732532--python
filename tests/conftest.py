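"""Shared fixtures: small planted genomes and one full default-study run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pbscout import pipeline as pl
from pbscout import synthetic_genome as sg

SEED = 1


@pytest.fixture(scope="session")
def default_sim() -> sg.SimulatedGenome:
    """The default study genome: 2 Mb, 5 families, 50 intact + 10 decayed."""
    return sg.simulate_default(rng_seed=SEED)


@pytest.fixture(scope="session")
def default_run(default_sim, tmp_path_factory):
    """One full pipeline run on the default study genome."""
    base = tmp_path_factory.mktemp("default_run")
    sim_dir = base / "sim"
    run_dir = base / "run"
    default_sim.write(sim_dir)
    config = pl.PipelineConfig(seed=SEED)
    report = pl.run_all(
        config, sim_dir / "genome.fasta", sim_dir / "query.faa", run_dir
    )
    elements = pd.read_csv(run_dir / "elements.tsv", sep="\t")
    metrics = pl.validate_against_truth(elements, default_sim.truth)
    return {
        "sim": default_sim,
        "sim_dir": sim_dir,
        "run_dir": run_dir,
        "report": report,
        "elements": elements,
        "metrics": metrics,
        "config": config,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def small_template() -> sg.ElementTemplate:
    return sg.make_template(
        "tfam", rng_seed=7, length_range=(2200, 2200), tir_length=13,
        orf_length=520,
    )


def tiny_specs(seed: int = 3) -> list[sg.PlantSpec]:
    """Two small families for fast end-to-end tests."""
    specs = []
    for j, (fam, tir, orf, elem, k) in enumerate(
        [("tinyA", 13, 510, 2100, 0.0), ("tinyB", 15, 540, 2400, 0.02)]
    ):
        specs.append(
            sg.PlantSpec(
                template=sg.make_template(
                    fam, rng_seed=seed * 100 + j,
                    length_range=(elem, elem), tir_length=tir, orf_length=orf,
                ),
                n_copies=5,
                expected_K=k,
                decay_fraction=0.2,
            )
        )
    return specs


@pytest.fixture(scope="session")
def tiny_sim() -> sg.SimulatedGenome:
    return sg.plant_genome(
        tiny_specs(), n_contigs=2, contig_length=80_000, rng_seed=5
    )
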