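import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from morphdispersal import BoxRegistry, NestBox, SimulationParams

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_registry() -> BoxRegistry:
    """Five boxes with easy hand-checkable distances; two pre-cutoff."""
    return BoxRegistry(
        [
            NestBox("A", 0.0, 0.0, 1980),
            NestBox("B", 3.0, 4.0, 1980),
            NestBox("C", 6.0, 8.0, 1990),
            NestBox("D", 0.0, 10.0, 1990),
            NestBox("E", 10.0, 0.0, 1990),
        ],
        era_cutoff_year=1987,
    )


@pytest.fixture
def tiny_recruits() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "recruit_id": ["r1", "r2", "r3"],
            "natal_box_id": ["A", "B", "C"],
            "breeding_box_id": ["B", "A", "A"],
            "hatch_year": [1990, 1992, 1995],
            "morph": ["gray", "brown", "gray"],
            "sex": ["female", "male", "male"],
            "dispersal_km": [5.0, 5.0, 10.0],
        }
    )


@pytest.fixture
def small_params() -> SimulationParams:
    """Down-scaled population for fast end-to-end runs."""
    return SimulationParams(
        n_years=12,
        n_boxes=60,
        n_broods_per_year=12,
        recruitment_prob=0.15,
        start_year=1981,
        era_cutoff_year=1987,
        baseline_start=1981,
        baseline_end=1992,
        seed=42,
    )


@pytest.fixture
def study_params() -> SimulationParams:
    return SimulationParams(seed=7)
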