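"""Shared fixtures: a small landscape and a mid-sized simulated study.

The "study" fixture simulates one winter of two-species tracking with
shooting at the generator's default (published) displacement truth; it
is session-scoped because several displacement/exposure tests and the
recovery checks all consume the same dataset.
"""

from __future__ import annotations

import warnings

import pytest

from fearscape.config import SimulationConfig
from fearscape.io import annotate_fixes, resample_hourly
from fearscape.landscape import generate_landscape
from fearscape.simulate import generate_shooting_log, generate_tracks

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_individuals_per_species=3)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def study():
    """One simulated winter at moderate scale, with ground truth.

    Returns dict with landscape, raw and perturbed tracks, events,
    injection truth, and hourly annotated fixes.
    """
    cfg = SimulationConfig(seed=11, n_individuals_per_species=12, shooting_rate=1.0)
    land = generate_landscape(cfg)
    tracks = generate_tracks(land, cfg)
    events, perturbed, truth = generate_shooting_log(land, tracks, cfg)
    fixes = annotate_fixes(resample_hourly(perturbed), land)
    return {"config": cfg, "landscape": land, "tracks": tracks,
            "events": events, "perturbed": perturbed, "truth": truth,
            "fixes": fixes}


@pytest.fixture(scope="session")
def fixture_dataset(tmp_path_factory):
    """The bundled small dataset written to disk (exercises every reader)."""
    from fearscape.pipeline import make_fixtures

    outdir = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(seed=3, outdir=outdir)
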