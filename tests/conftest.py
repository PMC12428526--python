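import numpy as np
import pytest

from zoopop import (
    generate_population,
    load_packaged_stage_reference,
    preset,
)


@pytest.fixture(scope="session")
def stage_ref():
    return load_packaged_stage_reference()


@pytest.fixture(scope="session")
def dvm_scenario():
    """M. pacifica DVM scenario at n=2,000, fixed seed, plus helpers."""
    cfg = preset("mpacifica_dvm", n_individuals=2000, seed=42)
    detections, metas, truth = generate_population(cfg)
    return cfg, detections, metas, truth


@pytest.fixture(scope="session")
def svm_scenario():
    cfg = preset("ebungii_svm_october", n_individuals=2000, seed=42)
    detections, metas, truth = generate_population(cfg)
    return cfg, detections, metas, truth


def split_day_night(detections, metas):
    """Partition a scenario's detections/metas into (day, night) halves."""
    out = []
    for phase in ("D", "N"):
        ids = {m.sample_id for m in metas if m.day_night == phase}
        out.append((
            [d for d in detections if d.sample_id in ids],
            [m for m in metas if m.sample_id in ids],
        ))
    return out
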