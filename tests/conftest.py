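import numpy as np
import pytest
from hypothesis import settings

import neovent as nv
from neovent import cohort as cp
from neovent import synth
from neovent.io import analyze_cohort

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lung():
    return nv.LungParams()


@pytest.fixture(scope="session")
def tpiece_dev():
    return nv.DeviceParams.tpiece()


@pytest.fixture(scope="session")
def sib_dev():
    return nv.DeviceParams.sib()


@pytest.fixture(scope="session")
def steady_op():
    """Jitter-free T-piece operator: PIP 20, PEEP 5, Ti 1.0 s, RR 40."""
    return nv.OperatorParams(pip_target=20.0, peep_target=5.0, ti_mean=1.0,
                             rr_mean=40.0, breath_jitter_cv=0.0)


@pytest.fixture(scope="session")
def steady_tpiece_epoch(steady_op, tpiece_dev, lung):
    """180-s jitter-free T-piece recording (exactly 120 commanded breaths)."""
    return nv.generate_tpiece_recording(steady_op, tpiece_dev, lung, 180.0, seed=7)


@pytest.fixture(scope="session")
def steady_sib_epoch(sib_dev, lung):
    op = nv.OperatorParams(pip_target=21.0, peep_target=0.0, ti_mean=0.85,
                           rr_mean=40.0, breath_jitter_cv=0.0)
    return nv.generate_sib_recording(op, sib_dev, lung, 180.0, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """Full default cohort (54+60 subjects) analyzed end to end, seed 1.

    Returns (manifest, accounting, subject-summary frame, SLI frame,
    comparison table).
    """
    cfg = synth.CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(1).spawn(1)[0])
    manifest = synth.build_manifest(54, 60, cfg, rng)
    accounting = cp.apply_participant_flow(manifest)
    _, subjects, sli = analyze_cohort(manifest, cfg, seed=1)
    table = cp.build_comparison_table(subjects, sli, accounting=accounting,
                                      manifest=manifest)
    return manifest, accounting, subjects, sli, table
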