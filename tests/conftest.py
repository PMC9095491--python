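import numpy as np
import pytest
from hypothesis import settings

from fearpet import (FrameSchedule, InputModel, TissueParams,
                     DEFAULT_KINETICS, simulate_tissue_tac)
from fearpet.srtm import reference_fine_curve

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def frames():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def input_model():
    return InputModel()


@pytest.fixture(scope="session")
def region_tacs(frames, input_model):
    """Noiseless baseline TACs for the three regions plus reference."""
    tissues = [TissueParams(BP_base=bp, region_label=lab, **DEFAULT_KINETICS)
               for lab, bp in (("striatum", 2.6), ("amygdala", 0.3),
                               ("frontal", 0.07), ("reference", 0.0))]
    tacs = simulate_tissue_tac(input_model, tissues, None, frames)
    return {t.region_label: tac for t, tac in zip(tissues, tacs)}


@pytest.fixture(scope="session")
def reference_fine(region_tacs, frames):
    """Fine-grid reconstruction of the reference TAC used by the fitters."""
    return reference_fine_curve(region_tacs["reference"], frames, 0.25)
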