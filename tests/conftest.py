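import numpy as np
import pytest
from hypothesis import settings

from paencase import (
    Cohort,
    LesionRecord,
    RelationType,
    VesselMeasurement,
)
from paencase import paper_tables

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


E = RelationType.ENCASEMENT
D = RelationType.DISPLACEMENT
P = RelationType.PENETRATION
IM = RelationType.IN_MARGIN
DC = RelationType.DISCONNECTION


def make_record(lesion_id="L1", truth="malignant", relations=(E,), degree=50.0,
                measurement=True, **kwargs):
    rels = frozenset(relations)
    measurements = ()
    if measurement and degree is not None and E in rels:
        if degree >= 100.0:
            measurements = (VesselMeasurement(vessel_id=f"{lesion_id}-a1",
                                              AB=6.0, amputated=True),)
        else:
            measurements = (VesselMeasurement(vessel_id=f"{lesion_id}-a1", AB=6.0,
                                              CD=6.0 * (1 - degree / 100.0)),)
    defaults = dict(
        lesion_id=lesion_id, truth=truth, location="peripheral", size=30.0,
        final_relations=rels, obs1_relations=rels, obs2_relations=rels,
        measurements=measurements,
        degree=degree if E in rels else None,
    )
    defaults.update(kwargs)
    return LesionRecord(**defaults)


@pytest.fixture(scope="session")
def reconstruction():
    """Per-lesion cohort consistent with the published relationship margins."""
    return paper_tables.reconstructed_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
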