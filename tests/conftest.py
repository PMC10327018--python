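import numpy as np
import pytest
from hypothesis import settings

from crossconn import morphology as mo
from crossconn import synthetic_data as sd

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def cohort_dotprops(cohort, midline_x=0.0):
    """Dotprops (right side mirrored onto the left), hemisphere tags and
    ground-truth labels for every neuron of a simulated cohort."""
    dps, tags, truth = [], {}, {}
    for hemi, entry in cohort["hemispheres"].items():
        for r in entry["records"]:
            sk = entry["skeletons"][r.neuron_id]
            pts = sk.xyz if r.side == "left" else mo.mirror(sk.xyz, midline_x)
            dps.append(mo.make_dotprops(pts, neuron_id=r.neuron_id))
            tags[r.neuron_id] = hemi
            truth[r.neuron_id] = r.extra["gt_type"]
    return dps, tags, truth


def cohort_distances(cohort):
    dps, tags, truth = cohort_dotprops(cohort)
    S = mo.nblast_matrix(dps)
    D = mo.scores_to_distance(mo.mean_scores(S))
    return D, tags, truth


@pytest.fixture(scope="session")
def small_cohort():
    """10 planted types, default biological variability, no corruption."""
    return sd.simulate_cohort(10, seed=42)


@pytest.fixture(scope="session")
def small_cohort_distances(small_cohort):
    return cohort_distances(small_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
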