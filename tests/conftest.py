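import numpy as np
import pytest

import tauspread as ts
from tauspread import connectome, epicentres, harmonize, io


@pytest.fixture(scope="session")
def study():
    """Default synthetic study conditions (200 ROIs, 7 networks)."""
    return ts.build_study(seed=7)


@pytest.fixture(scope="session")
def strong_run(study):
    """One strong-coupling cohort pushed through harmonization + epicentres.

    Session-scoped: the epicentre-recovery, covariance-distance and quartile
    analyses all reuse these intermediates.
    """
    cohort, truth = ts.simulate_tau_cohort(
        study.distance, study.scenario, n_subjects=50, timepoints=(0.0,),
        n_controls=30, noise_coupling=study.connectome)
    model = harmonize.TracerMixtureModel.fit(cohort, seed=7)
    harmonized = model.apply(cohort)
    patients = harmonized[harmonized["group"] == "patient"]
    suvr = io.cohort_to_wide(patients, "suvr")
    positivity = io.cohort_to_wide(patients, "positivity")
    meta = io.subject_metadata(patients)
    epis = epicentres.cohort_epicentres(suvr)
    epi_dists = {e.subject_id: connectome.epicentre_distance(study.distance,
                                                             np.array(e.roi_set))
                 for e in epis}
    return {
        "study": study, "cohort": cohort, "truth": truth, "model": model,
        "suvr": suvr, "positivity": positivity,
        "covariates": meta[["age", "sex", "site"]],
        "epicentres": epis, "epi_dists": epi_dists,
    }


@pytest.fixture()
def tiny_scenario():
    """A noise-free scenario for closed-form checks."""
    return ts.SpreadScenario(
        epicentre_rois=(0, 1), amplitude=1.0, decay_rate=1.0,
        baseline_suvr=1.0, noise_sd=0.0, noise_correlation=0.0,
        severity_sd=0.0, site_effects={"s0": 0.0}, age_slope=0.0,
        sex_offset=0.0, tracer_scale={"synthetic": 1.0},
        accumulation_rate=0.0, seed=3)


def make_scenario(**overrides):
    base = dict(epicentre_rois=(0, 1, 2), seed=5)
    base.update(overrides)
    return ts.SpreadScenario(**base)


@pytest.fixture()
def scenario_factory():
    return make_scenario
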