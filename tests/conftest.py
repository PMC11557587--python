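import numpy as np
import pytest

from deltapet import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Noise-free two-group phantom (3 vs 4 subjects) on the default grid."""
    config = synthetic.PhantomConfig(
        n_subjects_per_group={"CON": 3, "LS": 4}, noise_sd=0.0, seed=7)
    return synthetic.make_phantom_cohort(config)


@pytest.fixture(scope="session")
def noisy_cohort():
    config = synthetic.PhantomConfig(
        n_subjects_per_group={"CON": 4, "LS": 4}, noise_sd=0.05, seed=11)
    return synthetic.make_phantom_cohort(config)


def delta_table_for(cohort):
    """Run the ROI stage on a cohort and return the delta-SUV table."""
    import pandas as pd

    from deltapet import roi

    frames = {"F1": [], "F3": []}
    for subj in cohort.subjects:
        for session, vol in (("F1", subj.f1), ("F3", subj.f3)):
            norm = roi.normalize_to_brain_mean(vol, cohort.brain_mask)
            frames[session].append(roi.extract_suvs(norm, cohort.mask_set,
                                                    group=subj.group))
    f1 = pd.concat(frames["F1"], ignore_index=True)
    f3 = pd.concat(frames["F3"], ignore_index=True)
    return roi.compute_delta_suv(f1, f3)


@pytest.fixture(scope="session")
def small_delta_table(small_cohort):
    return delta_table_for(small_cohort)
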