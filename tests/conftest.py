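import numpy as np
import pytest

from maxstab.phantom import PhantomSpec, cohort, generate_baseline, synthesize_growth


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom at the clinical 0.4 mm voxel size (38 mm frame):
    anatomy shrunk to fit, used by fast unit tests."""
    return PhantomSpec(shape=(48, 48, 48), spacing=0.8,
                       semi_axes=(15.0, 13.0, 10.0))


@pytest.fixture(scope="session")
def small_baseline(small_spec):
    return generate_baseline(small_spec, seed=3)


@pytest.fixture(scope="session")
def clean_baseline(small_spec):
    """Noise-free variant for apply-then-recover oracles: with independent
    noise absent, interpolation smoothing must not bias the similarity
    optimum away from the planted transform."""
    import dataclasses
    return generate_baseline(dataclasses.replace(small_spec, noise_sd=0.0), seed=3)


@pytest.fixture(scope="session")
def small_pair(small_spec, small_baseline):
    t2, gt = synthesize_growth(small_baseline, small_spec, seed=5)
    return small_baseline, t2, gt


@pytest.fixture(scope="session")
def study_spec():
    """The study conditions: 96 voxel grid, 1.8 / 0.6 mm growth statistics."""
    return PhantomSpec()


@pytest.fixture(scope="session")
def discovery_cohort(study_spec):
    """The five-subject discovery cohort (heavy; shared across tests)."""
    return cohort(study_spec, 5, seed=123)


@pytest.fixture(scope="session")
def discovery_result(discovery_cohort):
    from maxstab.pipeline import discover_atlas
    return discover_atlas(discovery_cohort)


@pytest.fixture(scope="session")
def rigid_only_pair(small_spec):
    """Growth-free pair: T2 is the analytically re-rendered T1 under a pure
    rigid motion (known), with independent noise.  The oracle for
    apply-then-recover registration tests."""
    import dataclasses
    spec = dataclasses.replace(small_spec, mean_displacement=0.0, sd_displacement=0.0,
                               pole_magnitude=0.0, rotation_max_deg=2.0,
                               translation_max_mm=2.0, noise_sd=10.0)
    base = generate_baseline(spec, seed=6)
    t2, gt = synthesize_growth(base, spec, seed=7)
    return base, t2, gt


@pytest.fixture
def rng():
    # function-scoped so draws never depend on test execution order
    return np.random.default_rng(20240917)
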