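import dataclasses

import pytest

from onh import CohortParams, PhantomParams, ScanGeometry, make_phantom_volume


@pytest.fixture(scope="session")
def default_phantom():
    """Default noise-free phantom: flat LC at 203 um, 90% visible, no tilt."""
    return make_phantom_volume(PhantomParams())


@pytest.fixture(scope="session")
def coarse_geometry():
    """Quarter-resolution scan covering the same physical field."""
    return ScanGeometry(
        n_bscans=37, n_ascans=96, bscan_spacing=124.0, ascan_spacing=46.4
    )


@pytest.fixture()
def cohort_params():
    return CohortParams()


def quiet_cohort(params: CohortParams, **overrides) -> CohortParams:
    """Cohort params with every stochastic term switched off."""
    return dataclasses.replace(
        params,
        baseline_iop_sd=0.0,
        tonometry_noise_sd=0.0,
        iop_fluctuation_cv=0.0,
        baseline_mrw_sd=0.0,
        baseline_lcd_sd=0.0,
        mrw_change_m1m2_sd=0.0,
        lcd_change_m1m2_sd=0.0,
        mrw_drift_noise_sd=0.0,
        lcd_drift_noise_sd=0.0,
        **overrides,
    )
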