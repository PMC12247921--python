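import numpy as np
import pandas as pd
import pytest

import bundleval as bv


@pytest.fixture(scope="session")
def catalog():
    return bv.build_item_roster(40, 10, 10, 3, seed=1)


@pytest.fixture(scope="session")
def clean_linear_wtp(catalog):
    """Noiseless linear bids at the canonical sub-additive coefficients."""
    spec = bv.GenerativeBundleSpec(
        family="linear",
        params={"beta0": 0.83, "beta1": 0.73, "beta2": 0.73},
        noise_sd=0.0, item_noise_sd=0.0,
        re_sd_intercept=0.0, re_sd_slope=0.0,
        censor_bids=False,
    )
    return bv.simulate_wtp_dataset(spec, catalog, n_subjects=3, seed=2)


@pytest.fixture(scope="session")
def small_schedule(catalog, clean_linear_wtp):
    return bv.build_trial_schedule(catalog, clean_linear_wtp, seed=3)


def make_wtp(catalog, family, params, n_subjects=3, seed=0, noise_sd=0.0,
             re0=0.0, re1=0.0, item_noise=0.0, censor=False):
    spec = bv.GenerativeBundleSpec(
        family=family, params=params, noise_sd=noise_sd,
        item_noise_sd=item_noise, re_sd_intercept=re0, re_sd_slope=re1,
        censor_bids=censor,
    )
    return bv.simulate_wtp_dataset(spec, catalog, n_subjects=n_subjects, seed=seed)
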