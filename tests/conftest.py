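import numpy as np
import pandas as pd
import pytest

import heatcross as hc


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study: 2 years, ~50 presentations/day, truth RR 1.5."""
    cfg = hc.SyntheticConfig(
        seed=42,
        study_start="2014-01-01",
        study_end="2015-12-31",
        outcome=hc.OutcomeConfig(daily_rate=50.0, heatwave_rr=1.5),
    )
    return cfg, hc.simulate_study(cfg)


@pytest.fixture(scope="session")
def small_exposure(small_study):
    cfg, study = small_study
    pm = hc.fill_pm25_gaps(study["pm25"])
    return hc.assemble_exposure_table(
        study["calendar"], pm, study["holidays"], cfg.study_start, cfg.study_end
    )


def make_pairs_design(n10, n01, n_concordant=0):
    """1:1 matched-pair design with given discordance counts.

    n10 pairs have the case exposed and the referent not; n01 the reverse;
    concordant pairs have neither exposed.
    """
    rows = []
    sid = 0
    for _ in range(n10):
        rows += [(sid, 1, 1), (sid, 0, 0)]
        sid += 1
    for _ in range(n01):
        rows += [(sid, 1, 0), (sid, 0, 1)]
        sid += 1
    for _ in range(n_concordant):
        rows += [(sid, 1, 0), (sid, 0, 0)]
        sid += 1
    return pd.DataFrame(rows, columns=["stratum_id", "is_case", "exposed"])


def make_random_design(rng, n_strata=50, p_exposed=0.3, beta=0.0, extra_covariates=False):
    """Random strata of size 4-5 with cases drawn from the conditional model."""
    rows = []
    for s in range(n_strata):
        m = int(rng.integers(4, 6))
        x = (rng.random(m) < p_exposed).astype(int)
        w = np.exp(beta * x)
        case = rng.choice(m, p=w / w.sum())
        for j in range(m):
            row = [s, int(j == case), int(x[j])]
            if extra_covariates:
                row += [float(rng.normal(8, 3)), int(rng.random() < 0.05)]
            rows.append(row)
    cols = ["stratum_id", "is_case", "exposed"]
    if extra_covariates:
        cols += ["pm25", "holiday"]
    return pd.DataFrame(rows, columns=cols)
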