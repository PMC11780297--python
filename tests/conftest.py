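import numpy as np
import pandas as pd
import pytest

from hftrialkit.instruments import default_scale_definitions
from hftrialkit.tailoring import load_message_bank


@pytest.fixture(scope="session")
def scale_defs():
    return default_scale_definitions()


@pytest.fixture(scope="session")
def message_bank():
    return load_message_bank()


def reml_loglik(df: pd.DataFrame, sigma_u2: float, sigma_e2: float) -> float:
    """Independent closed-form REML log-likelihood for y ~ 1 + week with a
    random intercept per subject (block-diagonal V_i = s_e^2 I + s_u^2 J,
    fixed effects profiled out)."""
    XtViX = np.zeros((2, 2))
    XtViy = np.zeros(2)
    ytViy = 0.0
    logdetV = 0.0
    for _, g in df.groupby("patient_id"):
        ni = len(g)
        X = np.column_stack([np.ones(ni), g["week"].to_numpy(float)])
        y = g["y"].to_numpy(float)
        c = sigma_u2 / (sigma_e2 + ni * sigma_u2)
        Vinv = (np.eye(ni) - c * np.ones((ni, ni))) / sigma_e2
        logdetV += (ni - 1) * np.log(sigma_e2) + np.log(sigma_e2 + ni * sigma_u2)
        XtViX += X.T @ Vinv @ X
        XtViy += X.T @ Vinv @ y
        ytViy += y @ Vinv @ y
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - XtViy @ beta
    n, p = len(df), 2
    _, logdetXtViX = np.linalg.slogdet(XtViX)
    return float(
        -0.5 * (logdetV + logdetXtViX + quad) - 0.5 * (n - p) * np.log(2 * np.pi)
    )


def simulate_trajectories(
    seed: int,
    *,
    intercept: float = 92.0,
    slope: float = -0.95,
    sigma_u: float = 10.0,
    sigma_e: float = 8.0,
    n_subjects: int = 11,
    n_weeks: int = 8,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, sigma_u)
        for wk in range(1, n_weeks + 1):
            rows.append(
                {
                    "patient_id": f"s{s}",
                    "week": wk,
                    "y": intercept + slope * wk + u + rng.normal(0, sigma_e),
                }
            )
    return pd.DataFrame(rows)
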