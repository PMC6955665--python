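"""Independent reference implementations used only to validate the fitter.

These deliberately avoid the profiled-likelihood shortcut: the marginal
Gaussian log-likelihood is evaluated from the full per-patient covariance
matrices, maximized by grid search over all parameters followed by a
general-purpose simplex polish.
"""

import numpy as np
from scipy import optimize


def _group_indices(patient_id):
    ids = np.unique(patient_id)
    return [np.flatnonzero(patient_id == g) for g in ids]


def marginal_deviance(X, y, patient_id, beta, sigma_mu, sigma_eps):
    """-2 log-likelihood of the random-intercept model at explicit parameters."""
    r = y - X @ beta
    total = len(y) * np.log(2.0 * np.pi)
    for idx in _group_indices(patient_id):
        rg = r[idx]
        V = sigma_eps**2 * np.eye(len(idx)) + sigma_mu**2
        _, logdet = np.linalg.slogdet(V)
        total += logdet + float(rg @ np.linalg.solve(V, rg))
    return total


def _gls_beta(X, y, patient_id, sigma_mu, sigma_eps):
    XtVX = np.zeros((X.shape[1], X.shape[1]))
    XtVy = np.zeros(X.shape[1])
    for idx in _group_indices(patient_id):
        V = sigma_eps**2 * np.eye(len(idx)) + sigma_mu**2
        Vi = np.linalg.inv(V)
        XtVX += X[idx].T @ Vi @ X[idx]
        XtVy += X[idx].T @ Vi @ y[idx]
    return np.linalg.solve(XtVX, XtVy)


def brute_force_ml(X, y, patient_id):
    """Grid search over the variance parameters, then a Nelder-Mead polish.

    Returns (beta, sigma_mu, sigma_eps, deviance) at the maximum likelihood.
    """
    sd_y = max(np.std(y), 1e-3)
    log_smu_grid = np.log(sd_y) + np.linspace(-12.0, 2.0, 25)
    log_seps_grid = np.log(sd_y) + np.linspace(-6.0, 2.0, 25)
    best = (np.inf, None)
    for ls_mu in log_smu_grid:
        for ls_eps in log_seps_grid:
            smu, seps = np.exp(ls_mu), np.exp(ls_eps)
            beta = _gls_beta(X, y, patient_id, smu, seps)
            dev = marginal_deviance(X, y, patient_id, beta, smu, seps)
            if dev < best[0]:
                best = (dev, np.concatenate([beta, [ls_mu, ls_eps]]))

    def objective(params):
        p = X.shape[1]
        return marginal_deviance(
            X, y, patient_id, params[:p], np.exp(params[p]), np.exp(params[p + 1])
        )

    res = optimize.minimize(
        objective,
        best[1],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    res = optimize.minimize(
        objective,
        res.x,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    p = X.shape[1]
    smu, seps = float(np.exp(res.x[p])), float(np.exp(res.x[p + 1]))
    # exact GLS step at the polished variance estimates: beta has a closed
    # form given the variances, so do not leave it at simplex precision
    beta = _gls_beta(X, y, patient_id, smu, seps)
    dev = marginal_deviance(X, y, patient_id, beta, smu, seps)
    return beta, smu, seps, float(min(dev, res.fun))
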