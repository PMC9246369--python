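"""Power-law concentration dependence of the aggregation rate.

rate = A · c^n fitted by ordinary least squares on (ln c, ln rate).
A quadratic exponent (n ≈ 2) indicates a bimolecular rate-limiting
step; an inhibitor acting on that step lowers the pre-exponential
factor A and can raise n when larger assemblies start to contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["PowerLawFit", "PowerLawModel", "fit_power_law", "compare_arms"]


class ScalingError(ValueError):
    pass


@dataclass
class PowerLawFit:
    """Results of a power-law fit rate = A·c^n."""

    A: float              # pre-exponential factor, AU/s per μM^n
    n: float              # exponent
    A_se: float
    n_se: float
    r_squared: float
    n_points: int
    arm: str = ""
    method: str = "loglog_ols"

    def predict(self, concs) -> np.ndarray:
        return self.A * np.asarray(concs, dtype=float) ** self.n

    def summary(self) -> str:
        return "\n".join([
            f"Power-law fit{f' [{self.arm}]' if self.arm else ''} "
            f"(rate = A·c^n, {self.method}, {self.n_points} points)",
            f"  A = {self.A:.4e} ± {self.A_se:.2e} AU/s·μM^-n",
            f"  n = {self.n:.3f} ± {self.n_se:.3f}",
            f"  R² = {self.r_squared:.4f}",
        ])


class PowerLawModel:
    """Concentration-dependence model for one treatment arm.

    Parameters
    ----------
    concs_uM, rates : array-like
        Strictly positive protein concentrations and maximum
        aggregation rates (≥3 pairs).
    arm : str
        Label of the treatment arm (e.g. "0 mM inositol").
    """

    def __init__(self, concs_uM, rates, arm: str = ""):
        self.concs = np.asarray(concs_uM, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        self.arm = arm
        if self.concs.shape != self.rates.shape:
            raise ScalingError("concs and rates must have equal length")
        if self.concs.size < 3:
            raise ScalingError("power-law fit needs >= 3 points")
        if np.any(self.concs <= 0) or np.any(self.rates <= 0):
            raise ScalingError("concs and rates must be strictly positive")

    def fit(self, method: str = "loglog_ols") -> PowerLawFit:
        """Fit A and n.

        ``loglog_ols`` (default) regresses ln rate on ln c, matching a
        multiplicative noise model; ``nls`` does nonlinear least
        squares on the original scale.
        """
        if method == "loglog_ols":
            res = stats.linregress(np.log(self.concs), np.log(self.rates))
            A = float(np.exp(res.intercept))
            return PowerLawFit(
                A=A, n=float(res.slope),
                A_se=float(A * res.intercept_stderr),  # delta method
                n_se=float(res.stderr),
                r_squared=float(res.rvalue ** 2),
                n_points=self.concs.size, arm=self.arm, method=method)
        if method == "nls":
            def f(c, A, n):
                return A * c ** n

            p0 = (self.rates[0] / self.concs[0] ** 2, 2.0)
            popt, pcov = optimize.curve_fit(f, self.concs, self.rates, p0=p0,
                                            maxfev=10000)
            resid = self.rates - f(self.concs, *popt)
            ss_res = float(np.sum(resid ** 2))
            ss_tot = float(np.sum((self.rates - self.rates.mean()) ** 2))
            se = np.sqrt(np.diag(pcov))
            return PowerLawFit(A=float(popt[0]), n=float(popt[1]),
                               A_se=float(se[0]), n_se=float(se[1]),
                               r_squared=1.0 - ss_res / ss_tot if ss_tot else 1.0,
                               n_points=self.concs.size, arm=self.arm, method=method)
        raise ScalingError(f"unknown method {method!r}")


def fit_power_law(concs_uM, rates, arm: str = "", method: str = "loglog_ols") -> PowerLawFit:
    """Convenience wrapper: ``PowerLawModel(concs, rates).fit(method)``."""
    return PowerLawModel(concs_uM, rates, arm=arm).fit(method)


def compare_arms(fit_control: PowerLawFit, fit_treated: PowerLawFit) -> dict:
    """Compare treated vs control power laws.

    Returns the pre-exponential ratio A_treated/A_control, the exponent
    difference n_treated − n_control, and normal-approximation z-scores
    built from the fit standard errors (for ln A the delta-method SE
    is A_se/A).
    """
    ratio = fit_treated.A / fit_control.A
    dn = fit_treated.n - fit_control.n
    se_lnA = np.hypot(fit_treated.A_se / fit_treated.A,
                      fit_control.A_se / fit_control.A)
    se_dn = np.hypot(fit_treated.n_se, fit_control.n_se)
    return {
        "A_ratio": float(ratio),
        "delta_n": float(dn),
        "z_lnA": float(np.log(ratio) / se_lnA) if se_lnA > 0 else float("inf"),
        "z_n": float(dn / se_dn) if se_dn > 0 else float("inf"),
    }
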