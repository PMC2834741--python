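"""Thermodynamic integration (TI).

The free energy of an alchemical leg is dG = integral over lambda of the
ensemble mean <dH/dlambda>.  Two quadratures are provided:

* trapezoid over the sampled lambda grid (the conventional baseline), and
* polynomial regression: a least-squares polynomial is fitted to the per-lambda
  means and integrated analytically over [0, 1], which reduces the numerical
  integration error on sparse schedules.

`ThermodynamicIntegration` is the model object; `fit()` returns a `TIResults`.
The module-level `ti_trapezoid` / `ti_polynomial` are convenience wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import FreeEnergyEstimate, LambdaSeries

__all__ = ["ThermodynamicIntegration", "TIResults", "ti_trapezoid", "ti_polynomial"]

_MAX_CV_DEGREE = 6
_N_BOOTSTRAP = 1000


def _trap_weights(lam: np.ndarray) -> np.ndarray:
    dl = np.diff(lam)
    w = np.zeros_like(lam)
    w[:-1] += dl / 2.0
    w[1:] += dl / 2.0
    return w


def _integral_functional(lam: np.ndarray, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (L, V) with L the row vector mapping means -> integral of the
    degree-`degree` least-squares polynomial over [0, 1], V the Vandermonde."""
    V = np.vander(lam, degree + 1, increasing=True)
    pinv = np.linalg.pinv(V)
    a = 1.0 / np.arange(1, degree + 2)  # integral of x^j over [0,1]
    return a @ pinv, V


def _loo_cv_error(lam: np.ndarray, y: np.ndarray, degree: int) -> float:
    """Leave-one-out cross-validated mean squared error of a polynomial fit,
    via the hat-matrix shortcut e_i / (1 - h_ii)."""
    V = np.vander(lam, degree + 1, increasing=True)
    pinv = np.linalg.pinv(V)
    H = V @ pinv
    resid = y - H @ y
    denom = 1.0 - np.diag(H)
    denom = np.where(np.abs(denom) < 1e-12, np.nan, denom)
    loo = resid / denom
    return float(np.nanmean(loo**2))


@dataclass(frozen=True)
class TIResults:
    """Results of a thermodynamic-integration fit.

    Attributes
    ----------
    estimate : FreeEnergyEstimate
        Free energy of the leg (kJ/mol) and its standard error.
    method : str
        ``"TI-poly"`` or ``"TI-trap"``.
    degree : int or None
        Polynomial degree used (None for the trapezoid rule).
    coefficients : ndarray or None
        Fitted polynomial coefficients (increasing powers).
    cv_errors : dict or None
        Leave-one-out CV mean squared error per candidate degree.
    model : ThermodynamicIntegration
        The model this result came from.
    """

    estimate: FreeEnergyEstimate
    method: str
    degree: int | None
    coefficients: np.ndarray | None
    cv_errors: dict[int, float] | None
    model: "ThermodynamicIntegration"

    @property
    def value(self) -> float:
        return self.estimate.value

    @property
    def stderr(self) -> float:
        return self.estimate.stderr

    def summary(self) -> str:
        lines = [
            "Thermodynamic integration",
            "=" * 42,
            f"leg:          {self.model.series.leg_label or '(unnamed)'}",
            f"method:       {self.method}",
            f"lambda points: {self.model.series.n_lambdas}",
            f"temperature:  {self.model.series.temperature:.1f} K",
        ]
        if self.degree is not None:
            lines.append(f"degree:       {self.degree}")
        lines += [
            f"dG:           {self.value:10.4f} kJ/mol",
            f"stderr:       {self.stderr:10.4f} kJ/mol",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot per-lambda means (with error bars) and the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        lam = np.asarray(s.lambda_values)
        ax.errorbar(lam, s.means(), yerr=s.stderrs(), fmt="o", label="sample means")
        if self.coefficients is not None:
            grid = np.linspace(0, 1, 200)
            ax.plot(grid, np.polynomial.polynomial.polyval(grid, self.coefficients),
                    label=f"degree-{self.degree} fit")
        ax.set_xlabel(r"$\lambda$")
        ax.set_ylabel(r"$\langle \partial H/\partial\lambda \rangle$ (kJ/mol)")
        ax.legend()
        return ax


class ThermodynamicIntegration:
    """TI estimator for one alchemical leg.

    Parameters
    ----------
    series : LambdaSeries
        Per-lambda dH/dlambda samples.
    direction : str
        Recorded alchemical direction of the leg.
    """

    def __init__(self, series: LambdaSeries, direction: str = "forward") -> None:
        if series.n_lambdas < 2:
            raise ValueError("TI requires at least 2 lambda points")
        self.series = series
        self.direction = direction

    def fit(
        self,
        method: str = "polynomial",
        degree: int | None = None,
        n_bootstrap: int = _N_BOOTSTRAP,
        seed: int = 0,
    ) -> TIResults:
        """Estimate the leg free energy.

        Parameters
        ----------
        method : {"polynomial", "trapezoid"}
        degree : int, optional
            Fixed polynomial degree. By default the degree minimizing the
            leave-one-out cross-validated squared error over degrees 1-6
            (capped below the number of lambda points) is used.
        n_bootstrap, seed :
            Residual-bootstrap settings for the polynomial stderr.
        """
        if method == "trapezoid":
            return self._fit_trapezoid()
        if method == "polynomial":
            return self._fit_polynomial(degree, n_bootstrap, seed)
        raise ValueError(f"unknown method {method!r}")

    def _fit_trapezoid(self) -> TIResults:
        lam = np.asarray(self.series.lambda_values)
        y = self.series.means()
        w = _trap_weights(lam)
        value = float(w @ y)
        stderr = float(np.sqrt(w**2 @ self.series.stderrs() ** 2))
        est = FreeEnergyEstimate(value, stderr, "TI-trap", self.direction)
        return TIResults(est, "TI-trap", None, None, None, self)

    def _fit_polynomial(self, degree, n_bootstrap, seed) -> TIResults:
        lam = np.asarray(self.series.lambda_values)
        y = self.series.means()
        n = lam.size
        cv_errors = None
        if degree is None:
            candidates = [d for d in range(1, _MAX_CV_DEGREE + 1) if d < n]
            cv_errors = {d: _loo_cv_error(lam, y, d) for d in candidates}
            degree = min(cv_errors, key=lambda d: (cv_errors[d], d))
        elif degree >= n:
            raise ValueError(
                f"degree {degree} requires more than {n} lambda points"
            )
        L, V = _integral_functional(lam, degree)
        coef = np.linalg.pinv(V) @ y
        value = float(L @ y)
        fitted = V @ coef
        resid = y - fitted
        # residual bootstrap: resample residuals onto the fitted curve, refit
        # at the chosen degree; the refit integral is the linear map L @ y*.
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_bootstrap, n))
        boot = L @ fitted + (L * resid[idx]).sum(axis=1)
        stderr = float(boot.std(ddof=1)) if n_bootstrap > 1 else 0.0
        est = FreeEnergyEstimate(value, stderr, "TI-poly", self.direction)
        return TIResults(est, "TI-poly", degree, coef, cv_errors, self)


def ti_trapezoid(series: LambdaSeries, direction: str = "forward") -> FreeEnergyEstimate:
    """Trapezoid-rule TI over the sampled lambda grid."""
    return ThermodynamicIntegration(series, direction).fit(method="trapezoid").estimate


def ti_polynomial(
    series: LambdaSeries,
    degree: int | None = None,
    direction: str = "forward",
    seed: int = 0,
) -> FreeEnergyEstimate:
    """Polynomial-regression TI integrated analytically over [0, 1]."""
    return (
        ThermodynamicIntegration(series, direction)
        .fit(method="polynomial", degree=degree, seed=seed)
        .estimate
    )
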