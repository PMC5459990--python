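"""Climatic–edaphic forest suitability (CEFS).

The pre-human occurrence of moist forest is modelled as a logistic function
of five natural predictors — topsoil sand and clay fractions (%), topsoil
bulk density (g/cm^3), a clay×density interaction, rainfall seasonality
(MSI) and mean annual rainfall (MAR, mm/yr):

    log-odds = th0 + th1*sand + th2*clay + th3*rho + th4*clay*rho
               + th5*M + th6*P

The fitted log-odds itself is the CEFS statistic: the signed distance-like
coordinate perpendicular to the decision boundary, with CEFS = 0 the 50%
probability contour separating predicted forest from non-forest.  A
reference coefficient set estimated on Amazon-basin rasters ships as
``SuitabilityModel.reference()``.

Soil suitability ``pi`` is the soil part of the same linear predictor,
centred by a constant ``pi_c`` so that pi = 0 means "typical soil".

Fitting is L2-penalised (ridge) logistic regression so collinearity among
the predictors is not an issue; the model exposes both raw coefficients (on
original units) and standardized ones (z-scored predictors, the interaction
standardized as its own derived column).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

__all__ = [
    "COEF_NAMES",
    "REFERENCE_THETA",
    "REFERENCE_THETA_STD",
    "SuitabilityModel",
    "RidgeLogistic",
    "RidgeLogisticResults",
    "forest_probability",
    "predict_forest",
    "kappa_agreement",
    "simulate_samples",
]

COEF_NAMES = ("intercept", "sand", "clay", "density", "clay_density", "msi", "mar")

#: Reference coefficients of the Amazon forest-occurrence regression
#: (raw scale: sand/clay %, density g/cm^3, MSI dimensionless, MAR mm/yr).
REFERENCE_THETA = np.array([4.16, 2.38e-2, -1.88e-1, -5.99, 1.83e-1, -7.05, 2.90e-3])

#: Standardized coefficients reported alongside the reference fit.
REFERENCE_THETA_STD = np.array([1.80, 6.08e-1, 1.10, -9.09e-2, 4.79e-1, -1.09, 2.29])

_PREDICTORS = ("sand", "clay", "density", "msi", "mar")


@dataclass(frozen=True)
class SuitabilityModel:
    """A fixed logistic suitability model (coefficients + soil centring)."""

    theta: np.ndarray
    theta_std: np.ndarray | None = None
    pi_c: float = 0.0

    def __post_init__(self) -> None:
        th = np.asarray(self.theta, dtype=float)
        if th.shape != (7,):
            raise ValueError("theta must have exactly 7 components")
        object.__setattr__(self, "theta", th)
        if self.theta_std is not None:
            ts = np.asarray(self.theta_std, dtype=float)
            if ts.shape != (7,):
                raise ValueError("theta_std must have exactly 7 components")
            object.__setattr__(self, "theta_std", ts)

    @classmethod
    def reference(cls, pi_c: float = 0.0) -> "SuitabilityModel":
        """The shipped Amazon-regression coefficient set."""
        return cls(REFERENCE_THETA.copy(), REFERENCE_THETA_STD.copy(), pi_c)

    # -- linear predictor ---------------------------------------------------

    def log_odds(self, *, sand=None, clay=None, density=None, msi=None, mar=None):
        """CEFS log-odds; vectorised over grids/arrays.

        Raises a ValueError naming the first missing predictor.
        """
        vals = {}
        for name, v in (("sand", sand), ("clay", clay), ("density", density),
                        ("msi", msi), ("mar", mar)):
            if v is None:
                raise ValueError(f"missing predictor: {name!r}")
            vals[name] = np.asarray(v, dtype=float)
        th = self.theta
        return (th[0] + th[1] * vals["sand"] + th[2] * vals["clay"]
                + th[3] * vals["density"] + th[4] * vals["clay"] * vals["density"]
                + th[5] * vals["msi"] + th[6] * vals["mar"])

    def cefs(self, fields):
        """CEFS grid from an :class:`~firesavanna.landscape.EnvironmentalFields`."""
        return self.log_odds(sand=fields.sand, clay=fields.clay,
                             density=fields.density, msi=fields.M, mar=fields.P)

    def soil_term(self, sand, clay, density):
        th = self.theta
        sand = np.asarray(sand, dtype=float)
        clay = np.asarray(clay, dtype=float)
        density = np.asarray(density, dtype=float)
        return th[1] * sand + th[2] * clay + th[3] * density + th[4] * clay * density

    def soil_pi(self, sand, clay, density):
        """Soil suitability pi: the soil linear term centred at pi_c."""
        return self.soil_term(sand, clay, density) - self.pi_c

    def with_soil_reference(self, sand, clay, density) -> "SuitabilityModel":
        """Return a copy whose pi_c makes pi = 0 at the given reference soil
        (typically the landscape's median soils)."""
        pi_c = float(np.median(self.soil_term(sand, clay, density)))
        return SuitabilityModel(self.theta, self.theta_std, pi_c)

    # -- prediction ---------------------------------------------------------

    def predict(self, **predictors):
        return predict_forest(self.log_odds(**predictors))

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        std = self.theta_std if self.theta_std is not None else np.full(7, np.nan)
        return pd.DataFrame({"index": range(7), "name": COEF_NAMES,
                             "theta": self.theta, "theta_std": std})

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# pi_c={self.pi_c!r}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SuitabilityModel":
        with open(path) as fh:
            first = fh.readline()
            pi_c = 0.0
            if first.startswith("#"):
                pi_c = float(first.split("=", 1)[1])
                body = fh.read()
            else:
                body = first + fh.read()
        df = pd.read_csv(io.StringIO(body))
        theta_std = df["theta_std"].to_numpy()
        if np.isnan(theta_std).all():
            theta_std = None
        return cls(df["theta"].to_numpy(), theta_std, pi_c)


def forest_probability(log_odds):
    """Logistic transform of the log-odds; 0.5 exactly at the boundary."""
    return expit(np.asarray(log_odds, dtype=float))


def predict_forest(log_odds):
    """Forest is predicted strictly beyond the decision boundary (log-odds
    exactly 0 classifies as non-forest)."""
    return np.asarray(log_odds, dtype=float) > 0.0


def kappa_agreement(predicted, observed) -> float:
    """Cohen's kappa between two boolean maps.

    Chance agreement uses the marginal products.  When both maps are constant
    and identical (p_e = 1) the maps agree perfectly and 1.0 is returned by
    convention.
    """
    a = np.asarray(predicted, dtype=bool).ravel()
    b = np.asarray(observed, dtype=bool).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must have the same shape")
    if a.size == 0:
        raise ValueError("maps are empty")
    n = a.size
    p_o = np.mean(a == b)
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else -1.0
    return float((p_o - p_e) / (1.0 - p_e))


# ---------------------------------------------------------------------------
# Ridge logistic fitting


def _design(df: pd.DataFrame) -> np.ndarray:
    for name in _PREDICTORS:
        if name not in df.columns:
            raise ValueError(f"missing predictor column: {name!r}")
    X = df[list(_PREDICTORS)].to_numpy(dtype=float)
    interaction = (df["clay"].to_numpy(dtype=float)
                   * df["density"].to_numpy(dtype=float))
    # column order: sand, clay, density, clay*density, msi, mar
    return np.column_stack([X[:, 0], X[:, 1], X[:, 2], interaction, X[:, 3], X[:, 4]])


class RidgeLogistic:
    """L2-penalised logistic regression of forest occurrence on the five
    natural predictors plus the clay×density interaction.

    Parameters
    ----------
    endog : array-like of bool
        Forest occurrence labels.
    exog : DataFrame with columns sand, clay, density, msi, mar
        Predictors in their documented units.

    The penalty is expressed per sample, so duplicating every observation
    leaves the fit unchanged.  Ridge is applied on the standardized scale
    (predictors z-scored, interaction standardized as a derived column); raw
    coefficients are recovered by rescaling, the intercept is unpenalised.
    """

    def __init__(self, endog, exog: pd.DataFrame):
        y = np.asarray(endog, dtype=bool)
        X = _design(exog)
        if y.shape[0] != X.shape[0]:
            raise ValueError("endog and exog lengths differ")
        if y.all() or not y.any():
            raise ValueError("degenerate fit: both classes must be present")
        if y.shape[0] < 7:
            raise ValueError("need at least as many samples as coefficients")
        self.endog = y
        self.exog = X

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "forest") -> "RidgeLogistic":
        return cls(df[label].to_numpy(), df)

    def fit(self, penalty: float | str = "cv", max_iter: int = 2000,
            cv: int = 5, random_state: int = 0) -> "RidgeLogisticResults":
        """Fit; ``penalty`` is the per-sample ridge weight, or ``"cv"`` to
        select it by 5-fold cross-validated deviance."""
        X, y = self.exog, self.endog
        n = X.shape[0]
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant predictor column; cannot standardize")
        Z = (X - mu) / sd

        if penalty == "cv":
            Cs = np.logspace(-4, 4, 17)
            clf = LogisticRegressionCV(
                Cs=Cs, cv=cv, scoring="neg_log_loss", tol=1e-6,
                solver="lbfgs", max_iter=max_iter, random_state=random_state,
            ).fit(Z, y)
            C = float(clf.C_[0])
            penalty_value = 1.0 / (C * n)
        else:
            penalty_value = float(penalty)
            if penalty_value < 0:
                raise ValueError("penalty must be non-negative")
            # sklearn objective: ||w||^2/2 + C * sum(loss); per-sample lambda
            # means total penalty lambda*n*||w||^2/2, i.e. C = 1/(lambda*n).
            C = 1.0 / (penalty_value * n) if penalty_value > 0 else np.inf
            clf = LogisticRegression(
                C=C, solver="lbfgs", max_iter=max_iter, tol=1e-6,
            ).fit(Z, y)

        if np.any(clf.n_iter_ >= max_iter):
            raise RuntimeError(
                f"ridge logistic fit did not converge in {max_iter} iterations "
                f"(n={n}, penalty={penalty_value:g})"
            )

        beta_std = clf.coef_.ravel()
        beta0_std = float(clf.intercept_[0])
        beta_raw = beta_std / sd
        beta0_raw = beta0_std - float((beta_std * mu / sd).sum())
        theta = np.concatenate([[beta0_raw], beta_raw])
        theta_std = np.concatenate([[beta0_std], beta_std])
        model = SuitabilityModel(theta, theta_std)
        return RidgeLogisticResults(
            model=model, penalty=penalty_value, n_obs=n,
            n_iter=int(np.max(clf.n_iter_)),
            predictor_means=mu, predictor_sds=sd,
            log_loss_=self._deviance(model, X, y),
        )

    @staticmethod
    def _deviance(model: SuitabilityModel, X, y) -> float:
        eta = model.theta[0] + X @ model.theta[1:]
        p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        return float(-2.0 * np.mean(np.where(y, np.log(p), np.log1p(-p))))


@dataclass
class RidgeLogisticResults:
    """Fitted ridge logistic suitability model with diagnostics."""

    model: SuitabilityModel
    penalty: float
    n_obs: int
    n_iter: int
    predictor_means: np.ndarray
    predictor_sds: np.ndarray
    log_loss_: float

    @property
    def params(self) -> np.ndarray:
        return self.model.theta

    @property
    def params_std(self) -> np.ndarray:
        return self.model.theta_std

    def predict(self, **predictors):
        return self.model.predict(**predictors)

    def summary(self) -> str:
        lines = [
            "Ridge logistic forest-suitability model",
            "=" * 47,
            f"n obs: {self.n_obs}    penalty (per sample): {self.penalty:.3g}",
            f"iterations: {self.n_iter}    mean deviance: {self.log_loss_:.4f}",
            "-" * 47,
            f"{'term':<14}{'theta':>14}{'theta_std':>14}",
        ]
        for name, t, ts in zip(COEF_NAMES, self.model.theta, self.model.theta_std):
            lines.append(f"{name:<14}{t:>14.4g}{ts:>14.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Synthetic regression samples


def simulate_samples(n: int, model: SuitabilityModel | None = None, seed=None,
                     *, sand_sd: float = 25.0, clay_sd: float = 6.0,
                     density_sd: float = 0.15, msi_sd: float = 0.155,
                     mar_sd: float = 500.0) -> pd.DataFrame:
    """Draw predictor samples in realistic ranges and label them through the
    model's own forest probability (Bernoulli).

    Used to build a labelled sample whose generating coefficients are known,
    e.g. for parameter-recovery experiments.
    """
    if model is None:
        model = SuitabilityModel.reference()
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "sand": np.clip(rng.normal(40.0, sand_sd, n), 0.0, 100.0),
        "clay": np.clip(rng.normal(30.0, clay_sd, n), 0.0, 100.0),
        "density": np.clip(rng.normal(1.3, density_sd, n), 0.5, 2.2),
        "msi": np.clip(rng.normal(0.40, msi_sd, n), 0.0, 1.0),
        "mar": np.clip(rng.normal(1700.0, mar_sd, n), 0.0, None),
    })
    p = forest_probability(model.log_odds(**{k: df[k].to_numpy() for k in _PREDICTORS}))
    df["forest"] = rng.random(n) < p
    return df
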