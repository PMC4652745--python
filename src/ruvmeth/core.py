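"""Core estimation machinery for negative-control GLS differential methylation.

The model is ``Y = Z gamma + X beta + W alpha + eps`` where ``Y`` is an
n_samples x n_features matrix of M-values, ``X`` holds the factor of
interest, ``Z`` the known covariates (intercept etc.) and ``W`` unknown
unwanted factors.  RUV-inverse never estimates ``W`` explicitly: it fits a
generalized least squares (GLS) regression of every feature on ``[Z X]``,
weighting by the inverse of an empirical sample-by-sample covariance matrix
computed from negative-control features.  Controls carry no signal from
``X``, so their covariance captures the unwanted-variation structure.

Because the plain GLS standard error is identical for every feature, the
per-feature standard errors come from the "inverse method": the model is
repeatedly refit with an extra randomized design column whose true
coefficient is zero, and the spread of its estimated coefficients across
replicates measures each feature's variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import scipy.linalg as sla
import scipy.stats as st
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MethylationMatrix",
    "DesignSpec",
    "ControlSet",
    "ControlOrigin",
    "GlsContext",
    "RuvFit",
    "RandomColumnReplicate",
    "ModeratedStats",
    "control_covariance",
    "gls_fit",
    "inverse_method_se",
    "t_and_p",
    "bh_adjust",
    "moderate_variances",
    "rank_features",
]

# condition-number threshold beyond which the control covariance is ridged
_COND_LIMIT = 1e12


def _as_unique_tuple(ids: Sequence[str], what: str) -> tuple[str, ...]:
    out = tuple(str(i) for i in ids)
    if len(set(out)) != len(out):
        dupes = sorted({i for i in out if out.count(i) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")
    return out


@dataclass(frozen=True)
class MethylationMatrix:
    """Observed data Y: samples in rows, features in columns, M-value scale.

    On disk methylation matrices are conventionally features x samples; the
    reader transposes into this samples x features layout, which matches the
    RUV regression literature.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", _as_unique_tuple(self.sample_ids, "sample"))
        object.__setattr__(self, "feature_ids", _as_unique_tuple(self.feature_ids, "feature"))
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_features(self, ids: Sequence[str]) -> "MethylationMatrix":
        index = {f: j for j, f in enumerate(self.feature_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        cols = [index[i] for i in ids]
        return MethylationMatrix(self.values[:, cols], self.sample_ids, tuple(ids))

    def select_samples(self, ids: Sequence[str]) -> "MethylationMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [index[i] for i in ids]
        return MethylationMatrix(self.values[rows, :], tuple(ids), self.feature_ids)


@dataclass(frozen=True)
class DesignSpec:
    """Design matrices for the mean model: X (interest) and Z (known covariates)."""

    X: np.ndarray
    Z: np.ndarray
    coef_names: tuple[str, ...] = ("group",)

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if X.shape[0] == 1 and X.shape[1] > 1:
            X = X.T
        if Z.shape[0] == 1 and Z.shape[1] > 1:
            Z = Z.T
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Z", Z)
        object.__setattr__(self, "coef_names", tuple(self.coef_names))
        if X.shape[0] != Z.shape[0]:
            raise ValueError("X and Z must have the same number of rows (samples)")
        if len(self.coef_names) != X.shape[1]:
            raise ValueError("coef_names length must equal the number of X columns")
        M = self.full_matrix
        if np.linalg.matrix_rank(M) < M.shape[1]:
            raise ValueError("[Z X] is rank deficient")
        if M.shape[0] <= M.shape[1]:
            raise ValueError("need more samples than design columns")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    @property
    def full_matrix(self) -> np.ndarray:
        """[Z X], known covariates first."""
        return np.hstack([self.Z, self.X])

    @property
    def residual_df(self) -> float:
        return self.n_samples - np.linalg.matrix_rank(self.Z) - np.linalg.matrix_rank(self.X)

    @classmethod
    def from_groups(cls, groups: Sequence, name: str = "group") -> "DesignSpec":
        """Intercept-plus-indicator design from a two-level group label vector."""
        levels = sorted(set(groups))
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 group levels, got {levels}")
        x = np.array([1.0 if g == levels[1] else 0.0 for g in groups])[:, None]
        z = np.ones((len(x), 1))
        return cls(X=x, Z=z, coef_names=(f"{name}[{levels[1]}vs{levels[0]}]",))


class ControlOrigin(str, Enum):
    platform_negative = "platform_negative"
    empirical = "empirical"
    user = "user"


@dataclass(frozen=True)
class ControlSet:
    """Ordered set of feature ids designated as negative controls."""

    feature_ids: tuple[str, ...]
    origin: ControlOrigin = ControlOrigin.user

    def __post_init__(self):
        object.__setattr__(self, "feature_ids", _as_unique_tuple(self.feature_ids, "control"))
        object.__setattr__(self, "origin", ControlOrigin(self.origin))
        if len(self.feature_ids) == 0:
            raise ValueError("control set is empty")

    def __len__(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class GlsContext:
    """Sample covariance estimated from controls, plus the ridge actually applied."""

    sigma_c: np.ndarray
    ridge_lambda: float
    n_controls_used: int

    def __post_init__(self):
        sigma = np.asarray(self.sigma_c, dtype=float)
        object.__setattr__(self, "sigma_c", sigma)
        if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
            raise ValueError("sigma_c must be square")
        if not np.allclose(sigma, sigma.T, atol=1e-8):
            raise ValueError("sigma_c must be symmetric")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be nonnegative")

    @property
    def effective(self) -> np.ndarray:
        """sigma_c + lambda * I, the weight matrix inverted in the GLS fit."""
        return self.sigma_c + self.ridge_lambda * np.eye(self.sigma_c.shape[0])


@dataclass(frozen=True)
class RandomColumnReplicate:
    """One inverse-method replicate: the randomized column and its coefficients."""

    z_b: np.ndarray
    gamma_hat: np.ndarray


@dataclass(frozen=True)
class RuvFit:
    """Per-feature differential methylation statistics from one RUV-inverse fit."""

    feature_ids: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    fdr: np.ndarray
    rank: np.ndarray
    df: float
    n_replicates_B: int
    seed: int
    replicates: tuple[RandomColumnReplicate, ...] = field(default=(), repr=False)

    def __post_init__(self):
        m = len(self.feature_ids)
        for name in ("beta", "se", "t_stat", "p_value", "fdr", "rank"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (m,):
                raise ValueError(f"{name} must have shape ({m},)")
            object.__setattr__(self, name, arr)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_id": list(self.feature_ids),
                "coef": self.beta,
                "se": self.se,
                "t": self.t_stat,
                "pvalue": self.p_value,
                "fdr": self.fdr,
                "rank": self.rank,
            }
        )


def _residualize(values: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Project columns of ``values`` onto the orthogonal complement of ``basis``."""
    coef, *_ = np.linalg.lstsq(basis, values, rcond=None)
    return values - basis @ coef


def control_covariance(
    Y: MethylationMatrix,
    design: DesignSpec,
    controls: ControlSet,
    ridge_lambda: float | None = None,
) -> GlsContext:
    """Empirical sample covariance of the negative-control features.

    Control M-values are residualized against the known covariates Z (not X:
    controls are assumed unassociated with the factor of interest, and
    removing Z stops mean offsets from dominating) and the covariance is
    ``Sigma_c = R_c R_c' / n_c``.

    Parameters
    ----------
    ridge_lambda
        Explicit ridge added to the diagonal. ``None`` (default) applies
        ``0.1 * trace(Sigma_c) / n_samples`` automatically when the controls
        are too few (``n_c < n_samples``) or the covariance is numerically
        singular (condition number above 1e12), and 0 otherwise.
    """
    if design.n_samples != Y.n_samples:
        raise ValueError("design and matrix sample counts differ")
    unknown = [f for f in controls.feature_ids if f not in set(Y.feature_ids)]
    if unknown:
        raise KeyError(f"control ids not in the matrix: {unknown[:5]}")
    if len(controls) < 2:
        raise ValueError("need at least 2 control features")

    Yc = Y.select_features(controls.feature_ids).values
    Rc = _residualize(Yc, design.Z)
    if not np.any(np.abs(Rc) > 1e-12):
        raise ValueError("all control features are constant after removing Z (zero covariance)")
    n_c = Rc.shape[1]
    sigma = (Rc @ Rc.T) / n_c
    sigma = 0.5 * (sigma + sigma.T)

    if ridge_lambda is None:
        needs_ridge = n_c < Y.n_samples
        if not needs_ridge:
            eigvals = np.linalg.eigvalsh(sigma)
            needs_ridge = eigvals[0] <= 0 or eigvals[-1] / max(eigvals[0], 1e-300) > _COND_LIMIT
        ridge_lambda = 0.1 * np.trace(sigma) / Y.n_samples if needs_ridge else 0.0
        if needs_ridge:
            logger.info(
                "control covariance near-singular (n_controls=%d, n_samples=%d); "
                "applying ridge lambda=%.4g",
                n_c,
                Y.n_samples,
                ridge_lambda,
            )
    return GlsContext(sigma_c=sigma, ridge_lambda=float(ridge_lambda), n_controls_used=n_c)


def _gls_solves(design: DesignSpec, ctx: GlsContext):
    """Shared factorizations: returns (cho, M, Si_M, G_cho) for the base design."""
    M = design.full_matrix
    sigma = ctx.effective
    if sigma.shape[0] != design.n_samples:
        raise ValueError("covariance size does not match the number of samples")
    try:
        cho = sla.cho_factor(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError("effective covariance is not positive definite") from exc
    Si_M = sla.cho_solve(cho, M)
    return cho, M, Si_M


def gls_fit(Y: MethylationMatrix, design: DesignSpec, ctx: GlsContext) -> np.ndarray:
    """GLS coefficients of the factor of interest for every feature.

    Solves ``beta_hat = (M' Sigma^-1 M)^-1 M' Sigma^-1 Y`` with ``M = [Z X]``
    and returns only the X block, shape ``(n_features,)`` when X has one
    column, else ``(n_features, p)``.
    """
    if Y.n_samples != design.n_samples:
        raise ValueError("matrix and design sample counts differ")
    _, M, Si_M = _gls_solves(design, ctx)
    G = M.T @ Si_M
    theta = np.linalg.solve(G, Si_M.T @ Y.values)  # (q+p) x m
    beta = theta[design.q :, :].T
    return beta[:, 0] if design.p == 1 else beta


def _sandwich_var_unit_noise(M: np.ndarray, cho) -> np.ndarray:
    """Diagonal of (M'S^-1 M)^-1 M'S^-1 S^-1 M (M'S^-1 M)^-1: coefficient
    variances under unit-variance iid noise for the GLS estimator weighted by
    S^-1."""
    Si_M = sla.cho_solve(cho, M)
    G = M.T @ Si_M
    C = np.linalg.solve(G, Si_M.T)  # estimator matrix, k x n
    return np.einsum("ij,ij->i", C, C)


def inverse_method_se(
    Y: MethylationMatrix,
    design: DesignSpec,
    ctx: GlsContext,
    B: int = 50,
    seed: int = 0,
    max_redraws: int = 10,
    keep_replicates: bool = True,
) -> tuple[np.ndarray, tuple[RandomColumnReplicate, ...]]:
    """Per-feature standard errors by the randomized-extra-column method.

    For each of ``B`` replicates a random column is drawn iid standard
    normal, residualized against ``[Z X]`` and normalized; the model is refit
    with this extra column and its coefficient recorded for every feature.
    Since the column has no true effect, the spread of these coefficients
    reflects each feature's noise level:

        SE_g = sqrt( kappa * mean_b gamma_hat_{g,b}^2 )

    The calibration constant ``kappa`` is analytic: the ratio of the
    unit-noise sampling variance of beta_hat to the mean unit-noise sampling
    variance of the random-column coefficient, so that under homoscedastic
    Gaussian noise E[SE_g^2] equals the true sampling variance of beta_hat_g.
    Deterministic given (seed, B).
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if design.p != 1:
        raise ValueError("inverse-method SEs are defined for a single column of interest")
    if Y.n_samples != design.n_samples:
        raise ValueError("matrix and design sample counts differ")

    cho, M, Si_M = _gls_solves(design, ctx)
    a_x = _sandwich_var_unit_noise(M, cho)[-1]

    rng = np.random.default_rng(seed)
    n = design.n_samples
    gammas = np.empty((B, Y.n_features))
    v_b = np.empty(B)
    replicates = []
    for b in range(B):
        for attempt in range(max_redraws + 1):
            z = rng.standard_normal(n)
            z = _residualize(z[:, None], M)[:, 0]
            norm = np.linalg.norm(z)
            if norm > 1e-8:
                z = z / norm
                break
        else:
            raise RuntimeError(
                f"random column collinear with the design after {max_redraws} redraws"
            )
        Mb = np.hstack([M, z[:, None]])
        Si_Mb = sla.cho_solve(cho, Mb)
        Gb = Mb.T @ Si_Mb
        theta = np.linalg.solve(Gb, Si_Mb.T @ Y.values)
        gammas[b] = theta[-1]
        Cb = np.linalg.solve(Gb, Si_Mb.T)
        v_b[b] = float(np.dot(Cb[-1], Cb[-1]))
        if keep_replicates:
            replicates.append(RandomColumnReplicate(z_b=z, gamma_hat=theta[-1].copy()))

    kappa = a_x / v_b.mean()
    se = np.sqrt(kappa * np.mean(gammas**2, axis=0))
    return se, tuple(replicates)


def t_and_p(beta: np.ndarray, se: np.ndarray, df: float) -> tuple[np.ndarray, np.ndarray]:
    """t statistics and two-sided p-values on a Student-t reference with ``df``.

    Features with SE = 0 get t = 0, p = 1 when the coefficient is also zero
    (no evidence either way from a perfectly fit feature) and p = 0 with a
    logged warning otherwise.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se < 0):
        raise ValueError("standard errors must be nonnegative")
    t = np.zeros_like(beta)
    ok = se > 0
    t[ok] = beta[ok] / se[ok]
    p = np.ones_like(beta)
    p[ok] = 2.0 * st.t.sf(np.abs(t[ok]), df)
    degenerate = (~ok) & (beta != 0)
    if np.any(degenerate):
        logger.warning("%d features with zero SE but nonzero coefficient; p set to 0",
                       int(degenerate.sum()))
        p[degenerate] = 0.0
        t[degenerate] = np.sign(beta[degenerate]) * np.inf
    return t, p


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def rank_features(
    p: np.ndarray, t: np.ndarray, feature_ids: Sequence[str]
) -> np.ndarray:
    """Deterministic 1..m ranks: p ascending, |t| descending, id lexicographic."""
    order = sorted(
        range(len(feature_ids)), key=lambda i: (p[i], -abs(t[i]), feature_ids[i])
    )
    ranks = np.empty(len(order), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


@dataclass(frozen=True)
class ModeratedStats:
    se: np.ndarray
    df: float
    t_stat: np.ndarray
    p_value: np.ndarray
    d0: float
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    # Newton iteration on trigamma(x) = y
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x = x + dif
        if abs(dif / x) < 1e-8:
            break
    return float(x)


def moderate_variances(
    se: np.ndarray, df: float, beta: np.ndarray
) -> ModeratedStats:
    """Empirical-Bayes shrinkage of per-feature variances toward a common prior.

    The squared standard errors are treated as scaled chi-square variance
    estimates on ``df`` degrees of freedom; a scaled-F model is moment-matched
    on their logs to estimate the prior (d0, s0^2), and each variance is
    shrunk to ``(d0 s0^2 + df s^2) / (d0 + df)``.  Moderated t statistics use
    ``df + d0`` degrees of freedom.  If moment estimation fails the
    unmoderated statistics are returned with a logged warning.
    """
    se = np.asarray(se, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if df <= 0:
        raise ValueError("df must be positive")
    pos = se > 0
    if pos.sum() < 4:
        raise ValueError("need at least 4 features with positive SE")

    s2 = se[pos] ** 2
    z = np.log(s2)
    if np.ptp(z) < 1e-12:
        # all variances identical: infinite prior df centred exactly on them
        d0, s0_sq = np.inf, float(s2[0])
    else:
        e = z - digamma(df / 2.0) + np.log(df / 2.0)
        evar = np.var(e, ddof=1) - polygamma(1, df / 2.0)
        if evar > 0:
            d0 = 2.0 * _trigamma_inverse(evar)
            s0_sq = float(np.exp(np.mean(e) + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0, s0_sq = np.inf, float(np.exp(np.mean(e)))

    if not np.isfinite(s0_sq) or s0_sq <= 0:
        logger.warning("variance moderation failed; returning unmoderated statistics")
        t, p = t_and_p(beta, se, df)
        return ModeratedStats(se=se, df=df, t_stat=t, p_value=p, d0=0.0, s0_sq=float("nan"))

    s2_all = se**2
    if np.isinf(d0):
        s2_tilde = np.full_like(s2_all, s0_sq)
        df_total = 1e6  # effectively normal reference
    else:
        s2_tilde = (d0 * s0_sq + df * s2_all) / (d0 + df)
        df_total = df + d0
    se_tilde = np.sqrt(s2_tilde)
    t, p = t_and_p(beta, se_tilde, df_total)
    return ModeratedStats(
        se=se_tilde, df=float(df_total), t_stat=t, p_value=p, d0=float(d0), s0_sq=s0_sq
    )
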