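"""Seeded generator of 450k-like datasets with known ground truth.

The generator draws from the same linear model the estimator assumes,

    Y = Z gamma + X beta + W alpha + eps,

with a balanced two-group factor of interest X, a sparse effect vector beta,
``k`` unwanted factors W loading on both the CpG block and a separate
negative-control block, and heteroscedastic Gaussian noise.  Two mechanisms
emulate the hard situations seen in combined-cohort methylation studies:

* ``confounding_rho`` correlates the first unwanted factor with the group
  factor (a batch partially aligned with the biology, as happens when
  studies with different case fractions are merged);
* ``mislabel_fraction`` flips a fraction of group labels after the data are
  generated (misreported phenotypes / sample mix-ups).

The negative-control block receives only unwanted and technical variation —
no beta — mirroring platform negative controls, whose permuted probe
sequences cannot carry biological signal.  Data are generated directly on
the M-value scale; ``ruvmeth.preprocess.m_to_beta`` maps to the beta scale
for I/O realism if needed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import DesignSpec, MethylationMatrix

__all__ = [
    "SimulationParams",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate",
    "preset",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator; defaults give a mid-sized confounded study.

    ``noise_sd_median`` and ``noise_sd_log_sigma`` parameterize the lognormal
    per-feature noise scale (median 0.25 on the M-value scale, a typical
    residual spread for array CpGs, with some probes several-fold noisier).
    """

    n_samples: int = 60
    n_cpg_features: int = 2000
    n_inc_features: int = 613
    p_true_positive: float = 0.05
    effect_size_beta: float = 1.0
    k_unwanted: int = 1
    alpha_scale_cpg: float = 1.0
    alpha_scale_inc: float = 1.0
    confounding_rho: float = 0.0
    mislabel_fraction: float = 0.0
    noise_sd_median: float = 0.25
    noise_sd_log_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.n_inc_features < 2:
            raise ValueError("need at least 2 negative-control features")
        for name in ("p_true_positive", "mislabel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(self.confounding_rho) >= 1.0:
            raise ValueError("confounding_rho must lie strictly inside (-1, 1)")
        for name in ("effect_size_beta", "alpha_scale_cpg", "alpha_scale_inc",
                     "noise_sd_median", "noise_sd_log_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.k_unwanted < 0:
            raise ValueError("k_unwanted must be nonnegative")


@dataclass(frozen=True)
class SimulationTruth:
    beta: np.ndarray  # true effect per CpG feature
    W: np.ndarray  # n_samples x k unwanted factors
    alpha_cpg: np.ndarray  # k x n_cpg loadings
    alpha_inc: np.ndarray  # k x n_inc loadings
    noise_sd_cpg: np.ndarray
    noise_sd_inc: np.ndarray
    true_positive_ids: frozenset
    true_labels: np.ndarray  # group indicator before any mislabelling


@dataclass(frozen=True)
class SimulatedDataset:
    Y_cpg: MethylationMatrix
    Y_inc: MethylationMatrix
    design: DesignSpec  # X column reflects the (possibly mislabeled) observed labels
    truth: SimulationTruth


def simulate(params: SimulationParams) -> SimulatedDataset:
    """Draw one dataset; byte-reproducible from ``params.seed``."""
    p = params
    rng = np.random.default_rng(p.seed)
    n, m, m_inc, k = p.n_samples, p.n_cpg_features, p.n_inc_features, p.k_unwanted

    sample_ids = tuple(f"s{i:04d}" for i in range(n))
    cpg_ids = tuple(f"cg{j:06d}" for j in range(m))
    inc_ids = tuple(f"neg{j:04d}" for j in range(m_inc))

    # balanced group indicator; extra sample (odd n) goes to group 0
    x = np.zeros(n)
    x[n // 2 :] = 1.0
    x_std = (x - x.mean()) / x.std()

    # unwanted factors; the first one is a latent-Gaussian mixture with the
    # requested correlation to the (standardized) group factor
    W = rng.standard_normal((n, k)) if k else np.zeros((n, 0))
    if k:
        rho = p.confounding_rho
        W[:, 0] = rho * x_std + np.sqrt(1.0 - rho**2) * W[:, 0]

    # sparse effects of interest with random sign
    n_tp = int(round(p.p_true_positive * m))
    tp_idx = rng.choice(m, size=n_tp, replace=False) if n_tp else np.array([], dtype=int)
    beta = np.zeros(m)
    if n_tp:
        beta[tp_idx] = p.effect_size_beta * rng.choice((-1.0, 1.0), size=n_tp)

    # feature baselines: bimodal around +-3 M-units, as real CpGs are mostly
    # fully methylated or unmethylated
    gamma_cpg = rng.choice((-3.0, 3.0), size=m) + 0.5 * rng.standard_normal(m)
    alpha_cpg = p.alpha_scale_cpg * rng.standard_normal((k, m)) if k else np.zeros((0, m))
    sd_cpg = p.noise_sd_median * np.exp(p.noise_sd_log_sigma * rng.standard_normal(m))
    eps = rng.standard_normal((n, m)) * sd_cpg
    Y_cpg = gamma_cpg + x[:, None] * beta + W @ alpha_cpg + eps

    # negative-control block: background-level baseline, unwanted + noise only
    gamma_inc = -4.0 + 0.25 * rng.standard_normal(m_inc)
    alpha_inc = p.alpha_scale_inc * rng.standard_normal((k, m_inc)) if k else np.zeros((0, m_inc))
    sd_inc = p.noise_sd_median * np.exp(p.noise_sd_log_sigma * rng.standard_normal(m_inc))
    Y_inc = gamma_inc + W @ alpha_inc + rng.standard_normal((n, m_inc)) * sd_inc

    observed = x.copy()
    n_flip = int(round(p.mislabel_fraction * n))
    if n_flip:
        flip = rng.choice(n, size=n_flip, replace=False)
        observed[flip] = 1.0 - observed[flip]

    design = DesignSpec(X=observed[:, None], Z=np.ones((n, 1)), coef_names=("group",))
    truth = SimulationTruth(
        beta=beta,
        W=W,
        alpha_cpg=alpha_cpg,
        alpha_inc=alpha_inc,
        noise_sd_cpg=sd_cpg,
        noise_sd_inc=sd_inc,
        true_positive_ids=frozenset(cpg_ids[j] for j in tp_idx),
        true_labels=x,
    )
    return SimulatedDataset(
        Y_cpg=MethylationMatrix(Y_cpg, sample_ids, cpg_ids),
        Y_inc=MethylationMatrix(Y_inc, sample_ids, inc_ids),
        design=design,
        truth=truth,
    )


_PRESETS = {
    # no unwanted variation at all: calibration checks and null behaviour
    "clean": SimulationParams(
        n_samples=60,
        n_cpg_features=2000,
        n_inc_features=613,
        p_true_positive=0.05,
        effect_size_beta=1.0,
        k_unwanted=0,
        alpha_scale_cpg=0.0,
        alpha_scale_inc=0.0,
        confounding_rho=0.0,
        mislabel_fraction=0.0,
        seed=101,
    ),
    # batch effects much larger than the effect of interest, independent of it
    "batch_dominated": SimulationParams(
        n_samples=60,
        n_cpg_features=2000,
        n_inc_features=613,
        p_true_positive=0.05,
        effect_size_beta=1.0,
        k_unwanted=1,
        alpha_scale_cpg=2.0,
        alpha_scale_inc=2.0,
        confounding_rho=0.0,
        mislabel_fraction=0.0,
        seed=102,
    ),
    # small effects, unwanted factor correlated 0.6 with the group label and
    # 5% of labels flipped: the hardest combined-cohort scenario
    "confounded_mislabel": SimulationParams(
        n_samples=60,
        n_cpg_features=2000,
        n_inc_features=613,
        p_true_positive=0.05,
        effect_size_beta=0.6,
        k_unwanted=1,
        alpha_scale_cpg=1.0,
        alpha_scale_inc=1.0,
        confounding_rho=0.6,
        mislabel_fraction=0.05,
        seed=103,
    ),
    # pervasive differential methylation (~40% of probes), cancer-like
    "high_dm": SimulationParams(
        n_samples=60,
        n_cpg_features=2000,
        n_inc_features=613,
        p_true_positive=0.4,
        effect_size_beta=2.0,
        k_unwanted=1,
        alpha_scale_cpg=1.0,
        alpha_scale_inc=1.0,
        confounding_rho=0.0,
        mislabel_fraction=0.0,
        seed=104,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> SimulationParams:
    """Named parameter bundle for a study scenario; keyword overrides allowed."""
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    return replace(base, **overrides) if overrides else base
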