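"""Two-stage RUV-inverse differential methylation (the RUVm procedure).

Stage 1 fits RUV-inverse using the platform's negative-control probe block
(Illumina negative controls, INCs — permuted sequences that should not
hybridize and carry only technical variation) to rank all CpGs by p-value.
Stage 2 designates the least-associated CpGs from that ranking as empirical
control probes (ECPs) and refits RUV-inverse with them; ECPs, unlike INCs,
are real CpG probes and so also capture biological unwanted variation such
as cell-composition differences.  Stage 2 may be iterated to refine the ECP
set, though one round usually suffices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import (
    ControlOrigin,
    ControlSet,
    DesignSpec,
    GlsContext,
    MethylationMatrix,
    RuvFit,
    bh_adjust,
    control_covariance,
    gls_fit,
    inverse_method_se,
    moderate_variances,
    rank_features,
    t_and_p,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EcpMethod",
    "EcpRule",
    "RuvmResult",
    "ruv_inverse_fit",
    "stage1_fit",
    "select_ecps",
    "stage2_fit",
    "ruvm",
    "baseline_fit",
]


class EcpMethod(str, Enum):
    fdr_cutoff = "fdr_cutoff"
    bottom_fraction = "bottom_fraction"


@dataclass(frozen=True)
class EcpRule:
    """How to pick empirical control probes from a ranked Stage-1 fit.

    ``fdr_cutoff`` keeps features whose FDR-adjusted p-value exceeds the
    threshold; ``bottom_fraction`` keeps the stated fraction of features with
    the largest p-values.  A fraction (or cut-off) around 0.5 is a sensible
    default when little is known about the expected amount of differential
    methylation; studies with pervasive signal (cancer-like, ~40% of probes
    associated) need FDR-based selection or a small fraction to avoid
    recruiting true positives as controls.
    """

    method: EcpMethod = EcpMethod.bottom_fraction
    threshold: float = 0.5

    def __post_init__(self):
        object.__setattr__(self, "method", EcpMethod(self.method))
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")


@dataclass(frozen=True)
class RuvmResult:
    stage1: RuvFit
    ecps: tuple[ControlSet, ...]
    stage2: RuvFit
    n_stage2_iterations: int
    intermediate_fits: tuple[RuvFit, ...] = ()


def ruv_inverse_fit(
    Y: MethylationMatrix,
    design: DesignSpec,
    ctx: GlsContext,
    B: int = 50,
    seed: int = 0,
    keep_replicates: bool = False,
) -> RuvFit:
    """One complete RUV-inverse fit: GLS coefficients, inverse-method SEs,
    t/p statistics, BH FDR and deterministic ranks."""
    beta = gls_fit(Y, design, ctx)
    se, reps = inverse_method_se(
        Y, design, ctx, B=B, seed=seed, keep_replicates=keep_replicates
    )
    df = design.residual_df
    t, p = t_and_p(beta, se, df)
    fdr = bh_adjust(p)
    rank = rank_features(p, t, Y.feature_ids)
    return RuvFit(
        feature_ids=Y.feature_ids,
        beta=beta,
        se=se,
        t_stat=t,
        p_value=p,
        fdr=fdr,
        rank=rank,
        df=float(df),
        n_replicates_B=B,
        seed=seed,
        replicates=reps,
    )


def stage1_fit(
    Y_cpg: MethylationMatrix,
    Y_inc: MethylationMatrix,
    design: DesignSpec,
    B: int = 50,
    seed: int = 0,
    ridge_lambda: float | None = None,
) -> RuvFit:
    """Stage 1: RUV-inverse on the CpG matrix with the platform negative-control
    block supplying the sample covariance."""
    if Y_inc.sample_ids != Y_cpg.sample_ids:
        raise ValueError("CpG and negative-control matrices must share samples in order")
    overlap = set(Y_inc.feature_ids) & set(Y_cpg.feature_ids)
    if overlap:
        raise ValueError(
            f"negative-control features also present among CpGs: {sorted(overlap)[:5]}"
        )
    controls = ControlSet(Y_inc.feature_ids, origin=ControlOrigin.platform_negative)
    ctx = control_covariance(Y_inc, design, controls, ridge_lambda=ridge_lambda)
    logger.info("stage 1: %d negative controls, ridge=%.4g", len(controls), ctx.ridge_lambda)
    return ruv_inverse_fit(Y_cpg, design, ctx, B=B, seed=seed)


def select_ecps(stage1: RuvFit, rule: EcpRule) -> ControlSet:
    """Designate the least-associated features of a fit as empirical controls."""
    m = stage1.n_features
    if m == 0:
        raise ValueError("empty fit")
    ids = np.array(stage1.feature_ids)
    if rule.method is EcpMethod.fdr_cutoff:
        mask = stage1.fdr > rule.threshold
        selected = ids[mask]
        if mask.any():
            selected = selected[np.argsort(stage1.rank[mask])]
    else:
        n_sel = int(np.floor(rule.threshold * m))
        order = np.argsort(-stage1.rank)  # worst-ranked (largest p) first
        selected = ids[order[:n_sel]]
    if len(selected) == 0:
        raise ValueError(
            "no features selected as empirical controls; lower the cut-off — "
            "datasets where a large share of probes is truly associated "
            "(e.g. ~40% in cancer studies) leave few admissible controls"
        )
    logger.info(
        "selected %d/%d features as empirical controls (%.1f%%)",
        len(selected), m, 100.0 * len(selected) / m,
    )
    return ControlSet(tuple(selected), origin=ControlOrigin.empirical)


def stage2_fit(
    Y_cpg: MethylationMatrix,
    design: DesignSpec,
    ecps: ControlSet,
    B: int = 50,
    seed: int = 0,
    ridge_lambda: float | None = None,
) -> RuvFit:
    """Stage 2: RUV-inverse with the covariance estimated from the empirical
    control columns of the CpG matrix itself.  ECPs stay in the tested
    universe and receive statistics like every other feature."""
    if len(ecps) < 2:
        raise ValueError("need at least 2 empirical control probes")
    ctx = control_covariance(Y_cpg, design, ecps, ridge_lambda=ridge_lambda)
    return ruv_inverse_fit(Y_cpg, design, ctx, B=B, seed=seed)


def ruvm(
    Y_cpg: MethylationMatrix,
    Y_inc: MethylationMatrix | None,
    design: DesignSpec,
    rule: EcpRule = EcpRule(),
    iterations: int = 1,
    B: int = 50,
    seed: int = 0,
    ridge_lambda: float | None = None,
    initial_controls: ControlSet | None = None,
) -> RuvmResult:
    """Run the full two-stage procedure.

    Per-stage seeds are derived deterministically from the master seed as
    ``seed + stage_index`` (stage 1 = index 1, stage-2 round k = index 1+k).
    When no platform negative-control matrix is available, a user-supplied
    ``initial_controls`` set (CpG features, e.g. from a previous experiment)
    replaces Stage 1's INC-based covariance.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if Y_inc is not None:
        stage1 = stage1_fit(
            Y_cpg, Y_inc, design, B=B, seed=seed + 1, ridge_lambda=ridge_lambda
        )
    elif initial_controls is not None:
        ctx = control_covariance(Y_cpg, design, initial_controls, ridge_lambda=ridge_lambda)
        stage1 = ruv_inverse_fit(Y_cpg, design, ctx, B=B, seed=seed + 1)
    else:
        raise ValueError("provide either a negative-control matrix or an initial control set")

    current = stage1
    ecp_sets: list[ControlSet] = []
    fits: list[RuvFit] = []
    for k in range(1, iterations + 1):
        ecps = select_ecps(current, rule)
        current = stage2_fit(
            Y_cpg, design, ecps, B=B, seed=seed + 1 + k, ridge_lambda=ridge_lambda
        )
        ecp_sets.append(ecps)
        fits.append(current)
    return RuvmResult(
        stage1=stage1,
        ecps=tuple(ecp_sets),
        stage2=current,
        n_stage2_iterations=iterations,
        intermediate_fits=tuple(fits[:-1]),
    )


def baseline_fit(Y: MethylationMatrix, design: DesignSpec) -> RuvFit:
    """Unadjusted moderated-t comparator: per-feature ordinary least squares
    on [Z X] followed by empirical-Bayes variance moderation.  This is the
    standard regression analysis with no unwanted-variation correction."""
    if design.p != 1:
        raise ValueError("baseline comparator supports a single column of interest")
    M = design.full_matrix
    pinv = np.linalg.pinv(M)
    theta = pinv @ Y.values
    resid = Y.values - M @ theta
    df = design.residual_df
    s2 = (resid**2).sum(axis=0) / df
    c_beta = float((pinv @ pinv.T)[-1, -1])
    beta = theta[-1]
    se = np.sqrt(s2 * c_beta)
    mod = moderate_variances(se, df, beta)
    fdr = bh_adjust(mod.p_value)
    rank = rank_features(mod.p_value, mod.t_stat, Y.feature_ids)
    return RuvFit(
        feature_ids=Y.feature_ids,
        beta=beta,
        se=mod.se,
        t_stat=mod.t_stat,
        p_value=mod.p_value,
        fdr=fdr,
        rank=rank,
        df=float(mod.df),
        n_replicates_B=0,
        seed=0,
    )
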