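"""M-value computation and quality filtering for 450k-style array data.

Filtering follows standard array practice: samples with a mean detection
p-value above 0.01 are dropped first, then probes failing any of four rules
are removed — detection p-value above threshold in at least one retained
sample, located on a sex chromosome, a SNP at the CpG or single-base
extension site, or known cross-reactivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MethylationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityPair",
    "ProbeAnnotation",
    "DetectionPMatrix",
    "SampleFilterReport",
    "ProbeFilterReport",
    "m_from_intensities",
    "beta_to_m",
    "m_to_beta",
    "filter_samples",
    "filter_probes",
]

_SEX_CHROMS = {"x", "chrx", "y", "chry"}


@dataclass(frozen=True)
class IntensityPair:
    """Methylated/unmethylated channel intensities, samples x features."""

    methylated: np.ndarray
    unmethylated: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self):
        meth = np.asarray(self.methylated, dtype=float)
        unmeth = np.asarray(self.unmethylated, dtype=float)
        object.__setattr__(self, "methylated", meth)
        object.__setattr__(self, "unmethylated", unmeth)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if meth.shape != unmeth.shape:
            raise ValueError("channel shapes differ")
        if meth.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("shape does not match id lists")
        for name, arr in (("methylated", meth), ("unmethylated", unmeth)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative intensities")


@dataclass(frozen=True)
class ProbeAnnotation:
    """Per-probe annotation used by the filtering rules."""

    table: pd.DataFrame  # index: feature_id; columns: chromosome,
    # is_negative_control, has_snp_at_cpg_or_sbe, is_cross_reactive

    REQUIRED = ("chromosome", "is_negative_control", "has_snp_at_cpg_or_sbe", "is_cross_reactive")

    def __post_init__(self):
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        if t.index.has_duplicates:
            raise ValueError("duplicate feature ids in annotation")
        if (t["chromosome"].astype(str).str.len() == 0).any():
            raise ValueError("empty chromosome entries in annotation")


@dataclass(frozen=True)
class DetectionPMatrix:
    """Detection p-values, samples x features, entries in [0, 1]."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_ids: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        if v.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("shape does not match id lists")
        if np.any((v < 0) | (v > 1)) or not np.all(np.isfinite(v)):
            raise ValueError("detection p-values must lie in [0, 1]")

    def select_samples(self, ids) -> "DetectionPMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[i] for i in ids]
        return DetectionPMatrix(self.values[rows, :], tuple(ids), self.feature_ids)


@dataclass(frozen=True)
class SampleFilterReport:
    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    mean_detection_p: dict[str, float]


@dataclass(frozen=True)
class ProbeFilterReport:
    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    rule_counts: dict[str, int] = field(default_factory=dict)


def m_from_intensities(pair: IntensityPair, offset: float = 0.0) -> MethylationMatrix:
    """M = log2((methylated + offset) / (unmethylated + offset))."""
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    if offset == 0 and (np.any(pair.methylated == 0) or np.any(pair.unmethylated == 0)):
        raise ValueError("zero intensities require a positive offset")
    M = np.log2((pair.methylated + offset) / (pair.unmethylated + offset))
    return MethylationMatrix(M, pair.sample_ids, pair.feature_ids)


def beta_to_m(beta):
    """logit2 transform: M = log2(beta / (1 - beta)) for beta in (0, 1)."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)):
        raise ValueError("beta values must lie strictly in (0, 1); clip upstream")
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m):
    """Inverse logit2: beta = 2^M / (2^M + 1)."""
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


def filter_samples(detp: DetectionPMatrix, threshold: float = 0.01) -> SampleFilterReport:
    """Drop samples whose mean detection p-value across probes exceeds threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    means = detp.values.mean(axis=1)
    keep = means <= threshold
    if not keep.any():
        raise ValueError("all samples would be dropped; check the detection p-values")
    retained = tuple(s for s, k in zip(detp.sample_ids, keep) if k)
    dropped = tuple(s for s, k in zip(detp.sample_ids, keep) if not k)
    if dropped:
        logger.info("dropping %d poor-quality samples: %s", len(dropped), dropped)
    return SampleFilterReport(
        retained=retained,
        dropped=dropped,
        mean_detection_p={s: float(mu) for s, mu in zip(detp.sample_ids, means)},
    )


def filter_probes(
    detp: DetectionPMatrix | None,
    ann: ProbeAnnotation,
    feature_ids=None,
    threshold: float = 0.01,
) -> ProbeFilterReport:
    """Apply the four probe-removal rules and report per-rule counts.

    ``detp`` should already be restricted to retained samples.  Negative-
    control probes have no genomic locus and bypass the annotation rules;
    they still respect the detection rule when detection values cover them.
    A probe failing several rules is removed once but counted in each rule's
    tally.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    if feature_ids is None:
        feature_ids = tuple(detp.feature_ids) if detp is not None else tuple(ann.table.index)
    feature_ids = tuple(feature_ids)

    t = ann.table
    missing = [f for f in feature_ids if f not in t.index]
    if missing:
        raise KeyError(f"annotation missing for probes: {missing[:5]}")
    sub = t.loc[list(feature_ids)]
    is_nc = sub["is_negative_control"].astype(bool).to_numpy()

    fail_detp = np.zeros(len(feature_ids), dtype=bool)
    if detp is not None:
        det_index = {f: j for j, f in enumerate(detp.feature_ids)}
        for i, f in enumerate(feature_ids):
            j = det_index.get(f)
            if j is not None:
                fail_detp[i] = bool(np.any(detp.values[:, j] > threshold))

    chrom = sub["chromosome"].astype(str).str.strip().str.lower().to_numpy()
    fail_sex = np.isin(chrom, list(_SEX_CHROMS)) & ~is_nc
    fail_snp = sub["has_snp_at_cpg_or_sbe"].astype(bool).to_numpy() & ~is_nc
    fail_xr = sub["is_cross_reactive"].astype(bool).to_numpy() & ~is_nc

    fail_any = fail_detp | fail_sex | fail_snp | fail_xr
    retained = tuple(f for f, bad in zip(feature_ids, fail_any) if not bad)
    dropped = tuple(f for f, bad in zip(feature_ids, fail_any) if bad)
    counts = {
        "detection_p": int(fail_detp.sum()),
        "sex_chromosome": int(fail_sex.sum()),
        "snp_at_cpg_or_sbe": int(fail_snp.sum()),
        "cross_reactive": int(fail_xr.sum()),
        "total_removed": int(fail_any.sum()),
    }
    logger.info("probe filtering removed %d/%d probes: %s", counts["total_removed"],
                len(feature_ids), counts)
    return ProbeFilterReport(retained=retained, dropped=dropped, rule_counts=counts)
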