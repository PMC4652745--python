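"""Tab-delimited file formats and run configuration.

All matrices are stored features x samples (the methylation-array file
convention): first column ``feature_id``, header row of sample ids, numeric
body.  Readers transpose into the internal samples x features layout.  TSV
is used throughout to avoid locale decimal-separator issues; missing values
are rejected — the pipeline requires complete matrices.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ControlSet, MethylationMatrix, RuvFit
from .pipeline import EcpRule, RuvmResult
from .preprocess import DetectionPMatrix, IntensityPair, ProbeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "read_matrix",
    "read_detection_matrix",
    "read_intensity_pair",
    "read_annotation",
    "read_pheno",
    "write_matrix",
    "write_fit",
    "write_ruvm_result",
    "RunConfig",
]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate sample ids in header")
    return df


def _read_numeric(path) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
    df = _read_table(path)
    try:
        values = df.astype(float).to_numpy(dtype=float)
    except (ValueError, TypeError):
        for i, (_, row) in enumerate(df.iterrows(), start=2):  # +1 header, 1-based
            try:
                row.astype(float)
            except (ValueError, TypeError):
                raise ValueError(f"{path}: non-numeric cell on line {i}") from None
        raise
    if np.isnan(values).any():
        rows = np.where(np.isnan(values).any(axis=1))[0]
        raise ValueError(f"{path}: missing values (e.g. line {rows[0] + 2}); "
                         "complete matrices are required")
    feature_ids = tuple(str(i) for i in df.index)
    sample_ids = tuple(str(c) for c in df.columns)
    return values.T, sample_ids, feature_ids  # transpose to samples x features


def read_matrix(path) -> MethylationMatrix:
    """Read an M-value matrix (features x samples TSV)."""
    values, sample_ids, feature_ids = _read_numeric(path)
    return MethylationMatrix(values, sample_ids, feature_ids)


def read_detection_matrix(path) -> DetectionPMatrix:
    values, sample_ids, feature_ids = _read_numeric(path)
    return DetectionPMatrix(values, sample_ids, feature_ids)


def read_intensity_pair(meth_path, unmeth_path) -> IntensityPair:
    meth, s1, f1 = _read_numeric(meth_path)
    unmeth, s2, f2 = _read_numeric(unmeth_path)
    if s1 != s2 or f1 != f2:
        raise ValueError("methylated and unmethylated matrices have different ids")
    return IntensityPair(meth, unmeth, s1, f1)


def read_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for col in ("is_negative_control", "has_snp_at_cpg_or_sbe", "is_cross_reactive"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return ProbeAnnotation(df)


def read_pheno(path, group_col: str = "group") -> pd.DataFrame:
    """Sample sheet: first column sample_id, remaining columns phenotypes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if group_col not in df.columns:
        raise ValueError(f"{path}: no column named {group_col!r}")
    return df


def write_matrix(mat: MethylationMatrix, path) -> None:
    """Write features x samples TSV (transpose of the internal layout)."""
    df = pd.DataFrame(
        mat.values.T, index=list(mat.feature_ids), columns=list(mat.sample_ids)
    )
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_fit(fit: RuvFit, path) -> None:
    fit.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_ruvm_result(
    result: RuvmResult,
    out_dir,
    rule: EcpRule | None = None,
    seed: int | None = None,
    input_paths: dict | None = None,
) -> None:
    """Write per-stage tables, the ECP id list and a run_info provenance file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fit(result.stage1, out / "stage1.tsv")
    write_fit(result.stage2, out / "stage2.tsv")
    with open(out / "ecps.txt", "w") as fh:
        for f in result.ecps[-1].feature_ids:
            fh.write(f + "\n")
    from importlib.metadata import version

    try:
        ver = version("ruvmeth")
    except Exception:  # pragma: no cover
        ver = "unknown"
    lines = [
        f"ruvmeth_version\t{ver}",
        f"seed\t{seed}",
        f"replicates_B\t{result.stage2.n_replicates_B}",
        f"iterations\t{result.n_stage2_iterations}",
    ]
    if rule is not None:
        lines += [f"ecp_method\t{rule.method.value}", f"ecp_threshold\t{rule.threshold}"]
    for name, p in (input_paths or {}).items():
        lines.append(f"input_{name}\t{p}\t{_sha256(p)}")
    (out / "run_info.txt").write_text("\n".join(lines) + "\n")


@dataclass
class RunConfig:
    """Flat key-value run configuration; CLI flags override file values."""

    matrix: str | None = None
    inc_matrix: str | None = None
    pheno: str | None = None
    group_col: str = "group"
    ecp_method: str = "bottom_fraction"
    ecp_threshold: float = 0.5
    iterations: int = 1
    replicates_B: int = 50
    seed: int = 0
    offset: float = 0.0
    detp_threshold: float = 0.01
    out_dir: str = "ruvmeth_out"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat key-value document")
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs)
        cfg.extra = extra
        return cfg
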