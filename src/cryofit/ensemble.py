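"""Ensemble-level statistics over model sets.

The statistical layer relating a prediction ensemble to the map and
the reference model: accuracy filtering (the "high-accuracy" cutoff of
70 on GDT_TS and LDDT), per-residue mean/SD of local-fit profiles
across models, correlation of those statistics with the reference
profile, the paired improvement t-test for before/after refinement
scores, and the all-against-all score correlation matrix.

The central empirical signature this layer detects: per-residue SD of
the local fit across an ensemble is *anticorrelated* with the
reference local fit — poorly resolved regions both fit worse and vary
more across predictions — while the ensemble mean tracks the reference
profile positively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AtomicModel
from .local_scores import ResidueProfile
from .restraints import stereo_report  # re-exported: geometry quality report

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracyRecord",
    "EnsembleSummary",
    "filter_models",
    "ensemble_profiles",
    "profile_correlations",
    "paired_improvement_test",
    "score_correlation_matrix",
    "stereo_report",
]

HIGH_ACCURACY_THRESHOLD = 70.0


@dataclass(frozen=True)
class AccuracyRecord:
    """Externally supplied model accuracy (never computed here)."""

    model_id: str
    gdt_ts: float
    lddt: float
    is_multimer: bool = False

    def __post_init__(self) -> None:
        for name in ("gdt_ts", "lddt"):
            v = getattr(self, name)
            if not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100], got {v}")


def filter_models(
    records: list[AccuracyRecord],
    threshold: float = HIGH_ACCURACY_THRESHOLD,
) -> list[str]:
    """Model ids passing the high-accuracy cutoff.

    Monomers require both GDT_TS and LDDT strictly above the
    threshold; multimers require only LDDT strictly above it (a
    multimer subunit may score low on the rigid-body GDT_TS while its
    local geometry is accurate).
    """
    out = []
    for r in records:
        if r.is_multimer:
            ok = r.lddt > threshold
        else:
            ok = r.gdt_ts > threshold and r.lddt > threshold
        if ok:
            out.append(r.model_id)
    return out


@dataclass
class EnsembleSummary:
    """Per-residue mean and SD of a score across aligned profiles."""

    table: pd.DataFrame  # index (chain, resnum); columns mean, sd, n, incomplete
    n_models: int

    @property
    def mean(self) -> pd.Series:
        return self.table["mean"]

    @property
    def sd(self) -> pd.Series:
        return self.table["sd"]


def ensemble_profiles(profiles: list[ResidueProfile]) -> EnsembleSummary:
    """Per-residue sample mean and SD (n-1 denominator) across models.

    Residues missing from some models are computed over the models
    that contain them and flagged ``incomplete``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    frames = [p.keyed() for p in profiles]
    wide = pd.concat(frames, axis=1, keys=range(len(frames)))
    if wide.dropna(how="all").empty:
        raise ValueError("profiles share no residues")
    n = wide.notna().sum(axis=1)
    mean = wide.mean(axis=1)
    sd = wide.std(axis=1, ddof=1).fillna(0.0)  # n=1 residues -> SD 0
    table = pd.DataFrame(
        {"mean": mean, "sd": sd, "n": n, "incomplete": n < len(profiles)}
    )
    return EnsembleSummary(table=table, n_models=len(profiles))


def profile_correlations(
    summary: EnsembleSummary, reference: ResidueProfile
) -> dict[str, float | int | bool]:
    """Pearson correlations of ensemble SD and mean with the reference.

    Returns ``r_sd_ref``, ``r_mean_ref`` and the shared-residue count.
    Zero variance in any vector flags the correlation undefined (NaN).
    """
    ref = reference.keyed()
    shared = summary.table.index.intersection(ref.index)
    shared = shared[
        summary.table.loc[shared, ["mean", "sd"]].notna().all(axis=1)
        & ref.loc[shared].notna()
    ]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared residues")
    ref_v = ref.loc[shared].to_numpy()
    sd_v = summary.sd.loc[shared].to_numpy()
    mean_v = summary.mean.loc[shared].to_numpy()
    out: dict[str, float | int | bool] = {"n_residues": int(len(shared))}
    for name, v in (("r_sd_ref", sd_v), ("r_mean_ref", mean_v)):
        if np.std(v) == 0 or np.std(ref_v) == 0:
            logger.warning("zero variance; %s undefined", name)
            out[name] = float("nan")
            out["undefined"] = True
        else:
            out[name] = float(stats.pearsonr(v, ref_v).statistic)
    out.setdefault("undefined", False)
    return out


def paired_improvement_test(
    before: np.ndarray | list[float], after: np.ndarray | list[float]
) -> tuple[float, float]:
    """One-sided paired t-test that scores improved (after > before).

    t = mean(d) / (sd(d)/sqrt(n)) with d = after - before, p from the
    t distribution with n-1 degrees of freedom (upper tail).
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before/after must be paired (equal length)")
    n = before.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = after - before
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, 0.5
        logger.warning("zero-variance nonzero differences; p below machine floor")
        return math.copysign(math.inf, d.mean()), 0.0
    t = d.mean() / (sd / math.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), p


def score_correlation_matrix(
    table: pd.DataFrame,
    method: str = "pearson",
    min_models_per_target: int = 10,
    target_column: str | None = None,
) -> pd.DataFrame:
    """All-against-all correlation matrix over score columns.

    Rows are models, columns scores. When ``target_column`` names a
    grouping column, targets with ``min_models_per_target`` models or
    fewer are excluded before aggregating. Missing scores are handled
    by pairwise deletion; constant columns give NaN entries.
    """
    if target_column is not None:
        counts = table[target_column].value_counts()
        keep = counts[counts > min_models_per_target].index
        table = table[table[target_column].isin(keep)].drop(columns=[target_column])
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise ValueError("need at least 3 models")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    corr = numeric.corr(method=method, min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr
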