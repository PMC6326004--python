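"""Quality-control cascade: retention-time trimming, blank subtraction,
internal-standard normalisation, pooled-QC RSD filtering and imputation.

Stage order in the full pipeline is trim -> blank -> annotate/collapse ->
normalise -> QC-RSD -> impute; every stage writes to a :class:`FilterLedger`
that conserves feature counts (n_in = n_removed + n_out).

Conventions: boundary cases survive — the blank rule removes a feature
only when the blank maximum strictly exceeds ``factor`` times the highest
biological intensity, and the RSD rule only above (not at) the threshold.
RSD uses the sample standard deviation (n-1).  Missing intensities are
absent cells, treated as 0 only where a maximum is being taken.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import default_adduct
from .io import sample_columns
from .simulate import MORIN_MASS

RT_KEEP_MIN = 2.0
RT_KEEP_MAX = 29.0
BLANK_FACTOR = 2.0
RSD_MAX_PCT = 20.0
IS_MZ_TOL = 0.01
IS_RT_TOL_MIN = 0.5


@dataclass
class FilterLedger:
    """Ordered accounting of every filtering stage."""

    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, n_in: int, removed_ids: list[str]) -> None:
        n_removed = len(removed_ids)
        stage = {
            "stage": name,
            "n_in": n_in,
            "n_removed": n_removed,
            "n_out": n_in - n_removed,
            "removed_feature_ids": list(removed_ids),
        }
        if stage["n_out"] < 0:
            raise ValueError(f"ledger stage {name}: removed more than entered")
        self.stages.append(stage)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{k: s[k] for k in ("stage", "n_in", "n_removed", "n_out")} for s in self.stages]
        )

    def check_conservation(self) -> bool:
        """n_in = n_removed + n_out everywhere; counts flow stage to stage.

        Continuity is checked within each processing chain, identified by
        the bracketed suffix of the stage name (e.g. ``[pos]``); unmarked
        stages (post-merge) form their own chain.
        """
        ok = all(s["n_in"] == s["n_removed"] + s["n_out"] for s in self.stages)
        chains: dict[str, list[dict]] = {}
        for s in self.stages:
            name = s["stage"]
            suffix = name[name.index("[") :] if "[" in name else ""
            chains.setdefault(suffix, []).append(s)
        for chain in chains.values():
            for prev, nxt in zip(chain, chain[1:]):
                ok = ok and nxt["n_in"] == prev["n_out"]
        return ok

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.stages:
                fh.write(json.dumps(s) + "\n")


# ---------------------------------------------------------------------------
# functional stages on feature-per-row peak tables
# ---------------------------------------------------------------------------


def trim_rt(
    peaks: pd.DataFrame, rt_min: float = RT_KEEP_MIN, rt_max: float = RT_KEEP_MAX
) -> tuple[pd.DataFrame, list[str]]:
    """Drop features eluting outside the closed window [rt_min, rt_max] minutes."""
    keep = (peaks["rt_min"] >= rt_min) & (peaks["rt_min"] <= rt_max)
    removed = list(peaks.loc[~keep, "feature_id"])
    return peaks.loc[keep].reset_index(drop=True), removed


def blank_filter(
    peaks: pd.DataFrame,
    blank_ids: list[str],
    biological_ids: list[str],
    factor: float = BLANK_FACTOR,
) -> tuple[pd.DataFrame, list[str]]:
    """Remove blank-dominant features.

    A feature goes when its highest blank intensity strictly exceeds
    ``factor`` times its highest biological intensity (missing = 0 for the
    maxima).  With no blank injections the stage is skipped with a warning.
    """
    if not blank_ids:
        warnings.warn("no blank samples; blank filter skipped", stacklevel=2)
        return peaks.reset_index(drop=True), []
    blank_max = peaks[blank_ids].fillna(0.0).max(axis=1)
    bio_max = peaks[biological_ids].fillna(0.0).max(axis=1)
    remove = blank_max > factor * bio_max
    removed = list(peaks.loc[remove, "feature_id"])
    return peaks.loc[~remove].reset_index(drop=True), removed


def locate_internal_standard(
    peaks: pd.DataFrame,
    polarity: str,
    is_mz: float | None = None,
    is_rt: float | None = None,
    mz_tol: float = IS_MZ_TOL,
    rt_tol: float = IS_RT_TOL_MIN,
) -> str:
    """Find the morin internal-standard feature by m/z (and optionally RT).

    Default target m/z is the [M+H]+ / [M-H]- ion of morin for the given
    polarity (303.0499 / 301.0354).
    """
    target = is_mz if is_mz is not None else default_adduct(polarity).mz(MORIN_MASS)
    cand = peaks[(peaks["mz"] - target).abs() <= mz_tol]
    if is_rt is not None:
        cand = cand[(cand["rt_min"] - is_rt).abs() <= rt_tol]
    if len(cand) == 0:
        raise ValueError(f"internal standard not found at m/z {target:.4f} ({polarity})")
    # closest mass wins if several candidates fall in the window
    return cand.iloc[(cand["mz"] - target).abs().argmin()]["feature_id"]


def normalize_to_internal_standard(
    peaks: pd.DataFrame,
    nonblank_ids: list[str],
    polarity: str,
    is_mz: float | None = None,
    is_rt: float | None = None,
) -> tuple[pd.DataFrame, str]:
    """Divide every intensity by the sample's internal-standard intensity.

    Returns the peak-response-ratio table (the IS row removed) and the IS
    feature id.  Errors when the IS is missing or zero in any non-blank
    sample of the polarity.
    """
    is_fid = locate_internal_standard(peaks, polarity, is_mz, is_rt)
    is_row = peaks.loc[peaks["feature_id"] == is_fid, nonblank_ids].iloc[0]
    missing = [s for s in nonblank_ids if pd.isna(is_row[s])]
    if missing:
        raise ValueError(f"internal standard missing in samples: {missing}")
    zero = [s for s in nonblank_ids if is_row[s] == 0]
    if zero:
        raise ValueError(f"internal standard intensity is zero in samples: {zero}")
    ratios = peaks.loc[peaks["feature_id"] != is_fid].reset_index(drop=True).copy()
    ratios[nonblank_ids] = ratios[nonblank_ids].div(is_row[nonblank_ids], axis=1)
    return ratios, is_fid


def qa_rsd(peaks: pd.DataFrame, qa_ids: list[str]) -> pd.Series:
    """Percent relative standard deviation over QC injections per feature.

    Missing QC values are excluded; fewer than 3 observed values or a zero
    mean yields NaN (the filter treats NaN as a failure).
    """
    qa = peaks[qa_ids].to_numpy(float)
    n_obs = (~np.isnan(qa)).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(qa, axis=1)
        sd = np.nanstd(qa, axis=1, ddof=1)
    rsd = np.where((n_obs >= 3) & (mean != 0), 100.0 * sd / mean, np.nan)
    return pd.Series(rsd, index=peaks["feature_id"], name="qa_rsd_pct")


def qa_rsd_filter(
    peaks: pd.DataFrame, qa_ids: list[str], rsd_max: float = RSD_MAX_PCT
) -> tuple[pd.DataFrame, list[str], pd.Series]:
    """Remove features whose QC RSD strictly exceeds ``rsd_max`` percent."""
    if len(qa_ids) < 3:
        raise ValueError("QC-RSD filtering requires at least 3 pooled-QC samples")
    rsd = qa_rsd(peaks, qa_ids)
    fail = rsd.isna() | (rsd > rsd_max)
    removed = list(rsd.index[fail])
    kept = peaks[~peaks["feature_id"].isin(removed)].reset_index(drop=True)
    return kept, removed, rsd


def impute_missing(
    peaks: pd.DataFrame, sample_ids: list[str] | None = None
) -> tuple[pd.DataFrame, float]:
    """Replace missing ratios with one third of the global minimum observed ratio."""
    out = peaks.copy()
    cols = sample_ids if sample_ids is not None else sample_columns(peaks)
    values = out[cols].to_numpy(float)
    if np.all(np.isnan(values)):
        raise ValueError("cannot impute an all-missing matrix")
    fill = float(np.nanmin(values)) / 3.0
    out[cols] = out[cols].fillna(fill)
    return out, fill


# ---------------------------------------------------------------------------
# sklearn-style transformers on samples x features matrices
# ---------------------------------------------------------------------------


class InternalStandardNormalizer(BaseEstimator, TransformerMixin):
    """Divide each sample row by its internal-standard column; drop that column."""

    def __init__(self, is_feature: str):
        self.is_feature = is_feature

    def fit(self, X: pd.DataFrame, y=None):
        if self.is_feature not in X.columns:
            raise ValueError(f"internal-standard column {self.is_feature!r} absent")
        self.feature_names_in_ = np.asarray(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        is_col = X[self.is_feature]
        if is_col.isna().any():
            raise ValueError(f"internal standard missing in {list(X.index[is_col.isna()])}")
        if (is_col == 0).any():
            raise ValueError(f"internal standard zero in {list(X.index[is_col == 0])}")
        return X.drop(columns=[self.is_feature]).div(is_col, axis=0)


class QARSDFilter(BaseEstimator, TransformerMixin):
    """Drop feature columns whose RSD across pooled-QC rows exceeds the cap."""

    def __init__(self, qa_sample_ids: list[str], rsd_max: float = RSD_MAX_PCT):
        self.qa_sample_ids = qa_sample_ids
        self.rsd_max = rsd_max

    def fit(self, X: pd.DataFrame, y=None):
        if len(self.qa_sample_ids) < 3:
            raise ValueError("QC-RSD filtering requires at least 3 pooled-QC samples")
        qa = X.loc[self.qa_sample_ids]
        n_obs = qa.notna().sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = qa.mean(axis=0)
            sd = qa.std(axis=0, ddof=1)
        rsd = 100.0 * sd / mean
        rsd[(n_obs < 3) | (mean == 0)] = np.nan
        self.rsd_ = rsd
        self.support_ = rsd.notna() & (rsd <= self.rsd_max)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.support_.index[self.support_]]


class OneThirdMinimumImputer(BaseEstimator, TransformerMixin):
    """Fill missing ratios with (global minimum observed ratio) / 3."""

    def fit(self, X: pd.DataFrame, y=None):
        values = np.asarray(X, float)
        if np.all(np.isnan(values)):
            raise ValueError("cannot impute an all-missing matrix")
        self.fill_value_ = float(np.nanmin(values)) / 3.0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.fillna(self.fill_value_)
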