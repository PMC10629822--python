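"""Differential splicing between genotype groups.

The statistic follows a fixed pipeline on the events × samples PSI matrix:

1. ``ln(psi + x)`` transform (pseudocount ``x`` > 0, default 0.01);
2. drop events with no variability across samples (or all missing);
3. mean-impute remaining missing cells (event-wise mean over all samples);
4. standardize each event row to mean 0, population SD 1;
5. two-sided two-sample t-test per event (pooled variance by default,
   Welch optional), with optional Benjamini-Hochberg adjustment.

ΔPSI is always reported on the raw PSI scale, as mean(MUT) − mean(WT) over
the *observed* (non-imputed) values. Significance requires both
``|ΔPSI| > delta_psi_min`` and ``p < p_max``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ConfigurationError, IntegrityError

logger = logging.getLogger("crypticsplice")


@dataclass(frozen=True)
class DiffSpliceConfig:
    """Thresholds and options for the differential test.

    The default pair ``(delta_psi_min=0.1, p_max=0.01)`` is the mouse-cohort
    screen; :meth:`pan_cancer` switches to ``(0.05, 1e-10)``, the stricter
    pair used for large human cohorts.
    """

    pseudocount: float = 0.01
    min_coverage: int = 10
    delta_psi_min: float = 0.1
    p_max: float = 0.01
    test: str = "pooled"
    adjust: str = "none"

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ConfigurationError("pseudocount must be > 0")
        if not 0 < self.delta_psi_min < 1:
            raise ConfigurationError("delta_psi_min must be in (0, 1)")
        if not 0 < self.p_max < 1:
            raise ConfigurationError("p_max must be in (0, 1)")
        if self.test not in ("pooled", "welch"):
            raise ConfigurationError(f"test must be 'pooled' or 'welch': {self.test!r}")
        if self.adjust not in ("none", "BH"):
            raise ConfigurationError(f"adjust must be 'none' or 'BH': {self.adjust!r}")

    @classmethod
    def mouse_kpc(cls, **overrides) -> "DiffSpliceConfig":
        return cls(**{"delta_psi_min": 0.1, "p_max": 0.01, **overrides})

    @classmethod
    def pan_cancer(cls, **overrides) -> "DiffSpliceConfig":
        return cls(**{"delta_psi_min": 0.05, "p_max": 1e-10, **overrides})

    def with_overrides(self, **overrides) -> "DiffSpliceConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})


def transform_psi(matrix: pd.DataFrame, x: float = 0.01) -> pd.DataFrame:
    """``value -> ln(value + x)``; missing stays missing."""
    if x <= 0:
        raise ConfigurationError("pseudocount x must be > 0")
    vals = matrix.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise IntegrityError("PSI values outside [0, 1]")
    return np.log(matrix + x)


def filter_and_impute(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop no-variability (or all-missing) events; mean-impute the rest.

    Variability is judged on the observed values of each event; imputation
    uses the event-wise mean across all samples.
    """
    observed_var = matrix.var(axis=1, ddof=0, skipna=True)
    n_obs = matrix.notna().sum(axis=1)
    keep = (n_obs > 0) & (observed_var > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("removed %d events with no variability or no observations", dropped)
    kept = matrix.loc[keep]
    row_means = kept.mean(axis=1, skipna=True)
    return kept.apply(lambda col: col.fillna(row_means))


def standardize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each event row to mean 0 and population (ddof=0) SD 1."""
    if matrix.isna().any().any():
        raise IntegrityError("standardize requires a complete (imputed) matrix")
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0)
    if (sd == 0).any():
        bad = matrix.index[sd == 0].tolist()
        raise IntegrityError(f"zero-variance rows reached standardization: {bad}")
    return matrix.sub(mu, axis=0).div(sd, axis=0)


def _group_columns(
    matrix: pd.DataFrame, groups: Mapping[str, str]
) -> tuple[list[str], list[str]]:
    wt = [c for c in matrix.columns if groups.get(c) == "WT"]
    mut = [c for c in matrix.columns if groups.get(c) == "MUT"]
    if len(wt) < 2 or len(mut) < 2:
        raise ConfigurationError(
            f"differential testing needs >= 2 samples per group (WT={len(wt)}, MUT={len(mut)})"
        )
    return wt, mut


def differential_test(
    psi: pd.DataFrame,
    groups: Mapping[str, str],
    config: DiffSpliceConfig = DiffSpliceConfig(),
) -> pd.DataFrame:
    """Run the full transform → filter → impute → standardize → test chain.

    ``psi`` is the raw events × samples PSI matrix (NaN = missing);
    ``groups`` maps sample_id to 'WT' or 'MUT'. Returns one row per tested
    event with n_wt, n_mut (observed values per group), delta_psi, t, p,
    p_adj and the significance call. Events where either group has fewer
    than two observed values keep a missing p (logged) and are never
    significant.
    """
    wt_cols, mut_cols = _group_columns(psi, groups)

    transformed = transform_psi(psi, config.pseudocount)
    complete = filter_and_impute(transformed)
    standardized = standardize(complete)

    raw = psi.loc[complete.index]
    n_wt = raw[wt_cols].notna().sum(axis=1)
    n_mut = raw[mut_cols].notna().sum(axis=1)
    delta = raw[mut_cols].mean(axis=1, skipna=True) - raw[wt_cols].mean(axis=1, skipna=True)

    a = standardized[mut_cols].to_numpy(dtype=float)
    b = standardized[wt_cols].to_numpy(dtype=float)
    if len(standardized):
        t_stat, p_val = stats.ttest_ind(
            a, b, axis=1, equal_var=(config.test == "pooled")
        )
    else:
        t_stat = np.array([])
        p_val = np.array([])

    results = pd.DataFrame(
        {
            "n_wt": n_wt,
            "n_mut": n_mut,
            "delta_psi": delta,
            "t": t_stat,
            "p": p_val,
        },
        index=complete.index,
    )
    underpowered = (results["n_wt"] < 2) | (results["n_mut"] < 2)
    if underpowered.any():
        logger.info(
            "%d events have < 2 observed values in a group; p set missing",
            int(underpowered.sum()),
        )
        results.loc[underpowered, ["t", "p"]] = np.nan

    tested = results["p"].notna()
    results["p_adj"] = np.nan
    if tested.any():
        results.loc[tested, "p_adj"] = multipletests(
            results.loc[tested, "p"], method="fdr_bh"
        )[1]
    return apply_thresholds(results, config)


def apply_thresholds(results: pd.DataFrame, config: DiffSpliceConfig) -> pd.DataFrame:
    """Set the ``significant`` flag: |ΔPSI| above the bound and p (adjusted
    p when ``adjust='BH'``) below the cap."""
    p_col = "p_adj" if config.adjust == "BH" else "p"
    results = results.copy()
    results["significant"] = (
        (results["delta_psi"].abs() > config.delta_psi_min)
        & (results[p_col] < config.p_max)
        & results[p_col].notna()
    )
    return results


def significant_events(results: pd.DataFrame) -> list[str]:
    """Event identifiers flagged significant, in deterministic order."""
    return sorted(results.index[results["significant"]])
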