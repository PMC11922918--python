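"""Agreement statistics between two VI measurement pipelines.

Two sets of ROI-derived vegetation indices on the same images (e.g. an
automatic ROI vs an independently annotated reference ROI) are compared with

* per-sample unsigned percent error  |A − B| / |A| × 100  (A = reference),
  and its arithmetic mean over samples;
* simple OLS of candidate on reference: slope, intercept, correlation r,
  R², with t-based 95% confidence bands for the mean response and 95%
  prediction bands for a new observation.

Both r and R² are reported, since correlation magnitudes and coefficients of
determination are easily conflated in agreement studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateX,
    IdMismatch,
    TooFewPoints,
    ZeroReference,
)
from .indices import DEFAULT_VI_NAMES


# --- percent error ----------------------------------------------------------

def percent_error(reference: float, candidate: float) -> float:
    """Unsigned individual percent error |A − B| / |A| × 100 (A = reference)."""
    if reference == 0:
        raise ZeroReference("percent error undefined for reference value 0")
    return abs(reference - candidate) / abs(reference) * 100.0


def mean_percent_error(pairs: Iterable[Tuple[float, float]]) -> float:
    """Arithmetic mean of the individual unsigned percent errors."""
    errors = [percent_error(a, b) for a, b in pairs]
    if not errors:
        raise ValueError("mean_percent_error needs at least one pair")
    return float(np.mean(errors))


# --- OLS with bands ---------------------------------------------------------

@dataclass
class RegressionFit:
    """Simple-regression fit with 95% confidence/prediction band evaluators."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    resid_se: float
    n: int
    _results: object = field(repr=False, compare=False, default=None)

    def predict(self, x: Sequence[float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.intercept + self.slope * x

    def _bands(self, x: Sequence[float], obs: bool, level: float) -> Tuple[np.ndarray, np.ndarray]:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        exog = sm.add_constant(x, has_constant="add")
        pred = self._results.get_prediction(exog)
        ci = pred.conf_int(obs=obs, alpha=1.0 - level)
        return ci[:, 0], ci[:, 1]

    def confidence_band(self, x: Sequence[float], level: float = 0.95) -> Tuple[np.ndarray, np.ndarray]:
        """Band for the mean response at x."""
        return self._bands(x, obs=False, level=level)

    def prediction_band(self, x: Sequence[float], level: float = 0.95) -> Tuple[np.ndarray, np.ndarray]:
        """Band for a new observation at x (always contains the confidence band)."""
        return self._bands(x, obs=True, level=level)


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Least-squares fit of ``y = intercept + slope * x``.

    R² is defined as 1 − SS_res/SS_tot; a constant y yields slope 0 and
    R² = 0 by convention (no variance to explain).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise TooFewPoints(f"OLS needs n >= 3, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateX("x is constant; slope undefined")
    results = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = (float(v) for v in results.params)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        slope, r, r2 = 0.0, 0.0, 0.0
    else:
        r2 = float(results.rsquared)
        with np.errstate(invalid="ignore"):
            r = float(np.corrcoef(x, y)[0, 1])
    resid_se = float(np.sqrt(results.mse_resid)) if n > 2 else float("nan")
    return RegressionFit(slope=slope, intercept=intercept, r=r, r_squared=r2,
                         resid_se=resid_se, n=n, _results=results)


# --- per-VI agreement report ------------------------------------------------

@dataclass(frozen=True)
class AgreementStats:
    vi: str
    n: int
    slope: float
    intercept: float
    r: float
    r_squared: float
    mean_percent_error: float


def agreement_report(
    reference: pd.DataFrame,
    candidate: pd.DataFrame,
    vi_names: Optional[Sequence[str]] = None,
    id_col: str = "image_id",
) -> Dict[str, AgreementStats]:
    """Per-VI OLS + mean percent error between two id-keyed VI tables.

    The id sequences must be identical (same ids, same order); anything else
    raises :class:`~leafvi.errors.IdMismatch` rather than silently realigning
    rows.
    """
    if id_col not in reference.columns or id_col not in candidate.columns:
        raise IdMismatch(f"both tables need an {id_col!r} column")
    ref_ids = list(reference[id_col])
    cand_ids = list(candidate[id_col])
    if ref_ids != cand_ids:
        raise IdMismatch("reference and candidate id sequences differ")
    if vi_names is None:
        vi_names = [v for v in DEFAULT_VI_NAMES
                    if v in reference.columns and v in candidate.columns]
    out: Dict[str, AgreementStats] = {}
    for name in vi_names:
        a = reference[name].to_numpy(dtype=float)
        b = candidate[name].to_numpy(dtype=float)
        fit = ols_fit(a, b)
        mpe = mean_percent_error(zip(a, b))
        out[name] = AgreementStats(
            vi=name, n=fit.n, slope=fit.slope, intercept=fit.intercept,
            r=fit.r, r_squared=fit.r_squared, mean_percent_error=mpe,
        )
    return out


def report_frame(report: Dict[str, AgreementStats]) -> pd.DataFrame:
    """Agreement report as a tidy DataFrame (one row per VI)."""
    rows = [
        {
            "vi": s.vi, "n": s.n, "slope": s.slope, "intercept": s.intercept,
            "r": s.r, "r_squared": s.r_squared,
            "mean_percent_error": s.mean_percent_error,
        }
        for s in report.values()
    ]
    return pd.DataFrame(rows)


# --- paired auto/reference ROI study on phantom scenes ----------------------

def paired_roi_table(scenes, seed: int = 0, max_offset: int = 5):
    """Auto-ROI vs jitter-reference-ROI VI tables over phantom scenes.

    For every scene the automatic pipeline places its ROI; a reference ROI of
    the same size is offset by a seeded jitter of at most ``max_offset``
    pixels per axis, constrained to remain inside the lit-leaf mask — a
    surrogate for an independent manual annotation of the same leaf area.

    Returns ``(reference_df, candidate_df)`` keyed by ``image_id``.
    """
    # imported here to keep the stats layer usable without the pipeline
    from .indices import compute_all
    from .phantom import jittered_roi
    from .segmentation import auto_roi

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6A17]))
    ref_rows: List[dict] = []
    cand_rows: List[dict] = []
    for i, scene in enumerate(scenes):
        image_id = f"scene_{i:04d}"
        roi, _ = auto_roi(scene.rgb)
        ref_roi = jittered_roi(roi, scene.masks["lit"], rng, max_offset=max_offset)
        auto_vi = compute_all(scene.cube, roi)
        ref_vi = compute_all(scene.cube, ref_roi)
        cand_rows.append({"image_id": image_id, **auto_vi.values})
        ref_rows.append({"image_id": image_id, **ref_vi.values})
    return pd.DataFrame(ref_rows), pd.DataFrame(cand_rows)
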