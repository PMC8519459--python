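"""Vertical-stratum inference from temperature matching.

Outside quiet Night rest the pressure record of a carapace-mounted tag is
erratic (knocks, vegetation), so the animal's stratum in the water column is
inferred instead by regressing tag temperature on each reference series
(air, water surface, water at 20 cm, pond bottom): the stratum whose fit is
closest to identity (intercept ~ 0, slope ~ 1, R^2 ~ 1) wins.  The informal
triple criterion is operationalised as the composite score

    score = (1 - R^2) + |slope - 1| + |intercept| / 10

(lower is better; 1 degC of intercept error trades against 0.1 of R^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .logger_io import STRATA, STRATUM_COLUMNS


class DegenerateFitError(ValueError):
    """Zero variance in the regressor: an OLS fit is undefined."""


@dataclass
class StratumFit:
    stratum: str
    intercept: float
    slope: float
    r2: float
    n: int
    score: float


def ols(x, y):
    """Ordinary least squares of y on x: (intercept, slope, r2, n).

    r2 is the squared Pearson correlation.  Raises
    :class:`DegenerateFitError` when x has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 2 or np.ptp(x) == 0:
        raise DegenerateFitError("regressor has zero variance")
    res = sstats.linregress(x, y)
    return float(res.intercept), float(res.slope), float(res.rvalue ** 2), n


def stratum_score(intercept: float, slope: float, r2: float,
                  intercept_weight: float = 0.1) -> float:
    """Composite distance from the identity fit; 0 iff exact with slope 1
    and intercept 0."""
    return (1.0 - r2) + abs(slope - 1.0) + intercept_weight * abs(intercept)


def best_stratum(t, temp, reference, min_n: int = 30,
                 tie_tol: float = 1e-6):
    """Fit tag temperature against each reference stratum over one bout.

    ``reference`` is a DataFrame with columns time, t_air, t_surface,
    t_20cm, t_bottom (10-min cadence; NaN gaps allowed).  Each series is
    linearly interpolated to the tag timestamps.  Returns
    ``(winner, fits, ambiguous)``; a stratum whose reference gaps cover more
    than half the bout is skipped with a warning.  If every stratum is
    degenerate, the degenerate-fit error is propagated.
    """
    t = np.asarray(t, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if len(t) < min_n:
        raise ValueError(f"bout has fewer than {min_n} samples")
    fits = []
    last_error = None
    for stratum in STRATA:
        col = STRATUM_COLUMNS[stratum]
        rt = reference["time"].to_numpy(dtype=float)
        rv = reference[col].to_numpy(dtype=float)
        ok = np.isfinite(rv)
        if ok.sum() < 2:
            warnings.warn(f"reference stratum {stratum} empty; skipped")
            continue
        # coverage: fraction of bout samples bracketed by valid ref points
        # within one cadence step of a valid observation
        cadence = np.median(np.diff(rt)) if len(rt) > 1 else 600.0
        covered = np.interp(t, rt, ok.astype(float)) > 0.999
        inside = (t >= rt[ok][0]) & (t <= rt[ok][-1])
        frac = float(np.mean(covered & inside))
        if frac < 0.5:
            warnings.warn(
                f"reference stratum {stratum} covers only {frac:.0%} of the "
                f"bout (cadence {cadence:.0f} s); skipped"
            )
            continue
        x = np.interp(t, rt[ok], rv[ok])
        try:
            intercept, slope, r2, n = ols(x, temp)
        except DegenerateFitError as exc:
            last_error = exc
            continue
        fits.append(StratumFit(stratum, intercept, slope, r2, n,
                               stratum_score(intercept, slope, r2)))
    if not fits:
        if last_error is not None:
            raise DegenerateFitError(
                "all reference strata are degenerate"
            ) from last_error
        raise ValueError("no reference stratum could be fitted")
    fits.sort(key=lambda f: f.score)
    winner = fits[0]
    ambiguous = len(fits) > 1 and (fits[1].score - fits[0].score) < tie_tol
    return winner, fits, ambiguous


def pooled_stratum(segments, reference, min_n: int = 30):
    """Pooled variant of :func:`best_stratum` over several bouts.

    ``segments`` is an iterable of (t, temp) pairs; samples are concatenated
    before fitting, mirroring a regression pooled over all bouts of a phase.
    """
    ts = np.concatenate([np.asarray(t, dtype=float) for t, _ in segments])
    vs = np.concatenate([np.asarray(v, dtype=float) for _, v in segments])
    order = np.argsort(ts, kind="mergesort")
    return best_stratum(ts[order], vs[order], reference, min_n=min_n)
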