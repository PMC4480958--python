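"""Decay-model fitting of donor-coverage curves.

The re-parameterized CCD — fraction of donors covered (y) as a function
of the fraction of somatic mutations retained (x), both in (0, 1] —
decays as the recurrence threshold rises.  We model it with a
two-parameter power law

    y = A * x**b,

fitted by ordinary least squares in (log x, log y) space.  The power law
is an interpretation, not an established ground truth: it is the minimal
monotone two-parameter family able to express both fast-saturating
cohorts (a tiny fraction of hotspot mutations already covers nearly all
donors, so b is near 0) and slow cohorts (coverage climbs roughly in
proportion to the mutation fraction retained, b near 1).

The headline statistic is the mutation fraction needed to cover a target
fraction of donors (default 95%).  Observed data beats the model
whenever it can: if the target coverage is bracketed by observed points
the estimate is a monotone linear interpolation, and only otherwise is
the fitted law inverted (x = (target/A)**(1/b)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_POINTS_DEFAULT = 4


class FitRefusedError(ValueError):
    """Too few usable points to fit the decay model for a scope."""


class NotEstimableError(ValueError):
    """Coverage target cannot be estimated (no bracket and no valid fit)."""


@dataclass(frozen=True)
class FitResult:
    """Power-law fit of a donor-coverage curve for one scope."""

    scope: str
    amplitude: float  # A in y = A * x**b
    exponent: float  # b
    n_points: int  # points actually used in the log-log regression
    rss_log: float  # residual sum of squares in log-log space
    n_excluded: int = 0  # zero-y points excluded from the regression
    model: str = "power-law"

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.amplitude * np.asarray(x, dtype=float) ** self.exponent


def fit_coverage_model(
    points: list[tuple[float, float]],
    scope: str = "curve",
    min_points: int = MIN_POINTS_DEFAULT,
) -> FitResult:
    """Least-squares power-law fit in log-log space.

    Points with y = 0 (no donor covered at that threshold) have no
    logarithm; they are excluded from the regression and counted in
    ``n_excluded``.  Fewer than ``min_points`` usable points refuses the
    fit — cohorts that thin are reported nonparametrically instead.
    """
    pts = [(float(x), float(y)) for x, y in points]
    usable = [(x, y) for x, y in pts if x > 0 and y > 0]
    n_excluded = len(pts) - len(usable)
    if len(usable) < min_points:
        raise FitRefusedError(
            f"scope {scope!r}: {len(usable)} usable points < required {min_points}"
        )
    lx = np.log([x for x, _ in usable])
    ly = np.log([y for _, y in usable])
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    return FitResult(
        scope=scope,
        amplitude=float(np.exp(intercept)),
        exponent=float(slope),
        n_points=len(usable),
        rss_log=float(resid @ resid),
        n_excluded=n_excluded,
    )


def mutation_fraction_at_coverage(
    points: list[tuple[float, float]],
    fit: FitResult | None = None,
    target_donor_fraction: float = 0.95,
) -> tuple[float, str]:
    """Smallest mutation fraction estimated to cover the target donor fraction.

    Returns ``(x, method)`` with method ``"interpolated"`` when the
    target is bracketed by observed points (monotone linear
    interpolation of x against y) and ``"extrapolated"`` when the fitted
    power law must be inverted.  The result is clamped to (0, 1].
    """
    if not (0.0 < target_donor_fraction < 1.0):
        raise ValueError("target donor fraction must be in (0, 1)")
    pts = sorted((float(x), float(y)) for x, y in points)
    ys = [y for _, y in pts]
    if pts and min(ys) <= target_donor_fraction <= max(ys):
        # exact hit first; else bracketing pair (y is monotone in x here)
        for x, y in pts:
            if y == target_donor_fraction:
                return x, "interpolated"
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            lo, hi = min(y0, y1), max(y0, y1)
            if lo < target_donor_fraction < hi:
                x = x0 + (x1 - x0) * (target_donor_fraction - y0) / (y1 - y0)
                return float(min(max(x, 1e-300), 1.0)), "interpolated"
    if fit is None or fit.exponent == 0:
        raise NotEstimableError(
            "target coverage outside the observed range and no usable fit"
        )
    x = (target_donor_fraction / fit.amplitude) ** (1.0 / fit.exponent)
    return float(min(max(x, 1e-300), 1.0)), "extrapolated"
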