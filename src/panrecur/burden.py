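"""Per-donor exonic mutation burden and per-cancer-type distribution summaries.

Burden — the number of exonic somatic mutations a donor carries — varies
enormously between tumor types: cohort medians in public pan-cancer
catalogs span roughly 2.5 orders of magnitude, from ~1 per donor in
chronic myeloid disorders to ~400 in cutaneous melanoma.  The input
catalog is expected to be consequence-filtered to exonic classes
already; donors enrolled in the roster but carrying no passing call
count with burden 0 (a cohort median of 1 is only possible if such
donors are retained), with a flag to drop them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Catalog

logger = logging.getLogger("panrecur")


@dataclass(frozen=True)
class BurdenSummary:
    """Five-number summary of per-donor burdens in one cancer type."""

    cancer_type: str
    n_donors: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float


def donor_burden(catalog: Catalog, include_zero: bool = True) -> pd.DataFrame:
    """Exonic call count per roster donor.

    Returns (cancer_type, donor_id, burden); roster donors without calls
    get 0 unless ``include_zero`` is false.
    """
    counts = (
        catalog.calls.groupby(["cancer_type", "donor_id"], sort=False)
        .size()
        .to_dict()
    )
    rows = []
    for ctype in catalog.roster.types:
        for donor in sorted(catalog.roster.donors(ctype)):
            b = counts.get((ctype, donor), 0)
            if b == 0 and not include_zero:
                continue
            rows.append({"cancer_type": ctype, "donor_id": donor, "burden": b})
    return pd.DataFrame(rows, columns=["cancer_type", "donor_id", "burden"])


def _hinge_quartiles(values: np.ndarray) -> tuple[float, float, float]:
    """Median-of-halves quartiles (Tukey hinges): the median splits the
    sorted sample into halves, excluding itself when n is odd; q1/q3 are
    the medians of those halves."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    med = float(np.median(v))
    half = n // 2
    if half == 0:
        return med, med, med
    lower, upper = v[:half], v[n - half:]
    return float(np.median(lower)), med, float(np.median(upper))


def burden_summary(counts: pd.DataFrame) -> list[BurdenSummary]:
    """Five-number summaries per cancer type, sorted by ascending median.

    ``counts`` is the frame from :func:`donor_burden`; empty groups are
    skipped with a warning.
    """
    out = []
    for ctype, grp in counts.groupby("cancer_type", sort=True):
        vals = grp["burden"].to_numpy()
        if len(vals) == 0:
            logger.warning("cancer type %s has no donors; skipped", ctype)
            continue
        q1, med, q3 = _hinge_quartiles(vals)
        out.append(
            BurdenSummary(
                cancer_type=str(ctype),
                n_donors=len(vals),
                minimum=float(vals.min()),
                q1=q1,
                median=med,
                q3=q3,
                maximum=float(vals.max()),
            )
        )
    out.sort(key=lambda s: (s.median, s.cancer_type))
    return out


def summaries_frame(summaries: list[BurdenSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cancer_type": s.cancer_type, "n": s.n_donors, "min": s.minimum,
             "q1": s.q1, "median": s.median, "q3": s.q3, "max": s.maximum}
            for s in summaries
        ]
    )
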