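"""Mutation recurrence tables, cohort summaries, and donor-coverage curves.

Recurrence of a somatic mutation is the number of *distinct donors* in
which the identical genomic change (chromosome, position, ref, alt) is
observed; a mutation is *recurrent* when seen in at least two donors.
For a catalog scope (one cancer type, or the pooled ``PanCancer`` set)
this module computes:

* the per-mutation recurrence table;
* summary rows in the style of a cohort overview table — unique
  mutations, recurrent mutations (count and percent), and the donors
  carrying at least one recurrent mutation (count and percent of the
  enrolled roster);
* the complementary cumulative distributions (CCD): for an increasing
  recurrence threshold k, the fraction of somatic mutations with
  recurrence >= k, and the fraction of donors carrying at least one
  such mutation.

The re-parameterized curve (donor fraction against mutation fraction)
is the input to the decay-model fitting in :mod:`panrecur.fit`.
"""

from __future__ import annotations

import decimal
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Catalog, DonorRoster, KEY_COLUMNS, MutationKey, PAN_CANCER

logger = logging.getLogger("panrecur")


@dataclass
class RecurrenceTable:
    """Per-mutation distinct-donor counts within one scope.

    ``calls`` retains the deduplicated (donor_id, key) pairs of the scope
    so donor-level queries (who carries a recurrent mutation?) stay
    answerable; ``counts`` maps each unique mutation to its recurrence.
    """

    scope: str
    calls: pd.DataFrame  # columns: donor_id + KEY_COLUMNS (+ gene)
    counts: pd.DataFrame  # columns: KEY_COLUMNS + recurrence

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    @property
    def max_recurrence(self) -> int:
        return int(self.counts["recurrence"].max()) if len(self.counts) else 0

    @property
    def entries(self) -> dict[MutationKey, frozenset]:
        """Materialized map MutationKey -> donor set (small scopes only)."""
        out: dict[MutationKey, set] = {}
        for row in self.calls.itertuples(index=False):
            key = MutationKey(row.chromosome, int(row.start), row.ref, row.alt)
            out.setdefault(key, set()).add(row.donor_id)
        return {k: frozenset(v) for k, v in out.items()}


@dataclass(frozen=True)
class RecurrenceSummary:
    """One cohort-overview row: counts plus formatted percentage cells."""

    scope: str
    donors: int
    total_unique_mutations: int
    recurrent_mutations: int
    recurrent_pct: str
    donors_with_recurrent: int
    donors_with_recurrent_pct: str


@dataclass(frozen=True)
class CoveragePoint:
    k: int
    mutation_fraction: float
    donor_fraction: float


@dataclass
class CoverageCurve:
    """CCD points over recurrence thresholds k = 1..k_max."""

    scope: str
    points: list[CoveragePoint]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"scope": self.scope, "k": p.k,
                 "mutation_fraction": p.mutation_fraction,
                 "donor_fraction": p.donor_fraction}
                for p in self.points
            ]
        )


# ---------------------------------------------------------------------------
# Core counting
# ---------------------------------------------------------------------------

def recurrence_counts(catalog: Catalog, scope: str = PAN_CANCER) -> RecurrenceTable:
    """Count, per unique mutation in ``scope``, the distinct donors carrying it.

    The PanCancer scope pools every cancer type before counting, so a
    mutation seen once in each of two types has recurrence 2 pan-cancer
    while remaining non-recurrent within each type.
    """
    sub = catalog.calls_in_scope(scope)
    if len(sub) == 0:
        logger.warning("scope %s has no calls; empty recurrence table", scope)
        empty = pd.DataFrame(columns=[*KEY_COLUMNS, "recurrence"])
        return RecurrenceTable(scope, sub, empty)
    dedup = sub.drop_duplicates(subset=["donor_id", *KEY_COLUMNS])
    counts = (
        dedup.groupby(list(KEY_COLUMNS), sort=False, observed=True)["donor_id"]
        .nunique()
        .reset_index(name="recurrence")
    )
    return RecurrenceTable(scope, dedup, counts)


def format_percent(numerator: int, denominator: int, decimals: int = 1) -> str:
    """``100*numerator/denominator`` with half-up rounding, ``%``-suffixed.

    Half-up (not banker's) rounding reproduces conventionally printed
    table cells; a zero denominator is the caller's error.
    """
    if denominator <= 0:
        raise ZeroDivisionError("format_percent requires a positive denominator")
    value = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    q = decimal.Decimal(1).scaleb(-decimals)
    return f"{value.quantize(q, rounding=decimal.ROUND_HALF_UP)}%"


def recurrence_summary(table: RecurrenceTable, roster: DonorRoster) -> RecurrenceSummary:
    """Cohort-overview row for one scope.

    Donor percentages use the enrollment roster as denominator — a donor
    enrolled but carrying no passing call still counts in the
    denominator, which is the only reading consistent with cohorts whose
    donor count exceeds what their mutation count could imply.
    """
    n_donors = roster.size(table.scope)
    observed_donors = table.calls["donor_id"].nunique() if len(table.calls) else 0
    if n_donors < observed_donors:
        raise ValueError(
            f"roster for {table.scope} has {n_donors} donors but calls name "
            f"{observed_donors}"
        )
    total = table.n_unique
    rec = table.counts[table.counts["recurrence"] >= 2]
    n_rec = len(rec)
    if n_rec and len(table.calls):
        merged = table.calls.merge(rec[list(KEY_COLUMNS)], on=list(KEY_COLUMNS))
        donors_with = merged["donor_id"].nunique()
    else:
        donors_with = 0
    return RecurrenceSummary(
        scope=table.scope,
        donors=n_donors,
        total_unique_mutations=total,
        recurrent_mutations=n_rec,
        recurrent_pct=format_percent(n_rec, total) if total else "0.0%",
        donors_with_recurrent=donors_with,
        donors_with_recurrent_pct=(
            format_percent(donors_with, n_donors) if n_donors else "0.0%"
        ),
    )


# ---------------------------------------------------------------------------
# Coverage curves (CCDs)
# ---------------------------------------------------------------------------

def coverage_curve(
    table: RecurrenceTable, roster: DonorRoster, k_max: int | None = None
) -> CoverageCurve:
    """CCD of mutation fraction and donor fraction over thresholds 1..k_max.

    mutation_fraction(k) = |{m : rec(m) >= k}| / unique mutations;
    donor_fraction(k)    = |{d : d carries some m with rec(m) >= k}| / roster.
    Both are non-increasing in k and mutation_fraction(1) = 1.
    """
    if table.n_unique == 0:
        logger.warning("empty recurrence table for %s; empty curve", table.scope)
        return CoverageCurve(table.scope, [])
    if k_max is None:
        k_max = table.max_recurrence
    n_total = table.n_unique
    n_roster = roster.size(table.scope)
    rec = table.counts["recurrence"].to_numpy()
    # mutations: sorted recurrence -> tail counts by binary search
    rec_sorted = np.sort(rec)
    # donors: a donor qualifies at k iff max recurrence among its calls >= k
    joined = table.calls.merge(table.counts, on=list(KEY_COLUMNS), how="left")
    donor_max = joined.groupby("donor_id", sort=False)["recurrence"].max().to_numpy()
    donor_max_sorted = np.sort(donor_max)
    points = []
    for k in range(1, k_max + 1):
        n_ge = len(rec_sorted) - np.searchsorted(rec_sorted, k, side="left")
        d_ge = len(donor_max_sorted) - np.searchsorted(donor_max_sorted, k, side="left")
        points.append(
            CoveragePoint(
                k=k,
                mutation_fraction=n_ge / n_total,
                donor_fraction=(d_ge / n_roster) if n_roster else 0.0,
            )
        )
    return CoverageCurve(table.scope, points)


def donors_vs_mutations(curve: CoverageCurve) -> list[tuple[float, float]]:
    """Re-parameterize a CCD as (mutation_fraction, donor_fraction) pairs.

    Sorted by descending k (ascending mutation fraction); duplicate x
    values collapse to the one with maximal y, so the result is a
    monotone staircase suitable for interpolation and fitting.
    """
    best: dict[float, float] = {}
    for p in sorted(curve.points, key=lambda p: -p.k):
        x, y = p.mutation_fraction, p.donor_fraction
        if x not in best or y > best[x]:
            best[x] = y
    return sorted(best.items())


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def summaries_frame(summaries: list[RecurrenceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scope": s.scope,
                "donors": s.donors,
                "total_unique_mutations": s.total_unique_mutations,
                "recurrent_mutations": s.recurrent_mutations,
                "recurrent_pct": s.recurrent_pct,
                "donors_with_recurrent": s.donors_with_recurrent,
                "donors_with_recurrent_pct": s.donors_with_recurrent_pct,
            }
            for s in summaries
        ]
    )
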