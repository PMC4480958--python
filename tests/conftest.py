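"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive data structures (dicts of sets,
explicit loops) so they share no code path with the vectorized
implementations they check.
"""

from __future__ import annotations

import pandas as pd
import pytest

from panrecur.io import Catalog, DonorRoster, MutationKey


# ---------------------------------------------------------------------------
# Toy catalog: d1 carries m1+m2, d2 carries m1, d3 carries m3
# ---------------------------------------------------------------------------

M1 = ("7", 140453136, "A", "T")
M2 = ("12", 25398284, "C", "A")
M3 = ("17", 7577120, "G", "A")


def _call(donor, ctype, key, consequence="missense_variant", gene="GENE1"):
    chrom, start, ref, alt = key
    return {
        "donor_id": donor, "cancer_type": ctype, "chromosome": chrom,
        "start": start, "ref": ref, "alt": alt,
        "consequence": consequence, "gene": gene,
    }


@pytest.fixture
def toy_catalog() -> Catalog:
    rows = [
        _call("d1", "TYP", M1, gene="GA"),
        _call("d1", "TYP", M2, gene="GB"),
        _call("d2", "TYP", M1, gene="GA"),
        _call("d3", "TYP", M3, gene="GC"),
    ]
    return Catalog(pd.DataFrame(rows))


@pytest.fixture
def toy_roster() -> DonorRoster:
    return DonorRoster({"TYP": frozenset({"d1", "d2", "d3"})})


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_recurrence(catalog: Catalog, scope: str) -> dict[MutationKey, frozenset]:
    """Quadratic-spirit reference: explicit row loop into dict-of-sets."""
    out: dict[MutationKey, set] = {}
    for row in catalog.calls.itertuples(index=False):
        if scope != "PanCancer" and row.cancer_type != scope:
            continue
        key = MutationKey(row.chromosome, int(row.start), row.ref, row.alt)
        out.setdefault(key, set()).add(row.donor_id)
    return {k: frozenset(v) for k, v in out.items()}


def brute_coverage(entries: dict, roster_size: int, k_max: int):
    """Reference CCD: per k, filter entries and union donor sets."""
    total = len(entries)
    points = []
    for k in range(1, k_max + 1):
        kept = {m: d for m, d in entries.items() if len(d) >= k}
        donors = set().union(*kept.values()) if kept else set()
        points.append(
            (k, len(kept) / total if total else 0.0,
             len(donors) / roster_size if roster_size else 0.0)
        )
    return points


def brute_gene_matrix(catalog: Catalog, recurrent: set) -> dict:
    """Reference (type, gene) -> distinct donor count; explicit triple loop."""
    cells: dict[tuple[str, str], set] = {}
    for row in catalog.calls.itertuples(index=False):
        key = MutationKey(row.chromosome, int(row.start), row.ref, row.alt)
        if key in recurrent and row.gene:
            cells.setdefault((row.cancer_type, row.gene), set()).add(row.donor_id)
    return {k: len(v) for k, v in cells.items()}
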