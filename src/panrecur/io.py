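"""Reading, normalizing, filtering and writing donor-level somatic mutation catalogs.

The central container is :class:`Catalog`: a tidy table of donor-level
somatic mutation calls (one row per donor x mutation) together with a
:class:`DonorRoster` giving, per cancer type, the full set of enrolled
donors.  Rosters matter because cohort sizes routinely exceed the number
of donors that carry any call passing the filters, and every "fraction
of donors" statistic downstream uses the enrollment denominator.

Input follows the ICGC simple somatic mutation (SSM) TSV dialect: a
header-named tab-separated file with one row per donor x mutation x
consequence.  Rows repeated per consequence are collapsed to a single
call keeping the most severe consequence.  Coordinates are 1-based
inclusive; "-" denotes the empty allele of a pure insertion/deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

logger = logging.getLogger("panrecur")

# ---------------------------------------------------------------------------
# Schema constants
# ---------------------------------------------------------------------------

#: Column order of the tidy internal format (and of ``Catalog.calls``).
CALL_COLUMNS = (
    "donor_id",
    "cancer_type",
    "chromosome",
    "start",
    "ref",
    "alt",
    "consequence",
    "gene",
)

#: Columns identifying a somatic mutation across donors.
KEY_COLUMNS = ("chromosome", "start", "ref", "alt")

#: Allowed chromosome labels after normalization.
VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])

#: ICGC SSM header names -> tidy names.
ICGC_COLUMNS = {
    "icgc_donor_id": "donor_id",
    "project_code": "project_code",
    "chromosome": "chromosome",
    "chromosome_start": "start",
    "reference_genome_allele": "ref",
    "mutated_to_allele": "alt",
    "consequence_type": "consequence",
    "gene_affected": "gene",
}

#: Severity ranking used when collapsing per-consequence rows to one call.
#: Lower rank = more severe = kept.
CONSEQUENCE_PRIORITY = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
    "exon_variant",
    "synonymous_variant",
    "splice_region_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_region",
)

#: Consequence classes treated as exonic by default.
EXONIC_CONSEQUENCES = frozenset(
    {
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "inframe_insertion",
        "inframe_deletion",
        "exon_variant",
    }
)

_PRIORITY_RANK = {c: i for i, c in enumerate(CONSEQUENCE_PRIORITY)}
_UNKNOWN_RANK = len(CONSEQUENCE_PRIORITY)

PAN_CANCER = "PanCancer"


class CatalogFormatError(ValueError):
    """Raised when an input file violates the expected SSM/tidy format."""


class CatalogRecordError(ValueError):
    """Raised for an unparseable record (carries the offending line number)."""


class MutationKey(NamedTuple):
    """Genomic identity of a somatic mutation, shared across donors.

    Two calls with equal keys denote the same mutation; equality is exact
    on all four fields after chromosome normalization.
    """

    chromosome: str
    start: int
    ref: str
    alt: str


def normalize_chromosome(label: str) -> str:
    """Normalize a chromosome label: strip a leading ``chr``, upper-case,
    and map ``M`` to ``MT``."""
    lab = str(label).strip()
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    lab = lab.upper()
    if lab == "M":
        lab = "MT"
    return lab


@dataclass(frozen=True)
class DonorRoster:
    """Per cancer type, the set of enrolled donor ids.

    Enrollment may exceed the donors that carry calls; fractions of donors
    are always computed against this roster.
    """

    by_type: Mapping[str, frozenset]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "DonorRoster":
        acc: dict[str, set] = {}
        for donor, ctype in pairs:
            acc.setdefault(ctype, set()).add(donor)
        return cls({t: frozenset(d) for t, d in acc.items()})

    def donors(self, scope: str = PAN_CANCER) -> frozenset:
        if scope == PAN_CANCER:
            out: set = set()
            for d in self.by_type.values():
                out |= d
            return frozenset(out)
        return self.by_type.get(scope, frozenset())

    def size(self, scope: str = PAN_CANCER) -> int:
        return len(self.donors(scope))

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(sorted(self.by_type))

    def restrict(self, types: Iterable[str]) -> "DonorRoster":
        keep = set(types)
        return DonorRoster({t: d for t, d in self.by_type.items() if t in keep})

    def merged(self) -> "DonorRoster":
        """Merge national projects (CODE-CC -> CODE), unioning donor sets."""
        acc: dict[str, set] = {}
        for t, d in self.by_type.items():
            acc.setdefault(strip_country_suffix(t), set()).update(d)
        return DonorRoster({t: frozenset(d) for t, d in acc.items()})


@dataclass
class Catalog:
    """A deduplicated donor-level somatic mutation catalog plus its roster.

    ``calls`` holds one row per (donor_id, mutation) with columns
    :data:`CALL_COLUMNS`; ``roster`` holds enrollment per cancer type.
    """

    calls: pd.DataFrame
    roster: DonorRoster = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.calls is None or len(self.calls) == 0:
            self.calls = _empty_calls()
        else:
            self.calls = self.calls.loc[:, list(CALL_COLUMNS)].reset_index(drop=True)
        if self.roster is None:
            self.roster = DonorRoster.from_pairs(
                zip(self.calls["donor_id"], self.calls["cancer_type"])
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_calls(self) -> int:
        return len(self.calls)

    @property
    def cancer_types(self) -> tuple[str, ...]:
        return self.roster.types

    def calls_in_scope(self, scope: str) -> pd.DataFrame:
        if scope == PAN_CANCER:
            return self.calls
        return self.calls[self.calls["cancer_type"] == scope]

    def validate(self) -> None:
        """Assert the catalog invariants (dedup, chromosome set, roster cover)."""
        df = self.calls
        if df.duplicated(subset=["donor_id", *KEY_COLUMNS]).any():
            raise ValueError("duplicate (donor_id, mutation) pairs in catalog")
        bad = set(df["chromosome"].unique()) - VALID_CHROMOSOMES
        if bad:
            raise ValueError(f"invalid chromosome labels: {sorted(bad)}")
        if (df["start"] < 1).any():
            raise ValueError("coordinates must be >= 1 (1-based inclusive)")
        observed = set(zip(df["donor_id"], df["cancer_type"]))
        for donor, ctype in observed:
            if donor not in self.roster.donors(ctype):
                raise ValueError(
                    f"donor {donor!r} of type {ctype!r} missing from roster"
                )


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "donor_id": pd.Series(dtype=str),
            "cancer_type": pd.Series(dtype=str),
            "chromosome": pd.Series(dtype=str),
            "start": pd.Series(dtype="int64"),
            "ref": pd.Series(dtype=str),
            "alt": pd.Series(dtype=str),
            "consequence": pd.Series(dtype=str),
            "gene": pd.Series(dtype=str),
        }
    )


def strip_country_suffix(project_code: str) -> str:
    """``BRCA-US`` -> ``BRCA``; codes without a 2-letter country suffix pass
    through unchanged."""
    if "-" in project_code:
        head, _, tail = project_code.rpartition("-")
        if head and len(tail) == 2 and tail.isalpha() and tail.isupper():
            return head
    return project_code


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def _collapse_consequences(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-consequence rows to one call per (donor, mutation),
    keeping the most severe consequence by :data:`CONSEQUENCE_PRIORITY`."""
    if len(df) == 0:
        return df
    rank = df["consequence"].map(_PRIORITY_RANK).fillna(_UNKNOWN_RANK)
    df = df.assign(_rank=rank)
    # stable sort: severity first, then original order for reproducible genes
    df = df.sort_values("_rank", kind="stable")
    df = df.drop_duplicates(subset=["donor_id", *KEY_COLUMNS], keep="first")
    return df.drop(columns="_rank").sort_index().reset_index(drop=True)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_icgc_ssm(
    path,
    include_consequences: Iterable[str] | None = None,
    skip_bad_records: bool = False,
) -> Catalog:
    """Read an ICGC-style SSM TSV into a deduplicated :class:`Catalog`.

    Parameters
    ----------
    path:
        Tab-separated file with at least the ICGC SSM header columns
        (:data:`ICGC_COLUMNS`); extra columns are ignored.
    include_consequences:
        Optional consequence include-list applied after deduplication.
    skip_bad_records:
        If true, records with unparseable coordinates are logged and
        skipped instead of aborting the read.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ICGC_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    df = df.loc[:, list(ICGC_COLUMNS)].rename(columns=ICGC_COLUMNS)

    start = pd.to_numeric(df["start"], errors="coerce")
    bad = start.isna() | (start.fillna(0) < 1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header line + 1-based
        if not skip_bad_records:
            raise CatalogRecordError(
                f"{path}: unparseable or invalid coordinate at line(s) "
                f"{lines[:10]}{'...' if len(lines) > 10 else ''}"
            )
        logger.warning("%s: skipping %d bad record(s) at lines %s",
                       path, int(bad.sum()), lines[:10])
        df = df[~bad]
        start = start[~bad]
    df["start"] = start.astype("int64")

    df["chromosome"] = df["chromosome"].map(normalize_chromosome)
    unknown = set(df["chromosome"].unique()) - VALID_CHROMOSOMES
    if unknown:
        raise CatalogFormatError(
            f"{path}: chromosome label(s) outside 1..22/X/Y/MT: {sorted(unknown)}"
        )

    df["cancer_type"] = df["project_code"].map(strip_country_suffix)
    df = df.drop(columns="project_code")
    df = _collapse_consequences(df.loc[:, list(CALL_COLUMNS)])

    catalog = Catalog(df)
    if include_consequences is not None:
        catalog = filter_consequences(catalog, include_consequences)
    return catalog


def read_donor_manifest(path) -> DonorRoster:
    """Read a two-column (donor_id, project_code) TSV into a roster keyed
    by cancer type (country suffixes stripped)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise CatalogFormatError(f"{path}: expected two columns (donor_id, project_code)")
    donor_col, project_col = df.columns[:2]
    df = df.rename(columns={donor_col: "donor_id", project_col: "project_code"})
    df["cancer_type"] = df["project_code"].map(strip_country_suffix)
    conflicts = df.groupby("donor_id")["cancer_type"].nunique()
    conflicted = conflicts[conflicts > 1]
    if len(conflicted):
        raise CatalogFormatError(
            f"{path}: donor(s) listed under conflicting projects: "
            f"{sorted(conflicted.index)[:5]}"
        )
    return DonorRoster.from_pairs(zip(df["donor_id"], df["cancer_type"]))


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def merge_projects(catalog: Catalog) -> Catalog:
    """Merge national projects of one tumor type (CODE-CC -> CODE).

    Idempotent; a donor carrying the same mutation under two merged
    project codes collapses to a single call.
    """
    df = catalog.calls.copy()
    df["cancer_type"] = df["cancer_type"].map(strip_country_suffix)
    df = df.drop_duplicates(subset=["donor_id", *KEY_COLUMNS]).reset_index(drop=True)
    return Catalog(df, catalog.roster.merged())


def filter_consequences(catalog: Catalog, include: Iterable[str]) -> Catalog:
    """Keep only calls whose consequence is in ``include``.

    The roster is unchanged: donors may drop to zero passing calls yet
    keep contributing to donor denominators.  Unknown terms in the
    include-list produce a warning, not an error.
    """
    include = set(include)
    if not include:
        raise ValueError("consequence include-list must be non-empty")
    unknown = include - set(CONSEQUENCE_PRIORITY)
    if unknown:
        logger.warning("include-list terms not in the known vocabulary: %s",
                       sorted(unknown))
    df = catalog.calls[catalog.calls["consequence"].isin(include)]
    return Catalog(df.reset_index(drop=True), catalog.roster)


def filter_cancer_types(
    catalog: Catalog, min_mutations: int = 0, min_donors: int = 0
) -> Catalog:
    """Drop cancer types with fewer unique mutations or enrolled donors
    than the thresholds; removal is logged with counts."""
    if min_mutations < 0 or min_donors < 0:
        raise ValueError("thresholds must be >= 0")
    keep = []
    for ctype in catalog.cancer_types:
        sub = catalog.calls_in_scope(ctype)
        n_mut = len(sub.drop_duplicates(subset=list(KEY_COLUMNS)))
        n_don = catalog.roster.size(ctype)
        if n_mut >= min_mutations and n_don >= min_donors:
            keep.append(ctype)
        else:
            logger.info(
                "excluding cancer type %s (%d unique mutations, %d donors)",
                ctype, n_mut, n_don,
            )
    df = catalog.calls[catalog.calls["cancer_type"].isin(keep)]
    return Catalog(df.reset_index(drop=True), catalog.roster.restrict(keep))


# ---------------------------------------------------------------------------
# Tidy TSV round-trip
# ---------------------------------------------------------------------------

_TIDY_HEADER_COMMENT = (
    "# panrecur tidy catalog; coordinates 1-based inclusive; '-' = empty allele\n"
)


def write_catalog(catalog: Catalog, path, roster_path=None) -> None:
    """Write the tidy internal TSV (UTF-8, LF); optionally the roster too."""
    df = catalog.calls.sort_values(
        ["cancer_type", "donor_id", *KEY_COLUMNS]
    ).reset_index(drop=True)
    try:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(_TIDY_HEADER_COMMENT)
            df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    except OSError as exc:
        raise OSError(f"cannot write catalog to {path}: {exc}") from exc
    if roster_path is not None:
        write_roster(catalog.roster, roster_path)


def read_catalog(path, roster_path=None) -> Catalog:
    """Read a tidy TSV written by :func:`write_catalog`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in CALL_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogFormatError(
            f"{path}: missing tidy column(s): {', '.join(missing)}"
        )
    if len(df):
        df["start"] = pd.to_numeric(df["start"]).astype("int64")
    else:
        df = _empty_calls()
    roster = read_donor_manifest(roster_path) if roster_path is not None else None
    return Catalog(df, roster)


def write_roster(roster: DonorRoster, path) -> None:
    rows = [
        {"donor_id": d, "project_code": t}
        for t in roster.types
        for d in sorted(roster.donors(t))
    ]
    pd.DataFrame(rows, columns=["donor_id", "project_code"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )
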