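"""Seeded synthetic somatic-mutation catalogs with known recurrence structure.

The generator emulates the statistical shape of a pooled cancer mutation
catalog: per-donor exonic burdens are negative-binomial (heavy-tailed —
real cohorts span ~2.5 orders of magnitude in median burden and contain
hypermutators), and each drawn mutation is either *private* (unique to
its donor by construction) or comes from a finite *hotspot pool* whose
popularity follows a Zipf law, reproducing the few-mountains/many-hills
recurrence landscape in which most mutations are seen in one donor and
only a percent or two recur.

Because hotspot inclusion per donor is an independent event with a
closed-form probability, the expected complementary cumulative
distribution (CCD) of recurrence is computable exactly and serves as the
calibration oracle for the sampler (:func:`expected_recurrence_ccd`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io import CALL_COLUMNS, Catalog, DonorRoster, KEY_COLUMNS

_BASES = "ACGT"

#: Default consequence class frequencies for synthetic calls (exonic mix).
DEFAULT_CONSEQUENCE_PROBS = (
    ("missense_variant", 0.57),
    ("synonymous_variant", 0.25),
    ("stop_gained", 0.05),
    ("frameshift_variant", 0.05),
    ("inframe_insertion", 0.02),
    ("inframe_deletion", 0.02),
    ("exon_variant", 0.02),
    ("stop_lost", 0.01),
    ("start_lost", 0.01),
)

# Coordinate layout guaranteeing key uniqueness: hotspot pool p occupies
# starts [p*POOL_SPAN+1, ...]; private mutations live above PRIVATE_BASE.
_POOL_SPAN = 1_000_000
_PRIVATE_BASE = 1_000_000_000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic cancer-type cohort.

    Attributes
    ----------
    cancer_type:
        Label used as project code / cancer type.
    donors:
        Cohort size (enrolled donors; all appear in the roster even if a
        donor draws zero mutations).
    burden_mean, burden_dispersion:
        Mean and size (dispersion) parameter of the negative-binomial
        per-donor exonic mutation count; variance = mean + mean^2/size,
        so smaller ``burden_dispersion`` gives a heavier tail.
    shared_pool_size:
        Number of potentially recurrent hotspot mutations in this
        cohort's pool.
    shared_fraction:
        Probability that a drawn mutation is a hotspot rather than a
        donor-private mutation.
    zipf_exponent:
        Skew of hotspot popularity: hotspot ``i`` (0-based) has weight
        proportional to ``(i+1)**-zipf_exponent``.
    genes:
        Number of gene labels in the pool's namespace; hotspots map to
        genes once, pool-wide.
    pool_label:
        Cohorts sharing a ``pool_label`` share the identical hotspot pool
        (same mutation keys, genes and consequences), which is what makes
        cross-type recurrence and gene-vector similarity possible.
    seed:
        Base seed; :func:`generate_catalog` derives per-cohort streams
        from it deterministically.
    """

    cancer_type: str = "SYN"
    donors: int = 100
    burden_mean: float = 50.0
    burden_dispersion: float = 1.0
    shared_pool_size: int = 1000
    shared_fraction: float = 0.05
    zipf_exponent: float = 1.2
    genes: int = 100
    pool_label: str = "pan"
    seed: int = 0
    consequence_probs: tuple = DEFAULT_CONSEQUENCE_PROBS

    def validate(self) -> None:
        if self.donors < 1:
            raise ValueError("donors must be >= 1")
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be >= 0")
        if self.burden_mean <= 0:
            raise ValueError("burden_mean must be > 0")
        if self.burden_dispersion <= 0:
            raise ValueError("burden_dispersion must be > 0")
        if self.shared_pool_size < 1 and self.shared_fraction > 0:
            raise ValueError("shared_pool_size must be >= 1 when shared_fraction > 0")
        if self.genes < 1:
            raise ValueError("genes must be >= 1")
        total = sum(p for _, p in self.consequence_probs)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("consequence_probs must sum to 1")

    # -- YAML round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["consequence_probs"] = [list(x) for x in self.consequence_probs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "consequence_probs" in d:
            d["consequence_probs"] = tuple(
                (str(c), float(p)) for c, p in d["consequence_probs"]
            )
        return cls(**d)


def configs_to_yaml(configs: Sequence[SimConfig]) -> str:
    return yaml.safe_dump([c.to_dict() for c in configs], sort_keys=False)


def configs_from_yaml(text: str) -> list[SimConfig]:
    return [SimConfig.from_dict(d) for d in yaml.safe_load(text)]


# ---------------------------------------------------------------------------
# Hotspot pool machinery
# ---------------------------------------------------------------------------

def hotspot_weights(pool_size: int, zipf_exponent: float) -> np.ndarray:
    """Normalized Zipf popularity weights over the hotspot pool."""
    w = (np.arange(1, pool_size + 1, dtype=float)) ** (-zipf_exponent)
    return w / w.sum()


def _alleles_for(start: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = start % 4
    alt_idx = (ref_idx + 1 + start % 3) % 4
    bases = np.array(list(_BASES))
    return bases[ref_idx], bases[alt_idx]


def _build_pool(pool_index: int, pool_label: str, config: SimConfig) -> pd.DataFrame:
    """Fixed pool-wide identity of each hotspot: key, gene, consequence."""
    n = config.shared_pool_size
    i = np.arange(n)
    start = pool_index * _POOL_SPAN + i + 1
    chrom = ((i % 22) + 1).astype(str)
    ref, alt = _alleles_for(start)
    gene = np.array([f"{pool_label}:G{j % config.genes:04d}" for j in i])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7, pool_index]))
    terms = [c for c, _ in config.consequence_probs]
    probs = [p for _, p in config.consequence_probs]
    cons = rng.choice(terms, size=n, p=probs)
    return pd.DataFrame(
        {"chromosome": chrom, "start": start, "ref": ref, "alt": alt,
         "gene": gene, "consequence": cons}
    )


# ---------------------------------------------------------------------------
# Catalog generation
# ---------------------------------------------------------------------------

def generate_catalog(
    config: SimConfig | Sequence[SimConfig], seed: int | None = None
) -> Catalog:
    """Draw a synthetic catalog; deterministic given (config, seed).

    Per donor a burden ``n`` is drawn from the negative binomial; each of
    the ``n`` draws is a Zipf-weighted hotspot with probability
    ``shared_fraction``, else a globally unique private mutation.  Draws
    are with replacement, and a donor repeating the same hotspot
    collapses to one call (mirrored exactly by the binomial-inclusion
    oracle of :func:`expected_recurrence_ccd`).
    """
    configs = [config] if isinstance(config, SimConfig) else list(config)
    if not configs:
        raise ValueError("at least one SimConfig required")
    for c in configs:
        c.validate()
    if len({c.cancer_type for c in configs}) != len(configs):
        raise ValueError("cancer_type labels must be unique across configs")
    base_seed = configs[0].seed if seed is None else seed

    pool_index: dict[str, int] = {}
    pools: dict[str, pd.DataFrame] = {}
    for c in configs:
        if c.pool_label not in pool_index:
            pool_index[c.pool_label] = len(pool_index)
            pools[c.pool_label] = _build_pool(
                pool_index[c.pool_label], c.pool_label, replace(c, seed=base_seed)
            )

    frames: list[pd.DataFrame] = []
    roster_pairs: list[tuple[str, str]] = []
    private_counter = 0
    for ci, c in enumerate(configs):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, ci]))
        donors = [f"{c.cancer_type}_d{j:04d}" for j in range(c.donors)]
        roster_pairs += [(d, c.cancer_type) for d in donors]

        r, mu = c.burden_dispersion, c.burden_mean
        burdens = rng.negative_binomial(n=r, p=r / (r + mu), size=c.donors)
        total = int(burdens.sum())
        if total == 0:
            continue
        donor_idx = np.repeat(np.arange(c.donors), burdens)
        shared = rng.random(total) < c.shared_fraction
        n_shared = int(shared.sum())
        n_private = total - n_shared

        parts = []
        if n_shared:
            w = hotspot_weights(c.shared_pool_size, c.zipf_exponent)
            hs = rng.choice(c.shared_pool_size, size=n_shared, p=w)
            part = pools[c.pool_label].iloc[hs].reset_index(drop=True)
            part["donor_id"] = np.array(donors)[donor_idx[shared]]
            parts.append(part)
        if n_private:
            i = private_counter + np.arange(n_private)
            private_counter += n_private
            start = _PRIVATE_BASE + i
            ref, alt = _alleles_for(start)
            terms = [t for t, _ in c.consequence_probs]
            probs = [p for _, p in c.consequence_probs]
            part = pd.DataFrame(
                {
                    "chromosome": ((i % 22) + 1).astype(str),
                    "start": start,
                    "ref": ref,
                    "alt": alt,
                    "gene": [
                        f"{c.pool_label}:G{g:04d}"
                        for g in rng.integers(0, c.genes, size=n_private)
                    ],
                    "consequence": rng.choice(terms, size=n_private, p=probs),
                }
            )
            part["donor_id"] = np.array(donors)[donor_idx[~shared]]
            parts.append(part)

        df = pd.concat(parts, ignore_index=True)
        df["cancer_type"] = c.cancer_type
        df = df.drop_duplicates(subset=["donor_id", *KEY_COLUMNS])
        frames.append(df.loc[:, list(CALL_COLUMNS)])

    calls = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(CALL_COLUMNS))
    )
    calls = calls.sort_values(["cancer_type", "donor_id", *KEY_COLUMNS]).reset_index(
        drop=True
    )
    return Catalog(calls, DonorRoster.from_pairs(roster_pairs))


def drawn_burdens(
    config: SimConfig | Sequence[SimConfig], seed: int | None = None
) -> pd.DataFrame:
    """Replay the per-donor burden draws of :func:`generate_catalog`.

    Returns (donor_id, cancer_type, burden) for the same (config, seed);
    the catalog's call count equals the burden sum up to within-donor
    hotspot collisions (exactly, when ``shared_fraction`` is 0).
    """
    configs = [config] if isinstance(config, SimConfig) else list(config)
    base_seed = configs[0].seed if seed is None else seed
    rows = []
    for ci, c in enumerate(configs):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, ci]))
        r, mu = c.burden_dispersion, c.burden_mean
        burdens = rng.negative_binomial(n=r, p=r / (r + mu), size=c.donors)
        rows += [
            {"donor_id": f"{c.cancer_type}_d{j:04d}", "cancer_type": c.cancer_type,
             "burden": int(b)}
            for j, b in enumerate(burdens)
        ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Analytic recurrence oracle
# ---------------------------------------------------------------------------

def _nb_pgf(z: float | np.ndarray, mean: float, dispersion: float):
    """Probability generating function of the negative binomial."""
    r = dispersion
    return (r / (r + mean * (1.0 - z))) ** r


def hotspot_inclusion_probs(config: SimConfig) -> np.ndarray:
    """Per-donor probability that each hotspot is carried at least once.

    A donor with burden ``n`` includes hotspot ``i`` with probability
    ``1 - (1 - f*q_i)**n``; marginalizing over the negative-binomial
    burden gives ``1 - G(1 - f*q_i)`` with ``G`` the burden pgf.
    """
    q = hotspot_weights(config.shared_pool_size, config.zipf_exponent)
    a = config.shared_fraction * q
    return 1.0 - _nb_pgf(1.0 - a, config.burden_mean, config.burden_dispersion)


def expected_tail_counts(
    donor_counts: Sequence[int],
    prob_matrix: Sequence[np.ndarray],
    k_max: int,
) -> np.ndarray:
    """``E[#hotspots with recurrence >= k]`` for k = 1..k_max.

    Hotspot i's recurrence is the independent sum over cohorts t of
    Binomial(D_t, p_ti); the sum's pmf is built by convolution over
    0..k_max with an overflow bin, so tail expectations are exact.
    """
    if not prob_matrix:
        return np.zeros(k_max)
    n_hot = len(prob_matrix[0])
    pmf = np.zeros((n_hot, k_max + 2))  # bins 0..k_max plus overflow
    pmf[:, 0] = 1.0
    ks = np.arange(k_max + 1)
    for D, p in zip(donor_counts, prob_matrix):
        comp = stats.binom.pmf(ks[None, :], D, np.asarray(p)[:, None])
        comp_tail = stats.binom.sf(k_max, D, np.asarray(p))
        nxt = np.zeros_like(pmf)
        for k in range(k_max + 1):
            block = pmf[:, : k_max + 1] * comp[:, k : k + 1]
            keep = min(k_max + 1 - k, k_max + 1)
            nxt[:, k : k + keep] += block[:, :keep]
            nxt[:, k_max + 1] += block[:, keep:].sum(axis=1)
        nxt[:, k_max + 1] += comp_tail * pmf[:, : k_max + 1].sum(axis=1)
        nxt[:, k_max + 1] += pmf[:, k_max + 1]
        pmf = nxt
    # P(rec >= k) per hotspot: survival over bins k..k_max plus overflow
    sf = np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1]
    return sf[:, 1 : k_max + 1].sum(axis=0)


def expected_recurrence_ccd(
    config: SimConfig | Sequence[SimConfig], k_max: int = 10
) -> pd.DataFrame:
    """Expected mutation-fraction CCD of :func:`generate_catalog`'s output.

    Uses the ratio-of-expectations convention: the fraction at threshold
    k is ``E[#hotspots rec>=k] / E[#observed mutations]``, where observed
    mutations are hotspots seen at least once plus expected private
    calls.  At k=1 the fraction is 1 by definition; a single-donor
    cohort has fraction 0 for k >= 2.
    """
    configs = [config] if isinstance(config, SimConfig) else list(config)
    for c in configs:
        c.validate()
    by_pool: dict[str, list[SimConfig]] = {}
    for c in configs:
        by_pool.setdefault(c.pool_label, []).append(c)

    expected_private = sum(
        c.donors * c.burden_mean * (1.0 - c.shared_fraction) for c in configs
    )
    total_e_ge = np.zeros(k_max)  # index k-1 -> E[#hotspots rec >= k]
    for members in by_pool.values():
        if len({c.shared_pool_size for c in members}) != 1:
            raise ValueError("cohorts sharing a pool must agree on its size")
        e_ge = expected_tail_counts(
            [c.donors for c in members],
            [hotspot_inclusion_probs(c) for c in members],
            k_max,
        )
        total_e_ge += e_ge

    e_observed = total_e_ge[0] + expected_private
    rows = [{"k": 1, "mutation_fraction": 1.0}]
    for k in range(2, k_max + 1):
        frac = total_e_ge[k - 1] / e_observed if e_observed > 0 else 0.0
        rows.append({"k": k, "mutation_fraction": float(frac)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_panel(name: str) -> list[SimConfig]:
    """Documented cohort panels spanning the burden regimes seen in real
    pan-cancer catalogs.

    ``low-burden``  — one cohort with median ~1 exonic mutation/donor
    (chronic myeloid disorder-like); ``high-burden`` — one cohort with
    median ~400 (melanoma-like); ``pan-mini`` — a six-cohort panel
    sharing one hotspot pool, spanning both regimes at desk scale;
    ``pan-large`` — an eight-cohort, ~650-donor panel producing on the
    order of a million calls for end-to-end scale runs.
    """
    presets = {
        "low-burden": [
            SimConfig(
                cancer_type="LOWB",
                donors=129,
                burden_mean=1.6,
                burden_dispersion=1.5,
                shared_pool_size=60,
                shared_fraction=0.30,
                zipf_exponent=1.2,
                genes=40,
                pool_label="low",
            )
        ],
        "high-burden": [
            SimConfig(
                cancer_type="HIGHB",
                donors=323,
                burden_mean=470.0,
                burden_dispersion=3.0,
                shared_pool_size=3000,
                shared_fraction=0.05,
                zipf_exponent=1.1,
                genes=400,
                pool_label="high",
            )
        ],
        "pan-mini": [
            SimConfig("CMLK", donors=60, burden_mean=2.0, burden_dispersion=1.5,
                      shared_pool_size=1500, shared_fraction=0.60, zipf_exponent=0.8,
                      genes=120, pool_label="pan"),
            SimConfig("BRLK", donors=120, burden_mean=35.0, burden_dispersion=1.5,
                      shared_pool_size=1500, shared_fraction=0.12, zipf_exponent=0.8,
                      genes=120, pool_label="pan"),
            SimConfig("COLK", donors=80, burden_mean=90.0, burden_dispersion=1.2,
                      shared_pool_size=1500, shared_fraction=0.16, zipf_exponent=0.8,
                      genes=120, pool_label="pan"),
            SimConfig("LULK", donors=70, burden_mean=160.0, burden_dispersion=1.5,
                      shared_pool_size=1500, shared_fraction=0.08, zipf_exponent=0.8,
                      genes=120, pool_label="pan"),
            SimConfig("OVLK", donors=50, burden_mean=60.0, burden_dispersion=1.0,
                      shared_pool_size=1500, shared_fraction=0.10, zipf_exponent=0.8,
                      genes=120, pool_label="pan"),
            SimConfig("MELK", donors=60, burden_mean=420.0, burden_dispersion=3.0,
                      shared_pool_size=1500, shared_fraction=0.06, zipf_exponent=0.8,
                      genes=120, pool_label="pan"),
        ],
        "pan-large": [
            SimConfig("TYA", donors=120, burden_mean=900.0, burden_dispersion=3.0,
                      shared_pool_size=4000, shared_fraction=0.02, zipf_exponent=1.1,
                      genes=500, pool_label="pan"),
            SimConfig("TYB", donors=110, burden_mean=1600.0, burden_dispersion=3.0,
                      shared_pool_size=4000, shared_fraction=0.02, zipf_exponent=1.1,
                      genes=500, pool_label="pan"),
            SimConfig("TYC", donors=100, burden_mean=2500.0, burden_dispersion=3.0,
                      shared_pool_size=4000, shared_fraction=0.015, zipf_exponent=1.1,
                      genes=500, pool_label="pan"),
            SimConfig("TYD", donors=90, burden_mean=1200.0, burden_dispersion=2.0,
                      shared_pool_size=4000, shared_fraction=0.02, zipf_exponent=1.2,
                      genes=500, pool_label="pan"),
            SimConfig("TYE", donors=80, burden_mean=2000.0, burden_dispersion=2.0,
                      shared_pool_size=4000, shared_fraction=0.02, zipf_exponent=1.2,
                      genes=500, pool_label="pan"),
            SimConfig("TYF", donors=60, burden_mean=1800.0, burden_dispersion=2.0,
                      shared_pool_size=4000, shared_fraction=0.02, zipf_exponent=1.1,
                      genes=500, pool_label="pan"),
            SimConfig("TYG", donors=50, burden_mean=1500.0, burden_dispersion=2.0,
                      shared_pool_size=4000, shared_fraction=0.025, zipf_exponent=1.1,
                      genes=500, pool_label="pan"),
            SimConfig("TYH", donors=40, burden_mean=400.0, burden_dispersion=1.5,
                      shared_pool_size=4000, shared_fraction=0.03, zipf_exponent=1.2,
                      genes=500, pool_label="pan"),
        ],
    }
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    return presets[name]
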