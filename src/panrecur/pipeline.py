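"""End-to-end orchestration: ingest/simulate -> filter -> statistics -> report.

A single :class:`RunConfig` drives the whole analysis and every artifact
is written under one output directory:

* ``catalog.tsv`` / ``roster.tsv`` — the tidy filtered catalog;
* ``summary.tsv`` — one cohort-overview row per cancer type plus the
  pooled PanCancer row (unique / recurrent mutations, donors covered);
* ``table1.txt`` — the same table formatted with thousands separators
  and ``count (pct%)`` cells;
* ``curves.tsv`` — CCD points (scope, k, mutation_fraction,
  donor_fraction);
* ``fits.tsv`` — power-law fits and the mutation fraction covering the
  target donor fraction, per scope;
* ``burden.tsv`` / ``burden_summary.tsv`` — per-donor burdens and
  five-number summaries;
* ``gene_matrix.tsv``, ``similarity.tsv``, ``dendrogram.nwk`` — the
  clustering artifacts;
* ``manifest.json`` — config echo, package/library versions, seed, and
  row counts after every stage, sufficient to reproduce the run.

Runs are deterministic under a fixed seed, and the stage audit asserts
that filtering never increases calls or donors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    Catalog,
    EXONIC_CONSEQUENCES,
    PAN_CANCER,
    filter_cancer_types,
    filter_consequences,
    merge_projects,
    read_donor_manifest,
    read_icgc_ssm,
    write_catalog,
)
from .burden import burden_summary, donor_burden, summaries_frame as burden_frame
from .fit import FitRefusedError, NotEstimableError, fit_coverage_model, \
    mutation_fraction_at_coverage
from .recurrence import (
    coverage_curve,
    donors_vs_mutations,
    recurrence_counts,
    recurrence_summary,
    summaries_frame,
)
from .similarity import (
    cosine_similarity_matrix,
    gene_donor_matrix,
    hierarchical_dendrogram,
    pan_recurrent_set,
    to_newick,
)
from .simulate import SimConfig, generate_catalog, preset_panel

logger = logging.getLogger("panrecur")


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run.

    Exactly one of ``ssm_path`` (real input) or ``sim_configs`` /
    ``preset`` (synthetic mode) must be set.
    """

    out_dir: str | Path = "panrecur_out"
    ssm_path: str | Path | None = None
    manifest_path: str | Path | None = None
    sim_configs: list[SimConfig] | None = None
    preset: str | None = None
    include_consequences: frozenset = EXONIC_CONSEQUENCES
    merge_national_projects: bool = True
    min_mutations: int = 4
    min_donors: int = 0
    fit_min_donors: int = 50
    target_donor_fraction: float = 0.95
    linkage: str = "average"
    seed: int = 0
    include_zero_burden: bool = True
    plots: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        synthetic = self.sim_configs is not None or self.preset is not None
        if synthetic == (self.ssm_path is not None):
            raise ValueError(
                "exactly one of an SSM input path or a synthetic config/preset "
                "must be given"
            )
        if not (0.0 < self.target_donor_fraction < 1.0):
            raise ValueError("target donor fraction must be in (0, 1)")


@dataclass
class ReportBundle:
    """In-memory handles to everything a run produced."""

    catalog: Catalog
    summaries: pd.DataFrame
    curves: pd.DataFrame
    fits: pd.DataFrame
    burdens: pd.DataFrame
    burden_summaries: pd.DataFrame
    gene_matrix: pd.DataFrame | None
    similarity: pd.DataFrame | None
    newick: str | None
    manifest: dict
    out_dir: Path


def _stage(manifest: dict, name: str, catalog: Catalog) -> None:
    manifest["stages"].append(
        {
            "stage": name,
            "calls": int(catalog.n_calls),
            "donors": int(catalog.roster.size()),
            "cancer_types": len(catalog.cancer_types),
        }
    )
    logger.info(
        "stage %-22s calls=%-9d donors=%-6d types=%d",
        name, catalog.n_calls, catalog.roster.size(), len(catalog.cancer_types),
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis; see the module docstring for outputs."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "panrecur_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "stages": [],
        "config": _config_echo(config),
    }

    stage = "ingest"
    try:
        # ---- ingest / generate ------------------------------------------
        if config.ssm_path is not None:
            catalog = read_icgc_ssm(config.ssm_path)
            if config.manifest_path is not None:
                catalog = Catalog(catalog.calls, read_donor_manifest(config.manifest_path))
        else:
            sims = config.sim_configs or preset_panel(config.preset)
            catalog = generate_catalog(sims, seed=config.seed)
        _stage(manifest, "ingest", catalog)

        stage = "merge"
        if config.merge_national_projects:
            catalog = merge_projects(catalog)
            _stage(manifest, "merge_projects", catalog)

        stage = "filter_consequences"
        catalog = filter_consequences(catalog, config.include_consequences)
        _stage(manifest, "filter_consequences", catalog)

        stage = "filter_cancer_types"
        catalog = filter_cancer_types(
            catalog, min_mutations=config.min_mutations, min_donors=config.min_donors
        )
        _stage(manifest, "filter_cancer_types", catalog)
        _audit_conservation(manifest)
        write_catalog(catalog, out / "catalog.tsv", out / "roster.tsv")

        # ---- recurrence summaries + curves ------------------------------
        stage = "recurrence"
        scopes = list(catalog.cancer_types) + [PAN_CANCER]
        tables = {s: recurrence_counts(catalog, s) for s in scopes}
        summaries = [
            recurrence_summary(tables[s], catalog.roster)
            for s in scopes
            if tables[s].n_unique > 0
        ]
        sum_frame = summaries_frame(summaries)
        sum_frame.to_csv(out / "summary.tsv", sep="\t", index=False)
        (out / "table1.txt").write_text(table1_report(summaries), encoding="utf-8")

        stage = "coverage"
        curves = {
            s: coverage_curve(tables[s], catalog.roster)
            for s in scopes
            if tables[s].n_unique > 0
        }
        curve_frame = pd.concat(
            [c.to_frame() for c in curves.values()], ignore_index=True
        )
        curve_frame.to_csv(out / "curves.tsv", sep="\t", index=False)

        # ---- decay fits + coverage estimates ----------------------------
        stage = "fit"
        fit_rows = []
        for s, curve in curves.items():
            pts = donors_vs_mutations(curve)
            n_don = catalog.roster.size(s)
            row: dict = {"scope": s, "n_donors": n_don}
            if s != PAN_CANCER and n_don < config.fit_min_donors:
                row["status"] = "skipped_small_cohort"
                fit_rows.append(row)
                continue
            try:
                fr = fit_coverage_model(pts, scope=s)
                row.update(
                    status="fitted", amplitude=fr.amplitude, exponent=fr.exponent,
                    n_points=fr.n_points, rss_log=fr.rss_log,
                )
            except FitRefusedError:
                fr = None
                row["status"] = "fit_refused"
            try:
                x, method = mutation_fraction_at_coverage(
                    pts, fr, config.target_donor_fraction
                )
                row["x_at_target"] = x
                row["method_at_target"] = method
            except NotEstimableError:
                row["method_at_target"] = "not_estimable"
            fit_rows.append(row)
        fits = pd.DataFrame(fit_rows)
        fits.to_csv(out / "fits.tsv", sep="\t", index=False)

        # ---- burdens -----------------------------------------------------
        stage = "burden"
        burdens = donor_burden(catalog, include_zero=config.include_zero_burden)
        burdens.to_csv(out / "burden.tsv", sep="\t", index=False)
        bsum = burden_frame(burden_summary(burdens))
        bsum.to_csv(out / "burden_summary.tsv", sep="\t", index=False)

        # ---- similarity + dendrogram ------------------------------------
        stage = "similarity"
        gene_matrix = sim_matrix = None
        newick = None
        recurrent = pan_recurrent_set(tables[PAN_CANCER])
        if recurrent and len(catalog.cancer_types) >= 2:
            try:
                gene_matrix = gene_donor_matrix(catalog, recurrent)
                nz = gene_matrix[(gene_matrix.sum(axis=1) > 0)]
                if len(nz) >= 2:
                    sim_matrix = cosine_similarity_matrix(nz)
                    dendro = hierarchical_dendrogram(sim_matrix, config.linkage)
                    newick = to_newick(dendro)
                    gene_matrix.to_csv(out / "gene_matrix.tsv", sep="\t")
                    sim_matrix.to_csv(out / "similarity.tsv", sep="\t")
                    (out / "dendrogram.nwk").write_text(newick + "\n", encoding="utf-8")
            except ValueError as exc:
                logger.warning("similarity stage skipped: %s", exc)
        else:
            logger.warning("no pan-recurrent mutations or <2 types; no clustering")

        if config.plots:
            _render_plots(out, curve_frame, burdens)

        manifest["linkage"] = config.linkage
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return ReportBundle(
        catalog=catalog,
        summaries=sum_frame,
        curves=curve_frame,
        fits=fits,
        burdens=burdens,
        burden_summaries=bsum,
        gene_matrix=gene_matrix,
        similarity=sim_matrix,
        newick=newick,
        manifest=manifest,
        out_dir=out,
    )


def _config_echo(config: RunConfig) -> dict:
    echo = {
        "ssm_path": str(config.ssm_path) if config.ssm_path else None,
        "manifest_path": str(config.manifest_path) if config.manifest_path else None,
        "preset": config.preset,
        "sim_configs": [c.to_dict() for c in config.sim_configs]
        if config.sim_configs
        else None,
        "include_consequences": sorted(config.include_consequences),
        "merge_national_projects": config.merge_national_projects,
        "min_mutations": config.min_mutations,
        "min_donors": config.min_donors,
        "fit_min_donors": config.fit_min_donors,
        "target_donor_fraction": config.target_donor_fraction,
        "linkage": config.linkage,
        "seed": config.seed,
        "include_zero_burden": config.include_zero_burden,
    }
    return echo


def _audit_conservation(manifest: dict) -> None:
    """Assert calls/donors never increase through the filtering stages."""
    stages = manifest["stages"]
    for prev, cur in zip(stages, stages[1:]):
        if cur["calls"] > prev["calls"] or cur["donors"] > prev["donors"]:
            raise AssertionError(
                f"stage {cur['stage']} increased calls/donors over {prev['stage']}"
            )
    manifest["conservation_ok"] = True


def _render_plots(out: Path, curves: pd.DataFrame, burdens: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for scope, grp in curves.groupby("scope"):
        ax.plot(grp["mutation_fraction"], grp["donor_fraction"],
                marker="o", ms=2, lw=1, label=scope)
    ax.set_xscale("log")
    ax.set_xlabel("fraction of somatic mutations")
    ax.set_ylabel("fraction of donors")
    ax.legend(fontsize=5, ncol=2)
    fig.tight_layout()
    fig.savefig(out / "coverage.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    order = (
        burdens.groupby("cancer_type")["burden"].median().sort_values().index
    )
    data = [burdens.loc[burdens["cancer_type"] == t, "burden"] for t in order]
    ax.boxplot(data, labels=list(order))
    ax.set_yscale("symlog")
    ax.set_ylabel("exonic mutations per donor")
    plt.xticks(rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(out / "burden.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Table formatting
# ---------------------------------------------------------------------------

def table1_report(summaries) -> str:
    """Cohort-overview table: one row per cancer type, PanCancer last.

    Counts carry thousands separators; the recurrent-mutation and
    donor-coverage cells are formatted ``count (pct%)``.
    """
    header = (
        "Cancer Type\tDonors\tTotal Unique Mutations\t"
        "Total Recurrent Mutations\tDonors with Recurrent Mutations"
    )
    typed = [s for s in summaries if s.scope != PAN_CANCER]
    pooled = [s for s in summaries if s.scope == PAN_CANCER]
    lines = [header]
    for s in sorted(typed, key=lambda s: s.scope) + pooled:
        lines.append(
            f"{s.scope}\t{s.donors:,}\t{s.total_unique_mutations:,}\t"
            f"{s.recurrent_mutations:,} ({s.recurrent_pct})\t"
            f"{s.donors_with_recurrent:,} ({s.donors_with_recurrent_pct})"
        )
    return "\n".join(lines) + "\n"
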