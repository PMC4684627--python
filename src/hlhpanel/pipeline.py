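"""End-to-end orchestration: simulate -> qc -> call-cnv -> filter ->
diagnose -> burden, with plain-text intermediates, a manifest and a
consolidated Markdown report.

Every stage writes TSV so any step can be re-run standalone on the
saved intermediates; re-running with an identical config and seed
reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .cnv_caller import call_deletions, calls_to_frame, normalize
from .cohort_stats import carrier_burden, fisher_2x2
from .coverage_qc import failed_amplicons, summarize_coverage
from .diagnosis import (
    InheritanceModel,
    classify_cohort,
    cohort_yield,
    trigger_table,
)
from .io import (
    write_coverage,
    write_panel_bed,
    write_gene_config,
    write_patients,
    write_report,
    write_variants_tsv,
)
from .panel import default_panel
from .synthetic_data import SimulationConfig, simulate_cohort, simulate_coverage, simulate_population
from .variant_filter import FilterConfig, run_cascade

logger = logging.getLogger(__name__)

__all__ = ["run_all"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Run the whole pipeline per a config mapping.

    Required blocks: ``seed`` (int) and ``simulate`` (simulation
    parameters; may be empty for defaults).  Optional: ``filters``.
    Returns the output directory.
    """
    for block in ("seed", "simulate"):
        if block not in config:
            raise ValueError(f"config missing required block: {block!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    sim_kwargs = dict(config.get("simulate") or {})
    sim = SimulationConfig(seed=seed, **sim_kwargs)
    fcfg = FilterConfig(**dict(config.get("filters") or {}))

    genes, amplicons = default_panel()
    write_panel_bed(amplicons, out / "panel.bed")
    write_gene_config(genes, out / "genes.yaml")

    # --- simulate
    coverage, cov_truth = simulate_coverage(genes, amplicons, sim)
    variants, genotypes, patients, truth = simulate_cohort(genes, amplicons, sim)
    write_coverage(coverage, out / "coverage.tsv")
    write_variants_tsv(variants, genotypes, out / "variants.tsv")
    write_patients(patients, out / "patients.tsv")

    # --- qc
    qc = summarize_coverage(coverage, genes, amplicons, cutoff=10.0)
    write_report(qc.to_frame(), out / "qc_summary.tsv")

    # --- cnv
    failed = failed_amplicons(coverage, cutoff=10.0, amplicons=amplicons)
    norm = normalize(coverage, failed=failed)
    sexes = {p.id: p.sex for p in patients}
    calls, unconfirmed = call_deletions(norm, genes, amplicons, sexes)
    write_report(calls_to_frame(calls), out / "cnv_calls.tsv")
    write_report(calls_to_frame(unconfirmed), out / "cnv_unconfirmed.tsv")

    # --- filter (patient mode)
    survivors, trace = run_cascade(variants, fcfg, mode="patient")
    write_variants_tsv(
        survivors,
        [g for g in genotypes if g.variant_key in {v.key for v in survivors}],
        out / "variants_filtered.tsv",
    )
    write_report(trace.to_frame(), out / "filter_trace.tsv")
    for step in trace.steps:
        logger.info(
            "filter %-12s %4d -> %4d", step.name, step.input_count, step.output_count
        )

    # --- diagnose
    model = InheritanceModel.from_genes(genes)
    surviving_keys = {v.key for v in survivors}
    kept_gts = [g for g in genotypes if g.variant_key in surviving_keys]
    results = classify_cohort(patients, survivors, kept_gts, model, deletion_calls=calls)
    res_df = pd.DataFrame(
        [
            {
                "patient": r.patient_id,
                "status": r.status,
                "causal_gene": r.causal_gene or "",
                "disease": r.disease_label or "",
                "causal_variants": ";".join(r.causal_variants),
            }
            for r in results
        ]
    )
    write_report(res_df, out / "diagnoses.tsv")
    yields = cohort_yield(results, patients)
    write_report(yields.to_frame(), out / "yields.tsv")
    table = trigger_table(results, patients)
    trigger_p = fisher_2x2(table)

    # --- population burden (if sites configured)
    burden = None
    if sim.pop_sites:
        counts, geno, site_variants = simulate_population(genes, sim)
        write_report(counts, out / "population_counts.tsv")
        genotype_counts = {
            v.key: (int(r["n_AA"]), int(r["n_Aa"]), int(r["n_aa"]))
            for v, (_, r) in zip(site_variants, counts.iterrows())
        }
        pop_survivors, pop_trace = run_cascade(
            site_variants, fcfg, mode="population", genotype_counts=genotype_counts
        )
        write_report(pop_trace.to_frame(), out / "population_filter_trace.tsv")
        key_of = {v.hgvs_c: v.gene for v in pop_survivors}  # site label -> gene
        burden = carrier_burden(geno, key_of)
        write_report(burden.to_frame(), out / "burden.tsv")

    # --- consolidated report + manifest
    vus = sum(1 for r in results if r.status == "vus_only")
    with open(out / "report.md", "w") as fh:
        fh.write("# HLH panel pipeline report\n\n")
        fh.write(f"Seed: {seed}; samples: {sim.n_samples}\n\n")
        fh.write("## Coverage QC\n\n")
        fh.write(f"- failed amplicons (mean <= 10x): {len(qc.failed)}\n")
        fh.write(f"- mean per-gene coverage: {qc.mean_gene_pct:.1f}%\n\n")
        fh.write("## CNV calls\n\n")
        fh.write(f"- deletion calls: {len(calls)} (unconfirmed single dips: {len(unconfirmed)})\n\n")
        fh.write("## Filter cascade\n\n")
        for step in trace.steps:
            fh.write(f"- {step.name}: {step.input_count} -> {step.output_count}\n")
        fh.write("\n## Diagnoses\n\n")
        num, den = yields.overall
        fh.write(f"- diagnosed: {num}/{den} ({yields.pct(yields.overall):.0f}%)\n")
        fh.write(f"- monoallelic VUS carriers: {vus}\n")
        fh.write(f"- trigger enrichment Fisher p = {trigger_p:.3g}\n")
        if burden is not None:
            fh.write("\n## Population burden\n\n")
            fh.write(
                f"- carriers: {burden.n_carriers}/{burden.n_individuals} "
                f"({100 * burden.carrier_fraction:.1f}%)\n"
            )

    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": {k: v for k, v in config.items()},
        "checksums": {p.name: _sha256(p) for p in outputs},
        "row_counts": {
            "patients": len(patients),
            "variants": len(variants),
            "filtered_variants": len(survivors),
            "cnv_calls": len(calls),
            "diagnosed": sum(1 for r in results if r.status == "diagnosed"),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
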