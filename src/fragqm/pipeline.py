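"""End-to-end pipeline: simulate → ingest → compare → test → report.

Every stage persists its artifact (population files, deduplicated documents,
paired-results CSV, report JSON, rendered tables) so each rendered number can
be re-derived from the stage outputs.  The whole run is deterministic given
the configured seeds.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as fio
from .comparison import Report, aggregate_report, paired_evaluate
from .measures import MeasurementPeriod, load_catalog
from .records import deduplicate_documents
from .synth import GeneratorConfig, SyntheticPopulation, generate_population

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_table2", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    catalog_path: str | None = None  # None -> packaged 14-measure catalog
    n_resamples: int = 2000
    stats_seed: int = 0
    out_dir: str = "fragqm_run"

    @property
    def period(self) -> MeasurementPeriod:
        return self.generator.period


@dataclass
class PipelineResult:
    population: SyntheticPopulation
    n_documents_received: int
    n_documents_deduplicated: int
    report: Report
    out_dir: Path


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML; unspecified fields keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen_raw = raw.pop("generator", {})
    if "period" in gen_raw:
        p = gen_raw["period"]
        if isinstance(p, int):
            gen_raw["period"] = MeasurementPeriod.calendar_year(p)
        else:
            from datetime import date

            gen_raw["period"] = MeasurementPeriod(
                date.fromisoformat(str(p["start"])), date.fromisoformat(str(p["end"]))
            )
    generator = dataclasses.replace(GeneratorConfig(), **gen_raw)
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"generator"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    return PipelineConfig(generator=generator, **raw)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in order, logging counts at each stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: generating population (seed=%d)", config.generator.seed)
    pop = generate_population(config.generator)
    fio.write_population(pop, out / "population")
    logger.info(
        "simulate: %d patients, %d facilities, %d documents",
        len(pop.patients),
        len(pop.facilities),
        len(pop.documents),
    )

    logger.info("stage ingest: deduplicating documents")
    n_received = len(pop.documents)
    deduped = deduplicate_documents(pop.documents)
    logger.info("ingest: %d received, %d retained (%d duplicates removed)",
                n_received, len(deduped), n_received - len(deduped))
    clean = SyntheticPopulation(patients=pop.patients, facilities=pop.facilities, documents=deduped)

    logger.info("stage compare: dual-scope evaluation of %d measures", 14)
    catalog = load_catalog(config.catalog_path)
    paired = paired_evaluate(clean, catalog, config.period)
    fio.write_paired_results(paired, out / "paired_results.csv")

    logger.info("stage test/report: aggregation and symmetry tests")
    report = aggregate_report(
        paired, clean, catalog, n_resamples=config.n_resamples, seed=config.stats_seed
    )
    fio.write_report(report, out / "report.json")
    csv_table, text_table = render_table2(report)
    (out / "measure_table.csv").write_text(csv_table)
    (out / "measure_table.txt").write_text(text_table)
    pd.DataFrame([o.to_dict() for o in report.organizations]).to_csv(
        out / "organization_rates.csv", index=False
    )
    logger.info(
        "report: %d applicable calculations, %d discrepancies (%.1f%%), %d/%d patients affected",
        report.applicable_calculations,
        report.discrepancies,
        100 * (report.overall_change_fraction or 0.0),
        report.patients_with_change,
        report.n_patients,
    )
    return PipelineResult(
        population=clean,
        n_documents_received=n_received,
        n_documents_deduplicated=len(deduped),
        report=report,
        out_dir=out,
    )


_CATS = ["NA_TO_NC", "NA_TO_CC", "NC_TO_CC", "CC_TO_NC", "OTHER"]


def render_table2(report: Report) -> tuple[str, str]:
    """Render the per-measure impact table (CSV and aligned text).

    One row per measure — compliance change, applicable calculations, the
    five discrepancy columns and the FDR-adjusted q-value — plus a totals row
    whose category counts equal the column sums.  Measures with no applicable
    calculations render dashes rather than zeros-as-rates.
    """
    rows = []
    for m in sorted(
        report.measures,
        key=lambda s: (s.compliance_change_pp if s.compliance_change_pp is not None else 0.0),
    ):
        has_change = m.compliance_change_pp is not None
        rows.append(
            {
                "measure": f"{m.description} ({m.measure_id})",
                "compliance_change_pct": f"{m.compliance_change_pp:+.1f}" if has_change else "-",
                "applicable_calculations": m.applicable_count if m.applicable_count else "-",
                **{c.lower(): m.category_counts.get(c, 0) for c in _CATS},
                "q_value": "-" if m.q_value is None else f"{m.q_value:.4g}",
            }
        )
    totals = {c.lower(): report.category_totals.get(c, 0) for c in _CATS}
    rows.append(
        {
            "measure": "Total",
            "compliance_change_pct": "",
            "applicable_calculations": report.applicable_calculations,
            **totals,
            "q_value": "",
        }
    )
    df = pd.DataFrame(rows)
    return df.to_csv(index=False), df.to_string(index=False) + "\n"
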