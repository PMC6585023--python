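"""End-to-end orchestration of the discovery and association workflows.

``run_discovery`` executes the fixed stage order: merge case calls ->
SNV restriction -> rarity filter -> control-exome exclusion -> CADD filter ->
brain-expression gene restriction -> minimum-patient filter -> Poisson
accumulation test -> case/control chi-square accumulation -> validation mask
-> stage-1 triage, recording every stage's survivor counts in a
:class:`~rareburden.filtering.FilterTrace`.  ``run_association`` turns a
carrier-count table into the stratified association report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import __version__
from .assoc import build_association_report, stage1_triage
from .burden import (
    case_control_accumulation_test,
    min_patient_filter,
    poisson_burden_test,
    tabulate_gene_counts,
)
from .filtering import (
    FilterConfig,
    FilterTrace,
    annotate_variants,
    apply_validation_mask,
    brain_expression_gene_set,
    exclude_control_observed,
    filter_class,
    filter_deleterious,
    filter_rare,
    merge_case_variants,
    restrict_to_genes,
    variant_keys,
)

__all__ = ["PipelineConfig", "RunReport", "run_discovery", "run_association"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregated thresholds of the discovery workflow."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    q_poisson: float = 0.01
    q_chisq: float = 0.05
    min_patients: int = 2
    n_tests: int | None = None  # default: number of variants advancing triage
    mh_continuity: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("q_poisson", "q_chisq"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_patients < 0:
            raise ValueError("min_patients must be non-negative")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterConfig(**raw.pop("filter", {}))
        return cls(filter=filt, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Machine-readable summary of a pipeline run."""

    trace: FilterTrace
    burden: pd.DataFrame | None = None
    accumulation: pd.DataFrame | None = None
    candidate_variants: pd.DataFrame | None = None
    triage_advanced: pd.DataFrame | None = None
    triage_dropped: pd.DataFrame | None = None
    association: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)
    version: str = ""

    def summary(self) -> dict:
        out: dict = {
            "version": self.version,
            "config": self.config,
            "trace": self.trace.to_records(),
        }
        if self.burden is not None:
            out["burden"] = {
                "genes_tested": int(len(self.burden)),
                "genes_significant": int(self.burden["significant"].sum()),
            }
        if self.accumulation is not None:
            out["accumulation"] = {
                "genes_tested": int(len(self.accumulation)),
                "genes_significant": int(self.accumulation["significant"].sum()),
            }
        if self.triage_advanced is not None:
            out["triage"] = {
                "advanced": int(len(self.triage_advanced)),
                "dropped": int(len(self.triage_dropped)),
            }
        if self.association is not None:
            out["association_rows"] = int(len(self.association))
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [f"rareburden {self.version}", "", "stage trace:"]
        for s in self.trace.stages:
            lines.append(
                f"  {s['stage']:<30} variants={s['variants']:<8}"
                f" genes={s['genes']} samples={s['samples']}"
            )
        summary = self.summary()
        for key in ("burden", "accumulation", "triage"):
            if key in summary:
                lines.append(f"{key}: {summary[key]}")
        return "\n".join(lines) + "\n"


def _qualifying_control_table(
    control_calls: Mapping[str, Iterable[tuple]],
    annotations: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Apply the variant-level qualifying filters to the control cohort."""
    table = merge_case_variants(control_calls)
    if len(table) == 0:
        return table
    table = annotate_variants(table, annotations)
    table = filter_class(table, keep="SNV")
    table = filter_rare(table, config.filter)
    table = filter_deleterious(table, config.filter)
    return table


def run_discovery(
    case_calls: Mapping[str, Iterable[tuple]],
    annotations: pd.DataFrame,
    genes: pd.DataFrame,
    control_calls: Mapping[str, Iterable[tuple]],
    config: PipelineConfig | None = None,
    validation_failures: Iterable[tuple] = (),
    stage1_control_carriers: Mapping[tuple, int] | None = None,
) -> RunReport:
    """Run the variant discovery workflow end to end.

    Parameters
    ----------
    case_calls, control_calls:
        Per-sample variant key sets for cases and in-house control exomes
        (e.g. from :func:`rareburden.filtering.read_vcf`).
    annotations, genes:
        Variant and gene annotation tables.
    validation_failures:
        Keys that failed orthogonal validation (removed before triage).
    stage1_control_carriers:
        Optional per-variant control carrier counts from first-stage
        genotyping; when omitted the control-exome carrier counts of each
        candidate variant are used (zero by construction after the exclusion
        filter, so every candidate advances).
    """
    config = config or PipelineConfig()
    trace = FilterTrace()
    control_keys = set().union(*control_calls.values()) if control_calls else set()

    table = merge_case_variants(case_calls)
    table = annotate_variants(table, annotations)
    trace.record("merged", table)

    table = filter_class(table, keep="SNV")
    trace.record("snv_only", table)

    table = filter_rare(table, config.filter)
    trace.record("rare_or_unreported", table)

    table = exclude_control_observed(table, control_keys)
    trace.record("not_in_control_exomes", table)

    table = filter_deleterious(table, config.filter)
    trace.record("cadd_above_20", table)

    expressed = brain_expression_gene_set(genes, config.filter)
    table = restrict_to_genes(table, expressed)
    trace.record("brain_expressed_genes", table)

    counts = tabulate_gene_counts(table, genes)
    counts = min_patient_filter(counts, config.min_patients)
    table = restrict_to_genes(table, set(counts["gene"]))
    trace.record("min_patient_genes", table)

    burden = poisson_burden_test(counts, q_threshold=config.q_poisson)
    burden_hits = set(burden.loc[burden["significant"], "gene"])
    table = restrict_to_genes(table, burden_hits)
    trace.record("poisson_significant", table)

    # case/control carrier accumulation on the Poisson-significant genes:
    # controls contribute carriers of their own qualifying variants in the
    # same genes, under the same variant-level filters
    accumulation = None
    if len(table):
        ctrl_table = _qualifying_control_table(control_calls, annotations, config)
        ctrl_carriers_by_gene: dict[str, set] = {}
        if len(ctrl_table):
            for gene, sub in ctrl_table.groupby("gene"):
                carriers: set = set()
                for c in sub["carriers"]:
                    carriers.update(c)
                ctrl_carriers_by_gene[gene] = carriers
        per_gene = []
        for gene, sub in table.groupby("gene"):
            patients: set = set()
            for c in sub["carriers"]:
                patients.update(c)
            per_gene.append(
                {
                    "gene": gene,
                    "case_carriers": len(patients),
                    "control_carriers": len(ctrl_carriers_by_gene.get(gene, ())),
                }
            )
        accumulation = case_control_accumulation_test(
            pd.DataFrame(per_gene),
            n_cases=len(case_calls),
            n_controls=max(len(control_calls), 1),
            q_threshold=config.q_chisq,
        )
        acc_hits = set(accumulation.loc[accumulation["significant"], "gene"])
        table = restrict_to_genes(table, acc_hits)
    trace.record("chisq_significant", table)

    table = apply_validation_mask(table, validation_failures)
    trace.record("validated", table)

    # stage-1 triage: advance candidates absent from first-stage controls
    stage1 = dict(stage1_control_carriers or {})
    cand = table.copy()
    cand["control_carriers"] = [
        stage1.get((r.chrom, r.pos, r.ref, r.alt), 0)
        for r in cand.itertuples(index=False)
    ]
    cand["variant"] = [
        f"{r.chrom}:{r.pos}:{r.ref}:{r.alt}" for r in cand.itertuples(index=False)
    ]
    advanced, dropped = stage1_triage(cand)
    trace.record("stage1_advanced", advanced)

    return RunReport(
        trace=trace,
        burden=burden,
        accumulation=accumulation,
        candidate_variants=cand,
        triage_advanced=advanced,
        triage_dropped=dropped,
        config=config.to_dict(),
        version=__version__,
    )


def run_association(
    counts: pd.DataFrame,
    n_tests: int | None = None,
    config: PipelineConfig | None = None,
) -> RunReport:
    """Run the staged association analysis on a carrier-count table.

    ``counts`` columns: ``variant``, ``stratum``, ``cases_determined``,
    ``case_carriers``, ``controls_determined``, ``control_carriers`` (and
    optionally ``gene``).  Returns a report whose ``association`` table
    mirrors the per-stratum / combined layout of a staged case-control study.
    """
    config = config or PipelineConfig()
    if n_tests is None:
        n_tests = config.n_tests
    report_table = build_association_report(counts, n_tests=n_tests)
    trace = FilterTrace()
    trace.add("association_input", counts["variant"].nunique())
    trace.add("association_rows", len(report_table))
    return RunReport(
        trace=trace,
        association=report_table,
        config=config.to_dict(),
        version=__version__,
    )
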