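"""Step-by-step exome variant and gene filters.

The discovery cascade mirrors a rare-variant exome workflow: merge all
per-case calls into one table, restrict to SNVs, keep variants that are rare
(< 1% or unreported) in every public frequency panel, drop variants seen in
in-house control exomes, keep highly deleterious variants (scaled CADD
C score > 20), and restrict to genes expressed in brain.  Every stage records
its survivor counts in a :class:`FilterTrace`.

Variant keys are normalised tuples ``(chrom, pos, ref, alt)`` with the chrom
as a string without a ``chr`` prefix, 1-based position and upper-case alleles.
All filters are pure subset operations on a pandas variant table, hence
monotone, idempotent and (for the per-variant predicates) commuting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import ANNOTATION_COLUMNS, BRAIN_REGIONS, PANELS

__all__ = [
    "FilterConfig",
    "FilterTrace",
    "AnnotationError",
    "InputConsistencyError",
    "normalize_key",
    "read_vcf",
    "read_annotations",
    "read_genes",
    "merge_case_variants",
    "annotate_variants",
    "filter_class",
    "filter_rare",
    "exclude_control_observed",
    "filter_deleterious",
    "brain_expression_gene_set",
    "restrict_to_genes",
    "apply_validation_mask",
    "screen_known_pathogenic",
]

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed annotation values (e.g. frequency outside [0, 1])."""


class InputConsistencyError(ValueError):
    """Inconsistent inputs (e.g. conflicting REF alleles at one position)."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the filtering cascade.

    ``maf_threshold``: keep variants with every reported panel frequency
    strictly below this (default 0.01).  ``cadd_threshold``: keep variants
    with scaled C score strictly above this (default 20).  ``rpkm_floor``:
    genes must have mean brain RPKM strictly above this (default 0).
    ``zscore_cutoff``: among expressed genes, exclude those whose expression
    z-score is at or below this (default -1.96).  ``zscore_log``: compute the
    z-score on log10 summary RPKM (default) rather than on the raw scale.
    ``cadd_missing``: policy for variants without a CADD score
    ("drop", "keep" or "error").
    """

    maf_threshold: float = 0.01
    cadd_threshold: float = 20.0
    zscore_cutoff: float = -1.96
    rpkm_floor: float = 0.0
    zscore_log: bool = True
    cadd_missing: str = "drop"

    def __post_init__(self):
        if not 0.0 < self.maf_threshold <= 1.0:
            raise ValueError("maf_threshold must be in (0, 1]")
        if self.cadd_threshold < 0:
            raise ValueError("cadd_threshold must be >= 0")
        if self.cadd_missing not in ("drop", "keep", "error"):
            raise ValueError("cadd_missing must be 'drop', 'keep' or 'error'")


@dataclass
class FilterTrace:
    """Ordered record of filter stages and surviving counts."""

    stages: list[dict] = field(default_factory=list)

    def add(
        self,
        stage: str,
        n_variants: int,
        n_genes: int | None = None,
        n_samples: int | None = None,
    ) -> None:
        self.stages.append(
            {
                "stage": stage,
                "variants": int(n_variants),
                "genes": None if n_genes is None else int(n_genes),
                "samples": None if n_samples is None else int(n_samples),
            }
        )
        logger.info(
            "stage %-28s variants=%d genes=%s samples=%s",
            stage, n_variants, n_genes, n_samples,
        )

    def record(self, stage: str, table: pd.DataFrame) -> None:
        n_genes = table["gene"].nunique() if "gene" in table.columns else None
        n_samples = None
        if "carriers" in table.columns and len(table):
            n_samples = len(set().union(*table["carriers"]))
        elif "carriers" in table.columns:
            n_samples = 0
        self.add(stage, len(table), n_genes, n_samples)

    def to_records(self) -> list[dict]:
        return [dict(s) for s in self.stages]

    def variant_counts(self) -> list[int]:
        return [s["variants"] for s in self.stages]


def normalize_key(chrom, pos, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Normalise a variant key: chrom without 'chr', 1-based int pos, upper-case alleles."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return (c, int(pos), str(ref).upper(), str(alt).upper())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_vcf(path: str) -> dict[str, set]:
    """Read a (possibly multi-sample) VCF into per-sample carrier key sets.

    A sample carries a variant if its genotype includes at least one copy of
    the alternate allele.  Multi-allelic records contribute one key per ALT.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    carriers: dict[str, set] = {s: set() for s in samples}
    for rec in vcf:
        for alt in rec.ALT:
            key = normalize_key(rec.CHROM, rec.POS, rec.REF, alt)
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            for s, gt in zip(samples, rec.gt_types):
                if gt in (1, 3):
                    carriers[s].add(key)
    return carriers


def read_annotations(path: str) -> pd.DataFrame:
    """Read the variant annotation TSV (empty panel cells = unreported)."""
    table = pd.read_csv(
        path, sep="\t", dtype={"chrom": str, "rsid": str}, keep_default_na=True
    )
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise AnnotationError(f"annotation table lacks columns: {missing}")
    table["rsid"] = table["rsid"].fillna("")
    return table


def read_genes(path: str) -> pd.DataFrame:
    """Read the gene table (symbol, cds_length, 13 expression columns)."""
    table = pd.read_csv(path, sep="\t")
    needed = {"symbol", "cds_length", *BRAIN_REGIONS}
    missing = needed - set(table.columns)
    if missing:
        raise AnnotationError(f"gene table lacks columns: {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# merging and annotation
# ---------------------------------------------------------------------------

def merge_case_variants(per_sample: Mapping[str, Iterable[tuple]]) -> pd.DataFrame:
    """Merge per-sample variant calls into one table with carrier lists.

    One row per distinct ``(chrom, pos, ref, alt)`` key; ``carriers`` is the
    frozenset of sample IDs carrying it.  Two distinct REF alleles at the same
    position are rejected as inconsistent calls.
    """
    carried_by: dict[tuple, set] = {}
    for sample, keys in per_sample.items():
        for key in keys:
            key = normalize_key(*key)
            carried_by.setdefault(key, set()).add(sample)
    refs_at: dict[tuple, set] = {}
    for chrom, pos, ref, _alt in carried_by:
        refs_at.setdefault((chrom, pos), set()).add(ref)
    conflicts = {loc: refs for loc, refs in refs_at.items() if len(refs) > 1}
    if conflicts:
        loc, refs = next(iter(sorted(conflicts.items())))
        raise InputConsistencyError(
            f"conflicting REF alleles {sorted(refs)} at {loc[0]}:{loc[1]}"
        )
    keys = sorted(carried_by)
    if not keys:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=object),
                "pos": pd.Series(dtype=int),
                "ref": pd.Series(dtype=object),
                "alt": pd.Series(dtype=object),
                "carriers": pd.Series(dtype=object),
            }
        )
    return pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "pos": [k[1] for k in keys],
            "ref": [k[2] for k in keys],
            "alt": [k[3] for k in keys],
            "carriers": [frozenset(carried_by[k]) for k in keys],
        }
    )


def annotate_variants(table: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Left-join annotations (gene, class, panel freqs, CADD) onto the table."""
    ann = annotations.drop(columns=["cohort"], errors="ignore")
    ann = ann.drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    ann = ann.assign(pos=ann["pos"].astype(int), chrom=ann["chrom"].astype(str))
    return table.merge(ann, on=["chrom", "pos", "ref", "alt"], how="left")


def variant_keys(table: pd.DataFrame) -> set[tuple]:
    return {
        (r.chrom, r.pos, r.ref, r.alt) for r in table.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# variant-level filters (pure subset operations)
# ---------------------------------------------------------------------------

def filter_class(table: pd.DataFrame, keep: str = "SNV") -> pd.DataFrame:
    """Keep only variants of one class (default SNV)."""
    return table[table["variant_class"] == keep].copy()


def _panel_columns(table: pd.DataFrame) -> list[str]:
    cols = [c for c in table.columns if c.startswith("af_")]
    return cols or [f"af_{p}" for p in PANELS if f"af_{p}" in table.columns]


def filter_rare(table: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Keep variants rare in every public panel.

    A variant passes iff, for every panel, it is unreported (NaN) or its
    frequency is strictly below ``maf_threshold``.
    """
    config = config or FilterConfig()
    cols = _panel_columns(table)
    if not cols:
        return table.copy()
    freqs = table[cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.nanmin(freqs, initial=0.0) < 0 or np.nanmax(freqs, initial=0.0) > 1:
            raise AnnotationError("panel frequency outside [0, 1]")
    rare = np.all(np.isnan(freqs) | (freqs < config.maf_threshold), axis=1)
    return table[rare].copy()


def exclude_control_observed(
    table: pd.DataFrame, control_keys: Iterable[tuple]
) -> pd.DataFrame:
    """Drop variants whose key appears in the control exome call set."""
    controls = {normalize_key(*k) for k in control_keys}
    if not controls:
        return table.copy()
    keep = [
        (r.chrom, r.pos, r.ref, r.alt) not in controls
        for r in table.itertuples(index=False)
    ]
    return table[keep].copy()


def filter_deleterious(
    table: pd.DataFrame, config: FilterConfig | None = None
) -> pd.DataFrame:
    """Keep variants with scaled C score strictly above the threshold."""
    config = config or FilterConfig()
    scores = table["cadd_scaled"].to_numpy(dtype=float)
    missing = np.isnan(scores)
    if missing.any():
        if config.cadd_missing == "error":
            raise AnnotationError(f"{missing.sum()} variants lack a CADD score")
        if config.cadd_missing == "drop":
            logger.info("dropping %d variants without CADD score", missing.sum())
    with np.errstate(invalid="ignore"):
        passing = scores > config.cadd_threshold
    if config.cadd_missing == "keep":
        passing = passing | missing
    return table[passing].copy()


# ---------------------------------------------------------------------------
# gene-level expression filter
# ---------------------------------------------------------------------------

def brain_expression_gene_set(
    genes: pd.DataFrame, config: FilterConfig | None = None
) -> set[str]:
    """Select genes expressed in brain.

    The per-gene summary is the mean of the 13 per-region median RPKM values.
    Genes with summary <= ``rpkm_floor`` (default 0) are removed; among the
    remaining genes, z-scores of the (by default log10) summary are computed
    and genes with z <= ``zscore_cutoff`` are removed.
    """
    config = config or FilterConfig()
    expr = genes[list(BRAIN_REGIONS)].to_numpy(dtype=float)
    if (expr < 0).any():
        raise AnnotationError("negative RPKM value in gene expression table")
    summary = expr.mean(axis=1)
    expressed = summary > config.rpkm_floor
    values = summary[expressed]
    if config.zscore_log:
        values = np.log10(values)
    if len(values) > 1 and values.std(ddof=0) > 0:
        z = (values - values.mean()) / values.std(ddof=0)
    else:
        z = np.zeros(len(values))
    keep = z > config.zscore_cutoff
    symbols = genes.loc[expressed, "symbol"].to_numpy()
    return set(symbols[keep])


def restrict_to_genes(table: pd.DataFrame, gene_set: Iterable[str]) -> pd.DataFrame:
    """Keep variants whose gene is in the retained set; unannotated rows drop."""
    genes = set(gene_set)
    assigned = table["gene"].notna()
    if (~assigned).any():
        logger.info("dropping %d variants without a gene assignment", (~assigned).sum())
    return table[assigned & table["gene"].isin(genes)].copy()


def apply_validation_mask(
    table: pd.DataFrame, failed_keys: Iterable[tuple]
) -> pd.DataFrame:
    """Remove variants that failed orthogonal validation (e.g. Sanger)."""
    failed = {normalize_key(*k) for k in failed_keys}
    if not failed:
        return table.copy()
    keep = [
        (r.chrom, r.pos, r.ref, r.alt) not in failed
        for r in table.itertuples(index=False)
    ]
    removed = len(table) - sum(keep)
    logger.info("validation mask removed %d variants", removed)
    return table[keep].copy()


def screen_known_pathogenic(
    table: pd.DataFrame, known_mutations: Iterable[tuple]
) -> pd.DataFrame:
    """Report (not filter) overlaps with a user-supplied pathogenic mutation list.

    Used to check a cohort for known autosomal-dominant early-onset mutations
    (e.g. in APP/PSEN1/PSEN2) before rare-variant discovery; returns the
    overlapping rows so the caller can report their presence or absence.
    """
    known = {normalize_key(*k) for k in known_mutations}
    hit = [
        (r.chrom, r.pos, r.ref, r.alt) in known for r in table.itertuples(index=False)
    ]
    return table[hit].copy()
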