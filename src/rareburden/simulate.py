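"""Synthetic exome cohorts for the rare-variant discovery pipeline.

Generates a gene universe (heavy-tailed CDS lengths, partly brain-silent
expression across 13 brain regions) and case/control variant tables with the
statistical structure the downstream analysis assumes: per-gene qualifying
variant counts proportional to CDS length (Poisson), an optional minority of
"risk" genes with an elevated variant rate in cases, per-variant panel
frequencies and CADD-style deleteriousness scores, and heterozygous singleton
carriers.  Everything is deterministic under the configured seed, so the whole
pipeline is testable without any external data.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BRAIN_REGIONS",
    "PANELS",
    "SimulationConfig",
    "generate_gene_universe",
    "simulate_gene_counts",
    "generate_cohort",
    "write_fixture",
]

#: The 13 brain regions whose median expression (RPKM) is attached to each
#: gene; mirrors the brain sub-tissues of a bulk-tissue expression atlas.
BRAIN_REGIONS: tuple[str, ...] = (
    "amygdala",
    "anterior_cingulate_cortex",
    "caudate",
    "cerebellar_hemisphere",
    "cerebellum",
    "cortex",
    "frontal_cortex",
    "hippocampus",
    "hypothalamus",
    "nucleus_accumbens",
    "putamen",
    "spinal_cord",
    "substantia_nigra",
)

#: Public allele-frequency panels emulated by the generator.  A variant may be
#: reported in any subset of them; an empty entry means "not reported".
PANELS: tuple[str, ...] = ("g1000", "esp6500", "exac", "tommo")

N_REGIONS = len(BRAIN_REGIONS)


class ConfigurationError(ValueError):
    """Raised when a simulation or pipeline configuration is invalid."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the data regime of a 202-case / 176-control exome
    discovery cohort: roughly one qualifying variant per kilobase of coding
    sequence per cohort, about 19% of genes silent in brain, and a null
    (no risk gene) configuration unless ``risk_gene_fraction`` is raised.

    Parameters
    ----------
    seed:
        Base seed; identical configs produce byte-identical output.
    n_genes, n_cases, n_controls:
        Universe and cohort sizes.
    baseline_rate:
        Expected qualifying variants per CDS base pair per cohort.
    risk_gene_fraction:
        Proportion of genes designated "risk" genes.
    risk_rate_multiplier:
        Rate multiplier (rho >= 1) applied to the case variant rate in risk
        genes; 1.0 is the exchangeable null.
    frac_panel_reported:
        Probability a variant carries a (rare, < 0.01) public-panel frequency.
    frac_panel_common:
        Probability a variant is reported with a common (>= 0.01) frequency,
        exercising the rarity filter's rejection branch.
    cadd_pass_prob:
        Probability a variant's scaled C score exceeds 20.
    frac_brain_silent:
        Proportion of genes with all-zero brain expression.
    frac_indel:
        Proportion of variants labeled as indels (class label only; used to
        exercise the SNV restriction filter).
    frac_homozygous:
        Proportion of carried variants called homozygous instead of the
        default heterozygous singleton.
    """

    seed: int = 0
    n_genes: int = 5000
    n_cases: int = 202
    n_controls: int = 176
    baseline_rate: float = 0.001
    risk_gene_fraction: float = 0.0
    risk_rate_multiplier: float = 1.0
    frac_panel_reported: float = 0.5
    frac_panel_common: float = 0.05
    cadd_pass_prob: float = 0.3
    frac_brain_silent: float = 0.19
    frac_indel: float = 0.0
    frac_homozygous: float = 0.0

    def validate(self) -> None:
        proportions = {
            "risk_gene_fraction": self.risk_gene_fraction,
            "frac_panel_reported": self.frac_panel_reported,
            "frac_panel_common": self.frac_panel_common,
            "cadd_pass_prob": self.cadd_pass_prob,
            "frac_brain_silent": self.frac_brain_silent,
            "frac_indel": self.frac_indel,
            "frac_homozygous": self.frac_homozygous,
        }
        for name, value in proportions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.frac_panel_reported + self.frac_panel_common > 1.0:
            raise ConfigurationError(
                "frac_panel_reported + frac_panel_common must not exceed 1"
            )
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be non-negative")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigurationError("cohort sizes must be positive")
        if self.baseline_rate < 0:
            raise ConfigurationError("baseline_rate must be non-negative")
        if self.risk_rate_multiplier < 1.0:
            raise ConfigurationError("risk_rate_multiplier must be >= 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


# CDS-length model: log-normal with median 1500 bp and sigma 0.8 on the log
# scale, truncated below at 100 bp -- a plausible heavy-tailed human CDS scale.
CDS_LOG_MEDIAN = np.log(1500.0)
CDS_LOG_SIGMA = 0.8
CDS_MIN = 100

# Expression model for non-silent genes: a shared gene-level factor on the
# log10-RPKM scale plus small per-region noise, so regions are strongly
# correlated within a gene and the across-gene summary has log-normal tails.
EXPR_GENE_LOC = 0.8
EXPR_GENE_SCALE = 0.7
EXPR_REGION_SCALE = 0.15


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    return np.random.default_rng([config.seed, stream])


def generate_gene_universe(config: SimulationConfig) -> pd.DataFrame:
    """Generate the synthetic gene universe.

    Returns a DataFrame with one row per gene: ``symbol``, ``cds_length``
    (bp, >= 100) and one median-RPKM column per brain region.  A
    ``frac_brain_silent`` fraction of genes has all-zero expression.
    """
    config.validate()
    if config.n_genes == 0:
        cols = ["symbol", "cds_length", *BRAIN_REGIONS]
        return pd.DataFrame(columns=cols)
    rng = _rng(config, 0)
    n = config.n_genes
    symbols = [f"GENE{i + 1:05d}" for i in range(n)]
    lengths = np.exp(rng.normal(CDS_LOG_MEDIAN, CDS_LOG_SIGMA, n))
    lengths = np.maximum(np.round(lengths), CDS_MIN).astype(int)

    silent = rng.random(n) < config.frac_brain_silent
    gene_factor = rng.normal(EXPR_GENE_LOC, EXPR_GENE_SCALE, n)
    region_noise = rng.normal(0.0, EXPR_REGION_SCALE, (n, N_REGIONS))
    expr = 10.0 ** (gene_factor[:, None] + region_noise)
    expr[silent] = 0.0

    out = pd.DataFrame({"symbol": symbols, "cds_length": lengths})
    for j, region in enumerate(BRAIN_REGIONS):
        out[region] = expr[:, j]
    return out


def _risk_mask(config: SimulationConfig, n_genes: int) -> np.ndarray:
    rng = _rng(config, 1)
    n_risk = int(round(config.risk_gene_fraction * n_genes))
    mask = np.zeros(n_genes, dtype=bool)
    if n_risk > 0:
        mask[rng.choice(n_genes, size=n_risk, replace=False)] = True
    return mask


def simulate_gene_counts(
    config: SimulationConfig,
    genes: pd.DataFrame,
    cohort: str = "cases",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-gene qualifying-variant counts for one cohort.

    Counts are Poisson with mean ``baseline_rate * cds_length``; in the case
    cohort, risk genes use ``baseline_rate * risk_rate_multiplier``.  Returns
    ``(counts, risk_mask)`` aligned with ``genes``.  This count-level path is
    the statistical core of the generator and is what the full variant-level
    :func:`generate_cohort` builds on.
    """
    config.validate()
    if cohort not in ("cases", "controls"):
        raise ValueError(f"unknown cohort {cohort!r}")
    lengths = genes["cds_length"].to_numpy(dtype=float)
    risk = _risk_mask(config, len(genes))
    rate = np.full(len(genes), config.baseline_rate)
    if cohort == "cases":
        rate = np.where(risk, rate * config.risk_rate_multiplier, rate)
    stream = 2 if cohort == "cases" else 3
    rng = _rng(config, stream)
    counts = rng.poisson(rate * lengths)
    return counts, risk


_BASES = np.array(list("ACGT"))
# genes are laid out on fictitious contigs, 10 Mb apart, 22 genes per "chrom"
_GENE_SPACING = 10_000_000


def _gene_locus(index: int) -> tuple[str, int]:
    chrom = str(index % 22 + 1)
    start = (index // 22 + 1) * _GENE_SPACING
    return chrom, start


def _make_variants(
    config: SimulationConfig,
    genes: pd.DataFrame,
    counts: np.ndarray,
    sample_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Materialise per-variant rows for one cohort's per-gene counts."""
    rows: list[dict] = []
    lengths = genes["cds_length"].to_numpy()
    symbols = genes["symbol"].to_numpy()
    for gi in np.flatnonzero(counts):
        k = int(counts[gi])
        chrom, start = _gene_locus(gi)
        offsets = rng.choice(int(lengths[gi]), size=min(k, int(lengths[gi])), replace=False)
        for off in np.sort(offsets):
            ref, alt = rng.choice(4, size=2, replace=False)
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(start + off),
                    "ref": _BASES[ref],
                    "alt": _BASES[alt],
                    "gene": symbols[gi],
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "gene", "variant_class",
                     "consequence", "cadd_scaled", "carrier", "homozygous"]
        )
    table = pd.DataFrame(rows)
    n = len(table)
    # class / consequence labels
    is_indel = rng.random(n) < config.frac_indel
    table["variant_class"] = np.where(is_indel, "indel", "SNV")
    # indels get a two-base alt so REF != ALT stays true and the label is honest
    if is_indel.any():
        alt = table["alt"].to_numpy(dtype=object)
        extra = _BASES[rng.integers(0, 4, size=n)]
        alt[is_indel] = alt[is_indel] + extra[is_indel]
        table["alt"] = alt
    table["consequence"] = np.where(
        rng.random(n) < 0.75, "nonsynonymous", "synonymous"
    )
    # scaled CADD: above 20 with prob cadd_pass_prob, exponential tail above
    passing = rng.random(n) < config.cadd_pass_prob
    table["cadd_scaled"] = np.where(
        passing,
        20.0 + rng.exponential(8.0, n),
        rng.uniform(0.0, 20.0, n),
    ).round(3)
    # one carrier per variant (rare singleton regime)
    carriers = rng.integers(0, len(sample_ids), size=n)
    table["carrier"] = [sample_ids[i] for i in carriers]
    table["homozygous"] = rng.random(n) < config.frac_homozygous
    return table


def _attach_panel_freqs(
    table: pd.DataFrame, config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Assign panel frequencies: unreported (NaN), rare (<0.01) or common."""
    n = len(table)
    for panel in PANELS:
        table[f"af_{panel}"] = np.nan
    if n == 0:
        return table
    u = rng.random(n)
    rare = u < config.frac_panel_reported
    common = u >= 1.0 - config.frac_panel_common
    freqs = np.where(
        common,
        rng.uniform(0.01, 0.5, n),
        rng.uniform(0.0, 0.01, n),
    )
    reported = rare | common
    # each reported variant appears in a random non-empty subset of panels
    in_panel = rng.random((n, len(PANELS))) < 0.7
    none = ~in_panel.any(axis=1)
    in_panel[none, rng.integers(0, len(PANELS), size=int(none.sum()))] = True
    for j, panel in enumerate(PANELS):
        col = np.where(reported & in_panel[:, j], freqs, np.nan)
        table[f"af_{panel}"] = col
    return table


def _assign_rsids(table: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    n = len(table)
    if n == 0:
        table["rsid"] = pd.Series(dtype=object)
        return table
    has_id = rng.random(n) < 0.6
    ids = np.where(
        has_id, [f"rs{rng.integers(10**6, 10**9)}" for _ in range(n)], ""
    )
    table["rsid"] = ids
    return table


def generate_cohort(
    config: SimulationConfig, genes: pd.DataFrame
) -> tuple[dict[str, set], dict[str, set], pd.DataFrame]:
    """Generate case and control carrier sets plus a joint annotation table.

    Returns ``(case_carriers, control_carriers, annotations)`` where the
    carrier mappings go from sample ID to the set of variant keys
    ``(chrom, pos, ref, alt)`` carried, and ``annotations`` has one row per
    distinct variant with gene, class, consequence, panel frequencies
    (NaN = unreported), scaled CADD score and a ``cohort`` column.
    """
    config.validate()
    if len(genes) == 0:
        raise ValueError("gene universe must be non-empty")
    case_ids = [f"CASE{i + 1:04d}" for i in range(config.n_cases)]
    ctrl_ids = [f"CTRL{i + 1:04d}" for i in range(config.n_controls)]

    case_counts, _ = simulate_gene_counts(config, genes, "cases")
    ctrl_counts, _ = simulate_gene_counts(config, genes, "controls")

    rng = _rng(config, 4)
    case_tab = _make_variants(config, genes, case_counts, case_ids, rng)
    ctrl_tab = _make_variants(config, genes, ctrl_counts, ctrl_ids, rng)
    case_tab["cohort"] = "cases"
    ctrl_tab["cohort"] = "controls"
    table = pd.concat([case_tab, ctrl_tab], ignore_index=True)
    # collisions across cohorts at identical sites are vanishingly rare but
    # would break key uniqueness; drop duplicates deterministically
    table = table.drop_duplicates(subset=["chrom", "pos", "ref", "alt"], keep="first")
    table = _attach_panel_freqs(table, config, rng)
    table = _assign_rsids(table, rng)

    def carriers_of(sub: pd.DataFrame) -> dict[str, set]:
        out: dict[str, set] = {}
        for row in sub.itertuples(index=False):
            key = (row.chrom, row.pos, row.ref, row.alt)
            out.setdefault(row.carrier, set()).add(key)
        return out

    case_carriers = {s: set() for s in case_ids}
    case_carriers.update(carriers_of(table[table["cohort"] == "cases"]))
    ctrl_carriers = {s: set() for s in ctrl_ids}
    ctrl_carriers.update(carriers_of(table[table["cohort"] == "controls"]))
    return case_carriers, ctrl_carriers, table


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def _chrom_sort_key(c: str):
    return (0, int(c)) if c.isdigit() else (1, c)


def _write_vcf(
    path: str,
    carriers: Mapping[str, Iterable[tuple]],
    annotations: pd.DataFrame,
    cohort: str,
) -> None:
    sub = annotations[annotations["cohort"] == cohort]
    samples = sorted(carriers)
    hom = {
        (r.chrom, r.pos, r.ref, r.alt)
        for r in sub.itertuples(index=False)
        if getattr(r, "homozygous", False)
    }
    carried_by: dict[tuple, list[str]] = {}
    for sample, keys in carriers.items():
        for key in keys:
            carried_by.setdefault(key, []).append(sample)
    rsid = {
        (r.chrom, r.pos, r.ref, r.alt): (r.rsid or ".")
        for r in sub.itertuples(index=False)
    }
    contigs = sorted({r.chrom for r in sub.itertuples(index=False)}, key=_chrom_sort_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rareburden-simulate\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        keys = sorted(rsid, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3]))
        for key in keys:
            chrom, pos, ref, alt = key
            gts = []
            carrying = set(carried_by.get(key, ()))
            gt_alt = "1/1" if key in hom else "0/1"
            for s in samples:
                gts.append(gt_alt if s in carrying else "0/0")
            fh.write(
                f"{chrom}\t{pos}\t{rsid[key]}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "rsid", "gene", "variant_class",
    "consequence", *[f"af_{p}" for p in PANELS], "cadd_scaled",
]


def write_fixture(
    case_carriers: Mapping[str, Iterable[tuple]],
    control_carriers: Mapping[str, Iterable[tuple]],
    annotations: pd.DataFrame,
    genes: pd.DataFrame,
    directory: str,
) -> dict[str, str]:
    """Write a generated cohort to ``directory`` as plain-text files.

    Emits ``cases.vcf`` and ``controls.vcf`` (merged multi-sample VCF 4.2),
    ``annotations.tsv`` and ``genes.tsv``.  The files round-trip losslessly
    through the readers in :mod:`rareburden.filtering`.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "cases_vcf": os.path.join(directory, "cases.vcf"),
        "controls_vcf": os.path.join(directory, "controls.vcf"),
        "annotations": os.path.join(directory, "annotations.tsv"),
        "genes": os.path.join(directory, "genes.tsv"),
    }
    _write_vcf(paths["cases_vcf"], case_carriers, annotations, "cases")
    _write_vcf(paths["controls_vcf"], control_carriers, annotations, "controls")
    ann = annotations.copy()
    for col in ANNOTATION_COLUMNS:
        if col not in ann.columns:
            ann[col] = np.nan
    ann[ANNOTATION_COLUMNS].to_csv(paths["annotations"], sep="\t", index=False)
    genes.to_csv(paths["genes"], sep="\t", index=False)
    return paths
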