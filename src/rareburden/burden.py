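"""Gene-level accumulation tests.

Two tests are applied to the filtered variant table:

* a CDS-length-normalized Poisson accumulation test -- under the null, the
  number of qualifying variant sites in gene *g* is Poisson with mean
  ``lambda_g = M * L_g / sum_j L_j`` where *M* is the total number of
  qualifying variants over the tested genes and *L_g* the CDS length; the
  per-gene p value is the upper tail ``P(X >= k_g)``, adjusted by
  Benjamini-Hochberg FDR (significant at q < 0.01 by default);

* a case-vs-control carrier accumulation test -- per gene, a Pearson
  chi-square test (1 df, no continuity correction) on the 2x2 table of
  carriers/non-carriers by case/control, again BH-adjusted (q < 0.05).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import ContingencyTable, pearson_chisq

__all__ = [
    "tabulate_gene_counts",
    "min_patient_filter",
    "poisson_burden_test",
    "bh_fdr",
    "case_control_accumulation_test",
]

logger = logging.getLogger(__name__)


def tabulate_gene_counts(
    table: pd.DataFrame, gene_annotations: pd.DataFrame
) -> pd.DataFrame:
    """Tabulate per-gene variant-site and patient counts.

    For each gene in the filtered variant ``table``: ``k`` = number of
    distinct qualifying variant sites, ``n_patients`` = number of distinct
    case samples carrying at least one of them, ``cds_length`` from the gene
    annotation.  Genes lacking a CDS length are excluded with a warning.
    """
    if len(table) == 0:
        return pd.DataFrame(columns=["gene", "k", "n_patients", "cds_length"])
    lengths = gene_annotations.set_index("symbol")["cds_length"]
    rows = []
    for gene, sub in table.groupby("gene", sort=True):
        keys = {(r.chrom, r.pos, r.ref, r.alt) for r in sub.itertuples(index=False)}
        patients: set = set()
        for c in sub["carriers"]:
            patients.update(c)
        rows.append({"gene": gene, "k": len(keys), "n_patients": len(patients)})
    out = pd.DataFrame(rows)
    out["cds_length"] = out["gene"].map(lengths)
    missing = out["cds_length"].isna()
    if missing.any():
        logger.warning(
            "excluding %d genes without CDS length: %s",
            missing.sum(), sorted(out.loc[missing, "gene"])[:5],
        )
        out = out[~missing]
    out["cds_length"] = out["cds_length"].astype(int)
    return out.reset_index(drop=True)


def min_patient_filter(counts: pd.DataFrame, min_patients: int = 2) -> pd.DataFrame:
    """Keep genes carried by at least ``min_patients`` distinct cases."""
    return counts[counts["n_patients"] >= min_patients].reset_index(drop=True)


def bh_fdr(pvalues: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (q values).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p values, capped at
    1, returned in the input order.  ``m`` defaults to ``len(pvalues)``; a
    larger ``m`` treats the input as a subset of a larger testing family.
    Ties are resolved by a stable sort so the result is deterministic.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = int(m) if m is not None else p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def poisson_burden_test(
    counts: pd.DataFrame, q_threshold: float = 0.01
) -> pd.DataFrame:
    """CDS-length-normalized Poisson accumulation test.

    ``lambda_g = M * L_g / sum_j L_j`` with ``M = sum_g k_g`` over the genes
    in ``counts`` (the normalization set); ``p_g = P(X >= k_g)`` for
    ``X ~ Poisson(lambda_g)``, i.e. the survival function at ``k_g - 1``.
    Returns the input augmented with ``lam``, ``p``, ``q`` (BH) and
    ``significant`` (q < ``q_threshold``), sorted by (p, gene).
    """
    if len(counts) == 0:
        out = counts.copy()
        for col in ("lam", "p", "q"):
            out[col] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    lengths = counts["cds_length"].to_numpy(dtype=float)
    total_length = lengths.sum()
    if total_length <= 0:
        raise ValueError("total CDS length of the normalization set is zero")
    k = counts["k"].to_numpy(dtype=int)
    M = int(k.sum())
    lam = M * lengths / total_length
    p = stats.poisson.sf(k - 1, lam)
    out = counts.copy()
    out["lam"] = lam
    out["p"] = p
    out["q"] = bh_fdr(p)
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)


def case_control_accumulation_test(
    carrier_counts: pd.DataFrame,
    n_cases: int,
    n_controls: int,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene case-vs-control carrier chi-square test.

    ``carrier_counts`` needs columns ``gene``, ``case_carriers`` and
    ``control_carriers``.  Each gene's 2x2 table (carriers / non-carriers by
    case / control) is tested with an uncorrected Pearson chi-square (1 df);
    genes with no carriers in either cohort get p = 1 by convention.  q values
    are BH over the tested genes, significant at q < ``q_threshold``.
    """
    if (carrier_counts["case_carriers"] > n_cases).any() or (
        carrier_counts["control_carriers"] > n_controls
    ).any():
        raise ValueError("carrier counts exceed cohort sizes")
    stats_, ps = [], []
    for row in carrier_counts.itertuples(index=False):
        t = ContingencyTable(
            a=int(row.case_carriers),
            b=n_cases - int(row.case_carriers),
            c=int(row.control_carriers),
            d=n_controls - int(row.control_carriers),
        )
        chi2, p = pearson_chisq(t, continuity=False)
        stats_.append(chi2)
        ps.append(p)
    out = carrier_counts.copy()
    out["case_noncarriers"] = n_cases - out["case_carriers"]
    out["control_noncarriers"] = n_controls - out["control_carriers"]
    out["chi2"] = stats_
    out["p"] = ps
    out["q"] = bh_fdr(np.asarray(ps))
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["p", "gene"], kind="stable").reset_index(drop=True)
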