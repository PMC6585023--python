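"""Packaged carrier-count fixtures for the association stage."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("rareburden.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_association_counts() -> pd.DataFrame:
    """Two-cohort carrier counts for the SHARPIN (rs572750141) and TYK2
    (rs531355933) candidate variants, as published for a staged LOAD
    case-control study (first cohort plus replication cohort).
    """
    return _load("association_counts.tsv")


def load_stage1_counts() -> pd.DataFrame:
    """Stage-1 genotyping carrier counts for 16 candidate variants.

    The seven rows with zero control carriers are transcribed from the
    published candidate table of a staged LOAD study; the nine variants that
    were observed in first-stage controls (and therefore dropped before their
    counts were published) are synthetic stand-ins with at least one control
    carrier, so the triage rule can be exercised end to end.
    """
    return _load("stage1_counts_synthetic.tsv")
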