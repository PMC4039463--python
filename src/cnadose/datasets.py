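"""Loaders for the cohort summary tables shipped with the package.

These are transcriptions of printed per-tumor summary tables from a
cervical-carcinoma copy-number/expression study: a burden-and-counts table
(31 tumors, 27 with expression data) and a clinical follow-up table (59
patients), plus the differential-expression set sizes for the high- versus
low-burden comparison. They drive the headline-statistic recomputations and
serve as realistic fixtures.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("cnadose").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """Per-tumor burden (%CN-AG) and dosage/expression cross-counts.

    Columns: tumor, pct_genome, genes_cn_altered, and the per-status counts
    cn1_n/cn1_ex, cn3_n/cn3_ex, cn13_n/cn13_ex, cn2_n/cn2_ex, all_ex.
    Tumors without expression data carry NaN in the count columns.
    """
    with resources.as_file(_data_path("table1_cn_expression.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_table2() -> pd.DataFrame:
    """Clinical follow-up table (sample, histology, stage, age, treatment,
    followup_months, status, analysis)."""
    with resources.as_file(_data_path("table2_clinical.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_exclusive_set_counts() -> dict:
    """Sizes of the SAM call sets for the high- and low-burden groups and the
    recurrence strata of the exclusive-high set."""
    with resources.as_file(_data_path("exclusive_set_counts.json")) as p:
        return json.loads(p.read_text())
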