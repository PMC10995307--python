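"""Bundled reference tables.

Two small published tables ship with the package as plain TSV data:

* ``phylum_herb_counts.tsv`` — co-occurrence counts of eight widely used
  herbs across eleven disease chapters (門) of a classified classical
  formulary; the canonical input for the r×c chi-square test of
  independence.
* ``rule_metric_rows.tsv`` — association-rule rows (itemset supports and
  the derived metrics, 3 decimals) for high-support and high-lift herb
  pairs mined from the same formulary; used to check that the metric
  formulas reproduce the published confidence/lift columns from the
  published supports.

A handful of rows — the honey↔licorice confidences and the
rhubarb↔skullcap lifts — are exactly reproducible at 3 decimals from the
printed supports and are flagged as ``spotlight`` rows; the remainder
agree within the rounding propagation of 3-decimal inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import ContingencyTable

__all__ = ["phylum_herb_counts", "rule_metric_rows", "spotlight_rule_rows"]

# (antecedents, consequents, metric) triples exactly reproducible at 3 dp.
SPOTLIGHT = [
    ("蜜", "甘草", "confidence"),
    ("甘草", "蜜", "confidence"),
    ("大黄", "黄芩", "lift"),
    ("黄芩", "大黄", "lift"),
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("herbmine.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t")


def phylum_herb_counts() -> ContingencyTable:
    """The 11 phyla × 8 herbs co-occurrence count matrix."""
    df = _read("phylum_herb_counts.tsv").set_index("phylum")
    return ContingencyTable.from_dataframe(df)


def rule_metric_rows() -> pd.DataFrame:
    """All bundled rule rows with their published supports and metrics."""
    return _read("rule_metric_rows.tsv")


def spotlight_rule_rows() -> pd.DataFrame:
    """The rows whose printed metric is exactly reproducible at 3 decimals."""
    df = rule_metric_rows()
    keys = {(a, c) for a, c, _m in SPOTLIGHT}
    mask = [
        (row.antecedents, row.consequents) in keys for row in df.itertuples()
    ]
    return df[mask].reset_index(drop=True)
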