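"""Contingency tables and independence tests for co-occurrence counts.

Two kinds of count tables arise in the pipeline:

* **phylum × herb** — how often each herb is tagged within each disease
  chapter (門) of a classified formulary; an r×c chi-square test of
  independence asks whether herb usage varies across chapters;
* **gene–herb literature counts** — 3×2 tables per (candidate herb,
  gene pair), rows = candidate herb / control herb (licorice) /
  positive-control preparation, columns = literature counts for the two
  genes.

The selection rule between tests follows sample size: chi-square when the
grand total exceeds a threshold (default 30), Fisher's exact test
otherwise (the boundary total of exactly 30 goes to Fisher, the
conservative choice).  The chi-square statistic is computed from first
principles (E_ij = row_i·col_j/N, Σ(O−E)²/E, no continuity correction,
dof=(r−1)(c−1)); Fisher's exact test generalizes to r×c via the
Freeman–Halton rule: enumerate every table with the observed margins and
sum the probabilities of tables no more probable than the observed one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .extraction import Transaction

__all__ = [
    "ContingencyTable",
    "IndependenceTestResult",
    "chi_square_independence",
    "fisher_exact",
    "choose_test",
    "build_phylum_herb_table",
    "build_gene_herb_tables",
    "log2_transform",
    "pubmed_query",
    "results_table",
    "table_report",
]


@dataclass
class ContingencyTable:
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ContingencyTable":
        return cls(list(map(str, df.index)), list(map(str, df.columns)),
                   df.to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ContingencyTable":
        """First column = row labels, header = column labels, integer cells."""
        return cls.from_dataframe(pd.read_csv(path, index_col=0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)

    def drop_zero_margins(self) -> "ContingencyTable":
        """Remove all-zero rows/columns (warned), as required before testing."""
        rows = self.counts.sum(axis=1) > 0
        cols = self.counts.sum(axis=0) > 0
        if not rows.all() or not cols.all():
            dropped = [l for l, keep in zip(self.row_labels, rows) if not keep]
            dropped += [l for l, keep in zip(self.col_labels, cols) if not keep]
            warnings.warn(f"dropping zero-margin rows/columns: {dropped}")
        return ContingencyTable(
            [l for l, k in zip(self.row_labels, rows) if k],
            [l for l, k in zip(self.col_labels, cols) if k],
            self.counts[np.ix_(rows, cols)],
        )


@dataclass
class IndependenceTestResult:
    method: str  # "chi_square" | "fisher_exact"
    p_value: float
    statistic: float | None = None
    dof: int | None = None

    @property
    def significant_001(self) -> bool:
        return self.p_value < 0.001

    @property
    def significant_005(self) -> bool:
        return self.p_value < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_value < 0.01

    @property
    def stars(self) -> str:
        """'**' below 0.01, '*' below 0.05, empty otherwise."""
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _check_margins(table: ContingencyTable) -> None:
    if table.total == 0:
        raise ValueError("contingency table is empty")
    if (table.counts.sum(axis=1) == 0).any() or (table.counts.sum(axis=0) == 0).any():
        raise ValueError(
            "table has a zero marginal row/column; drop it before testing "
            "(see ContingencyTable.drop_zero_margins)"
        )


def chi_square_independence(table: ContingencyTable) -> IndependenceTestResult:
    """Pearson chi-square test of independence on an r×c table.

    Expected counts below 5 are a known reliability concern for the
    asymptotic test; they are warned about but do not switch the method.
    """
    _check_margins(table)
    obs = table.counts.astype(float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected < 5).any():
        warnings.warn(
            f"{int((expected < 5).sum())} expected counts below 5; "
            "the asymptotic chi-square p-value may be unreliable"
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return IndependenceTestResult(
        "chi_square", float(chi2.sf(stat, dof)), stat, dof
    )


def _log_table_prob(counts: np.ndarray, lg_margins: float, lg_n: float) -> float:
    return lg_margins - lg_n - float(gammaln(counts + 1).sum())


def fisher_exact(
    table: ContingencyTable, max_tables: int = 2_000_000
) -> IndependenceTestResult:
    """Exact test on an r×c table by Freeman–Halton enumeration.

    Under fixed margins the table probability is the multivariate
    hypergeometric mass; the two-sided p-value sums the probabilities of
    all margin-preserving tables whose probability does not exceed the
    observed table's (with a small relative tolerance for float ties).
    For 2×2 tables this reduces to the usual two-sided Fisher test.
    Enumeration beyond *max_tables* raises, pointing to chi-square.
    """
    _check_margins(table)
    counts = table.counts.astype(np.int64)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = int(counts.sum())
    lg_margins = float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum())
    lg_n = float(gammaln(n + 1))
    logp_obs = _log_table_prob(counts, lg_margins, lg_n)
    cutoff = logp_obs + 1e-7

    r, c = counts.shape
    total_p = 0.0
    seen = 0

    # DFS over tables row by row; within a row, cell by cell with
    # feasibility bounds from the remaining row and column totals.
    def rec_row(i: int, remaining_cols: np.ndarray, acc_lgf: float) -> None:
        nonlocal total_p, seen
        if i == r - 1:
            # last row forced by column margins
            last = remaining_cols
            lgp = lg_margins - lg_n - acc_lgf - float(gammaln(last + 1).sum())
            seen += 1
            if seen > max_tables:
                raise ValueError(
                    "table too large for exact enumeration; use chi-square"
                )
            if lgp <= cutoff:
                total_p += math.exp(lgp)
            return

        row_total = int(rows[i])
        cells = np.zeros(c, dtype=np.int64)

        def rec_cell(j: int, left: int, lgf: float) -> None:
            if j == c - 1:
                if left > remaining_cols[c - 1]:
                    return
                cells[c - 1] = left
                rec_row(
                    i + 1,
                    remaining_cols - cells,
                    acc_lgf + lgf + float(gammaln(left + 1)),
                )
                return
            hi = min(left, int(remaining_cols[j]))
            for v in range(hi + 1):
                cells[j] = v
                rec_cell(j + 1, left - v, lgf + float(gammaln(v + 1)))
            cells[j] = 0

        rec_cell(0, row_total, 0.0)

    rec_row(0, cols.copy(), 0.0)
    return IndependenceTestResult("fisher_exact", min(total_p, 1.0))


def choose_test(
    table: ContingencyTable, sample_threshold: int = 30, **fisher_kwargs
) -> IndependenceTestResult:
    """Chi-square when the grand total exceeds *sample_threshold*, else
    Fisher's exact test (a total of exactly the threshold goes to Fisher)."""
    if table.total > sample_threshold:
        return chi_square_independence(table)
    return fisher_exact(table, **fisher_kwargs)


def build_phylum_herb_table(
    transactions: Iterable[Transaction], herbs: Sequence[str]
) -> ContingencyTable:
    """counts[p][h] = number of transactions in phylum p containing herb h."""
    if not herbs:
        raise ValueError("herb list must be non-empty")
    txs = [t for t in transactions if t.phylum]
    vocab = set().union(*(t.items for t in txs)) if txs else set()
    unknown = [h for h in herbs if h not in vocab]
    if unknown:
        raise ValueError(f"herbs never observed in any transaction: {unknown}")
    phyla = sorted({t.phylum for t in txs})
    counts = np.zeros((len(phyla), len(herbs)), dtype=np.int64)
    index = {p: i for i, p in enumerate(phyla)}
    for t in txs:
        for j, h in enumerate(herbs):
            if h in t.items:
                counts[index[t.phylum], j] += 1
    return ContingencyTable(list(phyla), list(herbs), counts)


def build_gene_herb_tables(
    counts: pd.DataFrame,
    control_herb: str,
    positive_control: str,
    candidates: Sequence[str] | None = None,
    gene_pairs: Sequence[tuple[str, str]] | None = None,
) -> list[tuple[str, str, str, ContingencyTable]]:
    """3×2 tables from a herb × gene literature-count matrix.

    Rows: candidate herb, control herb, positive-control preparation;
    columns: literature counts for each gene of the pair.  One table per
    (candidate, gene pair).
    """
    if control_herb == positive_control:
        raise ValueError("control and positive control must differ")
    for ctrl in (control_herb, positive_control):
        if ctrl not in counts.index:
            raise ValueError(f"control row {ctrl!r} missing from counts")
    if candidates is None:
        candidates = [
            h for h in counts.index if h not in (control_herb, positive_control)
        ]
    else:
        for h in candidates:
            if h in (control_herb, positive_control):
                raise ValueError(f"candidate {h!r} duplicates a control row")
            if h not in counts.index:
                raise ValueError(f"candidate row {h!r} missing from counts")
    if gene_pairs is None:
        gene_pairs = list(combinations(counts.columns, 2))
    out = []
    for herb in candidates:
        for g1, g2 in gene_pairs:
            sub = counts.loc[[herb, control_herb, positive_control], [g1, g2]]
            out.append((herb, g1, g2, ContingencyTable.from_dataframe(sub)))
    return out


def log2_transform(counts: np.ndarray | pd.DataFrame):
    """Heat-map transform: elementwise log2(count + 1); 0 maps to 0."""
    values = counts.to_numpy() if isinstance(counts, pd.DataFrame) else np.asarray(counts)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    transformed = np.log2(values + 1.0)
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(transformed, index=counts.index, columns=counts.columns)
    return transformed


def pubmed_query(herb_name: str, gene_symbol: str) -> str:
    """Cross-search query string: herb English/Latin name AND gene symbol."""
    return f'("{herb_name}") AND ("{gene_symbol}")'


def results_table(
    tested: Sequence[tuple[str, str, str, IndependenceTestResult]],
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Result rows (Herbs, Gene_1, Gene_2, p-value, method flags, stars).

    No multiple-testing correction by default; ``bh_correction=True`` adds
    a Benjamini–Hochberg adjusted column.
    """
    df = pd.DataFrame(
        [
            {
                "Herbs": herb,
                "Gene_1": g1,
                "Gene_2": g2,
                "p-value": res.p_value,
                "Chi-square": "T" if res.method == "chi_square" else "F",
                "Fisher's exact test": "T" if res.method == "fisher_exact" else "F",
                "Significant": res.stars,
            }
            for herb, g1, g2, res in tested
        ]
    )
    if bh_correction and len(df):
        from statsmodels.stats.multitest import multipletests

        df["p-adjusted (BH)"] = multipletests(df["p-value"], method="fdr_bh")[1]
    return df.sort_values("p-value", kind="stable").reset_index(drop=True)


def table_report(table: ContingencyTable, result: IndependenceTestResult) -> str:
    """Human-readable report with the statistic/p-value/dof footer lines."""
    lines = [table.to_dataframe().to_string(), ""]
    if result.statistic is not None:
        lines.append(f"Statistic: {result.statistic!r}.")
    lines.append(f"p-value: {result.p_value!r}.")
    if result.dof is not None:
        lines.append(f"Degree of freedom: {result.dof}.")
    lines.append(f"p-value <0.001: {result.significant_001}.")
    return "\n".join(lines)
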