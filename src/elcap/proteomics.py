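"""IP-MS enrichment statistics for protein-group quantitation tables.

The workflow mirrors a Perseus-style volcano analysis of MaxQuant output:
load the protein-group table (zeros are missing), require a combined peptide
count strictly greater than a threshold, log2-transform, impute missing
values from a down-shifted per-column Gaussian, run a two-sample Student
t-test with injections as observations, and call a protein enriched when
log2 difference > 2 AND −log2 p > 2 (both strict). Note the −log2 scale:
a threshold of 2 means p < 0.25 combined with a > 4-fold intensity change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ColumnMap:
    """Maps table columns to their roles.

    ``intensity_columns`` maps a column name to its (condition, replicate,
    injection) triple; ``peptide_columns`` lists per-replicate peptide-count
    columns summed for the combined-count filter.
    """

    id_column: str = "Protein IDs"
    gene_column: Optional[str] = "Gene names"
    peptide_columns: Sequence[str] = ("Peptides r1", "Peptides r2")
    intensity_columns: Mapping[str, tuple[str, int, int]] = field(default_factory=dict)
    reverse_column: Optional[str] = "Reverse"
    contaminant_column: Optional[str] = "Potential contaminant"


@dataclass
class ProteinQuantTable:
    """Protein-group quantities: identifiers, peptide counts, intensities.

    ``intensities`` holds linear-scale values with 0 meaning missing;
    ``log2`` (after imputation) holds complete log2 matrices plus an
    ``imputed`` mask.
    """

    ids: pd.Series
    genes: Optional[pd.Series]
    peptides: pd.DataFrame
    intensities: pd.DataFrame
    column_map: ColumnMap
    log2: Optional[pd.DataFrame] = None
    imputed: Optional[pd.DataFrame] = None

    def __len__(self) -> int:
        return len(self.ids)

    def condition_columns(self, condition: str) -> list[str]:
        return [
            c for c, (cond, _, _) in self.column_map.intensity_columns.items()
            if cond == condition
        ]


def default_column_map(
    columns: Sequence[str], groups: Sequence[str] = ("IP", "control")
) -> ColumnMap:
    """Infer the mapping for tables written by the synthetic generator.

    Intensity columns look like ``LFQ intensity <group>_r<rep>_i<inj>``.
    """
    intensity: dict[str, tuple[str, int, int]] = {}
    peptide = []
    for col in columns:
        if col.startswith("LFQ intensity "):
            label = col[len("LFQ intensity "):]
            group, rep, inj = label.rsplit("_", 2)
            intensity[col] = (group, int(rep[1:]), int(inj[1:]))
        elif col.startswith("Peptides"):
            peptide.append(col)
    return ColumnMap(
        peptide_columns=tuple(peptide), intensity_columns=intensity
    )


def load_protein_groups(
    table: Union[str, IO[str], pd.DataFrame],
    column_map: Optional[ColumnMap] = None,
) -> ProteinQuantTable:
    """Read a protein-group TSV; drop reverse/contaminant-flagged rows.

    Zeros in intensity columns are recorded as missing (NaN) internally.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t")
    if column_map is None:
        column_map = default_column_map(df.columns)
    needed = [column_map.id_column, *column_map.peptide_columns,
              *column_map.intensity_columns]
    for col in needed:
        if col not in df.columns:
            raise KeyError(f"mapped column {col!r} missing from table")
    for flag_col in (column_map.reverse_column, column_map.contaminant_column):
        if flag_col and flag_col in df.columns:
            flags = df[flag_col].fillna("").astype(str).str.strip()
            df = df[flags != "+"]
    df = df.reset_index(drop=True)
    intensities = df[list(column_map.intensity_columns)].astype(float)
    intensities = intensities.where(intensities > 0, np.nan)
    genes = (
        df[column_map.gene_column]
        if column_map.gene_column and column_map.gene_column in df.columns
        else None
    )
    return ProteinQuantTable(
        ids=df[column_map.id_column],
        genes=genes,
        peptides=df[list(column_map.peptide_columns)].astype(int),
        intensities=intensities,
        column_map=column_map,
    )


def filter_min_peptides(
    table: ProteinQuantTable, min_combined: int = 3
) -> ProteinQuantTable:
    """Keep proteins with summed peptide count STRICTLY greater than the cutoff."""
    keep = table.peptides.sum(axis=1) > min_combined
    idx = keep[keep].index
    return ProteinQuantTable(
        ids=table.ids.loc[idx].reset_index(drop=True),
        genes=None if table.genes is None else table.genes.loc[idx].reset_index(drop=True),
        peptides=table.peptides.loc[idx].reset_index(drop=True),
        intensities=table.intensities.loc[idx].reset_index(drop=True),
        column_map=table.column_map,
    )


def impute_log_intensities(
    table: ProteinQuantTable,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int = 0,
) -> ProteinQuantTable:
    """Log2-transform and fill missing values from a down-shifted Gaussian.

    Per intensity column: missing cells are drawn from
    N(column mean − shift·column sd, (width·column sd)²), the conventional
    left-censoring model for label-free data where absence usually means
    below detection. Deterministic given ``seed``; imputed cells are flagged.
    """
    rng = np.random.default_rng(seed)
    log2 = np.log2(table.intensities)
    imputed = log2.isna()
    filled = log2.copy()
    for col in log2.columns:
        observed = log2[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} has no observed values to impute from")
        n_missing = int(imputed[col].sum())
        if n_missing:
            mu = observed.mean() - shift * observed.std(ddof=1)
            sd = width * observed.std(ddof=1)
            filled.loc[imputed[col], col] = rng.normal(mu, sd, size=n_missing)
    table.log2 = filled
    table.imputed = imputed
    return table


def enrichment_test(
    table: ProteinQuantTable,
    test_condition: str = "IP",
    control_condition: str = "control",
    equal_var: bool = True,
    replicate_means: bool = False,
) -> pd.DataFrame:
    """Per-protein two-sided two-sample t-test on log2 intensities.

    Injections are the observations by default (Student equal-variance, the
    Perseus default; Welch by ``equal_var=False``); ``replicate_means``
    collapses injections to biological-replicate means first for a
    sensitivity analysis. Returns a DataFrame with ``protein_id``,
    ``log2_diff`` (test − control), ``neg_log2_p`` and a degenerate-variance
    flag. Zero pooled variance: equal means → p = 1; unequal → smallest
    positive float (flagged).
    """
    if table.log2 is None:
        raise ValueError("run impute_log_intensities before enrichment_test")
    test_cols = table.condition_columns(test_condition)
    ctrl_cols = table.condition_columns(control_condition)
    if len(test_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least 2 observations per side")

    def side_matrix(cols: list[str]) -> np.ndarray:
        if not replicate_means:
            return table.log2[cols].to_numpy()
        reps: dict[int, list[str]] = {}
        for c in cols:
            reps.setdefault(table.column_map.intensity_columns[c][1], []).append(c)
        return np.column_stack(
            [table.log2[cs].to_numpy().mean(axis=1) for _, cs in sorted(reps.items())]
        )

    x = side_matrix(test_cols)
    y = side_matrix(ctrl_cols)
    diff = x.mean(axis=1) - y.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(x, y, axis=1, equal_var=equal_var)
        pvals = np.asarray(res.pvalue, dtype=float)
    var_zero = (x.var(axis=1) == 0) & (y.var(axis=1) == 0)
    degenerate = var_zero.copy()
    pvals = np.where(var_zero & (diff == 0), 1.0, pvals)
    pvals = np.where(var_zero & (diff != 0), np.finfo(float).tiny, pvals)
    return pd.DataFrame(
        {
            "protein_id": table.ids.to_numpy(),
            "log2_diff": diff,
            "neg_log2_p": -np.log2(pvals),
            "p_value": pvals,
            "degenerate_variance": degenerate,
        }
    )


def classify_enriched(
    results: pd.DataFrame, fc_threshold: float = 2.0, p_threshold: float = 2.0
) -> pd.DataFrame:
    """Flag proteins with log2_diff > fc AND −log2 p > p (strict inequalities)."""
    out = results.copy()
    out["enriched"] = (out["log2_diff"] > fc_threshold) & (
        out["neg_log2_p"] > p_threshold
    )
    return out


def compare_to_reference(
    double_ip_results: pd.DataFrame,
    reference_results: pd.DataFrame,
    fc_threshold: float = 2.0,
    p_threshold: float = 2.0,
) -> pd.DataFrame:
    """Join double-IP results onto the reference single-IP enriched set.

    Only proteins enriched in the reference (single RNAPII IP) are kept; each
    is reported with its double-IP log2 difference alongside the reference
    value. Proteins absent from the double-IP table are reported with missing
    double-IP values, not silently dropped.
    """
    ref = classify_enriched(reference_results, fc_threshold, p_threshold)
    ref_enriched = ref[ref["enriched"]]
    if ref_enriched.empty:
        raise ValueError("reference set contains no enriched proteins")
    joined = ref_enriched[["protein_id", "log2_diff", "neg_log2_p"]].rename(
        columns={"log2_diff": "ref_log2_diff", "neg_log2_p": "ref_neg_log2_p"}
    ).merge(
        double_ip_results[["protein_id", "log2_diff", "neg_log2_p"]].rename(
            columns={"log2_diff": "double_log2_diff", "neg_log2_p": "double_neg_log2_p"}
        ),
        on="protein_id",
        how="left",
    )
    return joined
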