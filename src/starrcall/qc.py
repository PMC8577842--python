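"""Count normalization, inclusion filters, and replicate QC correlations.

Raw de-duplicated amplicon counts are converted to pseudocounted proportions
per sample: p = (c + 1) / (total + 1), the pseudocount added once to the
numerator and once to the sample total so no amplicon divides by zero.
Proportions therefore need not sum exactly to 1.

Amplicons then pass two independent exclusion rules before activity analysis:
a minimum raw count in every DNA sample (default 200) and a minimum mean DNA
proportion (default 2^-15).  An amplicon is removed if either rule fires; the
exclusion log records which.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class QCError(ValueError):
    pass


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.size == 0:
        raise QCError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise QCError("counts must be non-negative")
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise QCError("amplicon and sample ids must be unique")


def validate_samples(samples: pd.DataFrame, counts: pd.DataFrame | None = None) -> None:
    required = {"sample_id", "kind", "replicate"}
    if not required <= set(samples.columns):
        raise QCError(f"sample sheet needs columns {sorted(required)}")
    bad = set(samples["kind"]) - {"library", "DNA", "RNA"}
    if bad:
        raise QCError(f"unknown sample kinds: {sorted(bad)}")
    if counts is not None:
        sheet = set(samples["sample_id"])
        cols = set(counts.columns)
        if sheet != cols:
            raise QCError(
                "sample sheet and count matrix disagree: "
                f"only in sheet {sorted(sheet - cols)}, only in counts {sorted(cols - sheet)}"
            )


def biological(samples: pd.DataFrame, kind: str | None = None) -> pd.DataFrame:
    """Biological (non-technical) samples, optionally restricted to one kind."""
    tech = samples.get("technical_of")
    if tech is None:
        out = samples
    else:
        out = samples[tech.isna() | (tech.astype(str) == "")]
    if kind is not None:
        out = out[out["kind"] == kind]
    return out


def compute_proportions(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Pseudocounted proportions: (c + k) / (column total + k), k = 1 by default."""
    validate_counts(counts)
    totals = counts.sum(axis=0)
    return (counts + pseudocount) / (totals + pseudocount)


def filter_amplicons(
    counts: pd.DataFrame,
    proportions: pd.DataFrame,
    samples: pd.DataFrame,
    min_dna_count: int = 200,
    min_lib_proportion: float = 2.0 ** -15,
) -> tuple[pd.Index, pd.DataFrame]:
    """Apply the two library-QC exclusion rules.

    An amplicon is removed iff its minimum raw count across DNA samples is
    below ``min_dna_count`` OR its mean proportion across DNA samples is below
    ``min_lib_proportion``.  Returns the retained index and an exclusion log
    (amplicon_id, rule, value) with one row per fired rule.
    """
    validate_samples(samples, counts)
    dna = biological(samples, "DNA")["sample_id"].tolist()
    if not dna:
        raise QCError("no DNA samples in sample sheet")
    min_count = counts[dna].min(axis=1)
    mean_prop = proportions[dna].mean(axis=1)

    low_count = min_count < min_dna_count
    low_prop = mean_prop < min_lib_proportion
    log_rows = []
    for aid in counts.index[low_count]:
        log_rows.append((aid, "min_dna_count", float(min_count[aid])))
    for aid in counts.index[low_prop]:
        log_rows.append((aid, "min_lib_proportion", float(mean_prop[aid])))
    exclusion_log = pd.DataFrame(
        log_rows, columns=["amplicon_id", "rule", "value"]
    ).sort_values(["amplicon_id", "rule"], kind="mergesort").reset_index(drop=True)
    retained = counts.index[~(low_count | low_prop)]
    return retained, exclusion_log


def pairwise_correlation(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson r and its two-sided p (t transform).

    Used for replicate-replicate, GC-representation, and ortholog comparisons.
    Raises on constant input, where the correlation is undefined.
    """
    if method != "pearson":
        raise ValueError("only the pearson method is supported")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise QCError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise QCError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_matrix(proportions: pd.DataFrame, log2: bool = True) -> pd.DataFrame:
    """All pairwise sample correlations of (log2) proportions, for QC reports."""
    mat = np.log2(proportions) if log2 else proportions
    return mat.corr(method="pearson")
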