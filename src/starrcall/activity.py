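"""The two MPRA activity models and their significance machinery.

Background-regression model
    Mean per-amplicon RNA and DNA proportions are computed across biological
    replicates (technical replicates excluded).  The middle 80% of amplicons
    ranked by ratiometric activity train an OLS model

        log2(mean RNA proportion) ~ log2(mean DNA proportion) + GC

    which absorbs basal transcription from the minimal promoter and residual
    GC bias.  The model is applied to every retained amplicon; residuals are
    Z-scaled over the full scored set and one-tailed p-values taken from the
    upper standard-normal tail (activity means *more* RNA than background
    predicts; low residuals are reported but never called).  q-values come
    from an empirical tail-area FDR with a half-normal empirical null fitted
    by mirroring the non-positive Z scores.

Ratiometric model
    Per replicate, the RNA/DNA ratio of proportions computed after adding a
    stabilizer (1000 counts) to every raw count; an amplicon is called active
    when the replicate mean ratio exceeds 1.5 and the replicate standard
    deviation is below the mean.

Supporting tests: exact (midrank-enumeration) one-tailed Wilcoxon rank-sum of
DNA vs RNA proportions, Benjamini-Hochberg adjustment, one-way ANOVA across
amplicon groups, and one-tailed Fisher 2x2 tests of enhancer-ascertainment
enrichment among calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import AmpliconCatalog
from .qc import QCError, biological, compute_proportions


class DegenerateDesignError(ValueError):
    """Raised when a regression design matrix is rank-deficient."""


# ---------------------------------------------------------------------------
# ratiometric model
# ---------------------------------------------------------------------------

def paired_replicates(samples: pd.DataFrame) -> list[int]:
    """Replicate ids present in both biological DNA and RNA samples."""
    dna = set(biological(samples, "DNA")["replicate"])
    rna = set(biological(samples, "RNA")["replicate"])
    return sorted(dna & rna)


def mean_proportions(proportions: pd.DataFrame, samples: pd.DataFrame, kind: str) -> pd.Series:
    """Mean proportion per amplicon over biological samples of one kind."""
    cols = biological(samples, kind)["sample_id"].tolist()
    if not cols:
        raise QCError(f"no biological {kind} samples")
    return proportions[cols].mean(axis=1)


def ratiometric_summary(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    stabilizer: float = 1000.0,
    ratio_threshold: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate stabilized RNA/DNA ratios and their per-amplicon summary.

    The stabilizer is added to the raw counts before proportion conversion,
    damping ratios where counts are low.  Technical replicates are excluded;
    DNA and RNA samples are paired by replicate id.

    Returns ``(ratios, summary)``: ratios has one column per replicate;
    summary has ratio_mean, ratio_sd (sample sd across replicates, 0 when only
    one replicate) and the call ``ratio_mean > ratio_threshold and
    ratio_sd < ratio_mean``.
    """
    reps = paired_replicates(samples)
    if not reps:
        raise QCError("no paired DNA/RNA replicates")
    stab = compute_proportions(counts, pseudocount=stabilizer)
    bio = biological(samples)
    ratios = pd.DataFrame(index=counts.index)
    for r in reps:
        dna_col = bio[(bio["kind"] == "DNA") & (bio["replicate"] == r)]["sample_id"].iloc[0]
        rna_col = bio[(bio["kind"] == "RNA") & (bio["replicate"] == r)]["sample_id"].iloc[0]
        ratios[f"rep{r}"] = stab[rna_col] / stab[dna_col]
    mean = ratios.mean(axis=1)
    sd = ratios.std(axis=1, ddof=1).fillna(0.0) if len(reps) > 1 else pd.Series(0.0, index=ratios.index)
    summary = pd.DataFrame(
        {
            "ratio_mean": mean,
            "ratio_sd": sd,
            "ratiometric_call": (mean > ratio_threshold) & (sd < mean),
        }
    )
    return ratios, summary


def select_training_set(
    ratio_mean: pd.Series, trim_fraction: float = 0.10
) -> pd.Index:
    """Middle (1 - 2*trim_fraction) of amplicons ranked by mean ratiometric activity.

    ``floor(trim_fraction * n)`` amplicons are removed from each extreme; ties
    broken by amplicon id for determinism.
    """
    n = len(ratio_mean)
    if n < 10:
        raise ValueError("need at least 10 amplicons to trim")
    k = math.floor(trim_fraction * n)
    order = ratio_mean.sort_index().sort_values(kind="mergesort").index
    keep = order[k : n - k] if k else order
    return pd.Index(sorted(keep))


# ---------------------------------------------------------------------------
# background-regression model
# ---------------------------------------------------------------------------

@dataclass
class BackgroundModelFit:
    """OLS fit of log2 mean RNA on log2 mean DNA + GC over the training set."""

    intercept: float
    slope_dna: float
    coeff_gc: float
    residual_sd: float
    training_ids: pd.Index
    ks_stat: float
    ks_p: float

    def predict(self, log2_dna: np.ndarray, gc: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope_dna * np.asarray(log2_dna) + self.coeff_gc * np.asarray(gc)

    def to_text(self) -> str:
        lines = [
            f"intercept\t{self.intercept!r}",
            f"slope_dna\t{self.slope_dna!r}",
            f"coeff_gc\t{self.coeff_gc!r}",
            f"residual_sd\t{self.residual_sd!r}",
            f"ks_stat\t{self.ks_stat!r}",
            f"ks_p\t{self.ks_p!r}",
            f"n_training\t{len(self.training_ids)}",
        ]
        return "\n".join(lines) + "\n"


def fit_background_model(
    activity: pd.DataFrame, catalog: AmpliconCatalog, training_ids: Iterable[str]
) -> BackgroundModelFit:
    """Fit the background model on the trimmed training set.

    ``activity`` must be indexed by amplicon_id with columns mean_dna_prop and
    mean_rna_prop.  The residual-normality Kolmogorov-Smirnov diagnostic is
    computed on standardized training residuals.
    """
    import statsmodels.api as sm

    ids = pd.Index(training_ids)
    sub = activity.loc[ids]
    gc = catalog.gc().loc[ids].to_numpy()
    x = np.log2(sub["mean_dna_prop"].to_numpy())
    y = np.log2(sub["mean_rna_prop"].to_numpy())
    X = np.column_stack([np.ones_like(x), x, gc])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateDesignError("constant or collinear predictors in training set")
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    sd = float(np.std(resid, ddof=X.shape[1]))
    std_resid = (resid - resid.mean()) / np.std(resid, ddof=1)
    ks_stat, ks_p = stats.kstest(std_resid, "norm")
    return BackgroundModelFit(
        intercept=float(fit.params[0]),
        slope_dna=float(fit.params[1]),
        coeff_gc=float(fit.params[2]),
        residual_sd=sd,
        training_ids=ids,
        ks_stat=float(ks_stat),
        ks_p=float(ks_p),
    )


def score_activity(
    fit: BackgroundModelFit, activity: pd.DataFrame, catalog: AmpliconCatalog
) -> pd.DataFrame:
    """Apply the background model to every retained amplicon.

    residual = observed - predicted log2 RNA proportion; z = residual Z-scaled
    over the full scored set; p_model = upper-tail standard-normal probability.
    """
    gc = catalog.gc().loc[activity.index].to_numpy()
    log2_dna = np.log2(activity["mean_dna_prop"].to_numpy())
    log2_rna = np.log2(activity["mean_rna_prop"].to_numpy())
    resid = log2_rna - fit.predict(log2_dna, gc)
    z = (resid - resid.mean()) / resid.std(ddof=1)
    return pd.DataFrame(
        {"residual": resid, "z": z, "p_model": stats.norm.sf(z)}, index=activity.index
    )


def empirical_fdr(z, pi0: float = 1.0) -> np.ndarray:
    """Empirical tail-area FDR q-values from one-tailed Z scores.

    The null is a half-normal fitted by mirroring the non-positive scores
    (scale = root mean square of the mirrored set);

        q(z_i) = pi0 * n * S_null(z_i) / #{j : z_j >= z_i}

    capped at 1 with monotone non-increasing enforcement in z.  ``pi0``
    defaults to 1, the conservative choice.
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    if n < 20:
        raise ValueError("need at least 20 z-scores for an empirical null")
    neg = z[z <= 0]
    if len(neg) >= 2:
        sigma = math.sqrt(float(np.mean(neg ** 2)))
    else:  # pathologically one-sided input: fall back to the full rms
        sigma = math.sqrt(float(np.mean(z ** 2)))
    if sigma == 0:
        sigma = 1.0
    s_null = stats.norm.sf(z / sigma)
    z_sorted = np.sort(z)
    rank_ge = n - np.searchsorted(z_sorted, z, side="left")
    raw = np.minimum(1.0, pi0 * n * s_null / rank_ge)
    # q(z) = min over z' <= z of raw(z'): non-increasing in z
    order = np.argsort(z, kind="mergesort")
    q = np.empty(n)
    q[order] = np.minimum.accumulate(raw[order])
    return q


# ---------------------------------------------------------------------------
# rank-based and categorical tests
# ---------------------------------------------------------------------------

class WilcoxonResult(NamedTuple):
    p_value: float
    shift_lower_bound: float

    @property
    def shift_positive(self) -> bool:
        return self.shift_lower_bound > 0


def _exact_rank_sum_p(dna: np.ndarray, rna: np.ndarray) -> float:
    """P(rank sum of RNA >= observed) by enumeration with midranks for ties."""
    combined = np.concatenate([dna, rna])
    ranks = stats.rankdata(combined)
    n_rna = len(rna)
    obs = ranks[len(dna):].sum()
    total = 0
    hits = 0
    for idx in combinations(range(len(combined)), n_rna):
        total += 1
        if ranks[list(idx)].sum() >= obs - 1e-9:
            hits += 1
    return hits / total


def _shift_lower_bound(dna: np.ndarray, rna: np.ndarray, alpha: float = 0.05) -> float:
    """One-sided (1 - alpha) lower confidence bound for the RNA - DNA shift.

    Hodges-Lehmann construction: the (c+1)-th smallest of all pairwise
    differences, c the largest integer with P(U <= c) <= alpha under the exact
    (small samples) or normal-approximate Mann-Whitney null.
    """
    m, n = len(dna), len(rna)
    diffs = np.sort((rna[:, None] - dna[None, :]).ravel())
    mn = m * n
    if m + n <= 12:
        u_counts = np.zeros(mn + 1)
        for idx in combinations(range(m + n), n):
            u = sum(idx) - n * (n - 1) // 2  # Mann-Whitney U of that assignment
            u_counts[u] += 1
        cdf = np.cumsum(u_counts) / u_counts.sum()
        below = np.nonzero(cdf <= alpha)[0]
        c = int(below[-1]) if len(below) else -1
    else:
        mean = mn / 2.0
        sd = math.sqrt(mn * (m + n + 1) / 12.0)
        c = int(math.floor(mean + stats.norm.ppf(alpha) * sd - 0.5))
    if c < 0:
        return -math.inf
    return float(diffs[c])


def wilcoxon_rank_sum(
    dna_props, rna_props, alternative: str = "greater", alpha: float = 0.05
) -> WilcoxonResult:
    """One-tailed Wilcoxon rank-sum of RNA vs DNA proportions.

    Exact enumeration of the rank-sum null (midranks for ties) when the
    combined sample size is at most 12; otherwise the normal approximation
    with continuity and tie correction.  Also reports the one-sided
    Hodges-Lehmann lower confidence bound for the location shift, whose
    positivity is the "confidence interval greater than 0" call criterion.
    """
    dna = np.asarray(dna_props, dtype=float)
    rna = np.asarray(rna_props, dtype=float)
    if len(dna) < 2 or len(rna) < 2:
        raise ValueError("need at least two values per group")
    if alternative != "greater":
        raise ValueError("only the 'greater' (RNA above DNA) alternative is supported")
    if len(dna) + len(rna) <= 12:
        p = _exact_rank_sum_p(dna, rna)
    else:
        _, p = stats.mannwhitneyu(rna, dna, alternative="greater", method="asymptotic")
    return WilcoxonResult(float(p), _shift_lower_bound(dna, rna, alpha))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def anova_groups(activity_values, group_labels) -> tuple[float, float]:
    """One-way ANOVA of activity across amplicon groups."""
    values = np.asarray(activity_values, dtype=float)
    labels = np.asarray(group_labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups each with >= 2 members")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def fisher_2x2(
    a: int, b: int, c: int, d: int, alternative: str = "greater"
) -> tuple[float, float]:
    """Sample odds ratio (a*d)/(b*c) and one-tailed hypergeometric p.

    The table is [[a, b], [c, d]] with `a` = called-and-ascertained in the
    enrichment use.  A zero b*c margin yields an infinite odds ratio with a
    valid p.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return odds, float(p)


# ---------------------------------------------------------------------------
# assembled activity table
# ---------------------------------------------------------------------------

ACTIVITY_COLUMNS = [
    "amplicon_id",
    "group",
    "mean_dna_prop",
    "mean_rna_prop",
    "ratio_mean",
    "ratio_sd",
    "ratiometric_call",
    "residual",
    "z",
    "p_model",
    "q_model",
    "p_wilcoxon",
    "q_bh",
]


def activity_table(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    catalog: AmpliconCatalog,
    retained: pd.Index | None = None,
    stabilizer: float = 1000.0,
    trim_fraction: float = 0.10,
    ratio_threshold: float = 1.5,
) -> tuple[pd.DataFrame, BackgroundModelFit]:
    """Run both activity models end to end on retained amplicons.

    Returns the per-amplicon activity table (stable column order
    ``ACTIVITY_COLUMNS``) and the background-model fit.
    """
    if retained is None:
        retained = counts.index
    counts = counts.loc[retained]
    proportions = compute_proportions(counts)
    act = pd.DataFrame(
        {
            "mean_dna_prop": mean_proportions(proportions, samples, "DNA"),
            "mean_rna_prop": mean_proportions(proportions, samples, "RNA"),
        }
    )
    _, ratio_summary = ratiometric_summary(counts, samples, stabilizer, ratio_threshold)
    training = select_training_set(ratio_summary["ratio_mean"], trim_fraction)
    fit = fit_background_model(act, catalog, training)
    scores = score_activity(fit, act, catalog)
    scores["q_model"] = empirical_fdr(scores["z"].to_numpy())

    bio = biological(samples)
    dna_cols = bio[bio["kind"] == "DNA"]["sample_id"].tolist()
    rna_cols = bio[bio["kind"] == "RNA"]["sample_id"].tolist()
    p_wil = np.array(
        [
            wilcoxon_rank_sum(
                proportions.loc[aid, dna_cols].to_numpy(),
                proportions.loc[aid, rna_cols].to_numpy(),
            ).p_value
            for aid in counts.index
        ]
    )
    table = pd.concat([act, ratio_summary, scores], axis=1)
    table["p_wilcoxon"] = p_wil
    table["q_bh"] = bh_adjust(p_wil)
    table["group"] = catalog.groups().loc[table.index]
    table = table.reset_index(names="amplicon_id")[ACTIVITY_COLUMNS]
    return table, fit
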