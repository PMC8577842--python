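"""Epigenomic-annotation enrichment of active amplicons.

Annotation interval sets (DNase, histone marks, ATAC peaks, TF footprints,
conserved elements) are merged (book-ended intervals fuse) and intersected
with amplicon spans (any shared base counts).  Enrichment of overlap among
significant amplicons is assessed against the *library background*: the null
resamples sets of the same size from the assayed amplicons, which accounts
for the selection bias of the library itself rather than for genomic position.

Two complementary covariate analyses mirror the interval tests: adding the
overlap flag to the background linear model and comparing BIC with/without it,
and the point-biserial correlation of the flag with the Z-scaled residuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats


class IntervalError(ValueError):
    pass


@dataclass
class IntervalSet:
    """A named collection of genomic intervals, 0-based half-open."""

    name: str
    trees: dict[str, IntervalTree]

    @classmethod
    def from_intervals(
        cls, name: str, intervals: Iterable[tuple[str, int, int]]
    ) -> "IntervalSet":
        trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise IntervalError(f"interval end <= start: {chrom}:{start}-{end}")
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
        return cls(name, trees)

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "IntervalSet":
        path = Path(path)
        bed = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], comment="#",
            names=["chrom", "start", "end"],
        )
        return cls.from_intervals(
            name or path.stem, bed.itertuples(index=False, name=None)
        )

    def to_bed(self, path: str | Path) -> None:
        rows = self.intervals()
        pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
            path, sep="\t", index=False, header=False
        )

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom in sorted(self.trees):
            for iv in sorted(self.trees[chrom]):
                out.append((chrom, iv.begin, iv.end))
        return out

    def merge(self) -> "IntervalSet":
        """Union of overlapping or book-ended intervals (reduce semantics)."""
        trees = {}
        for chrom, tree in self.trees.items():
            t = IntervalTree(tree)
            t.merge_overlaps(strict=False)  # strict=False fuses book-ended
            trees[chrom] = t
        return IntervalSet(self.name, trees)

    def total_bases(self) -> int:
        return sum(iv.end - iv.begin for t in self.trees.values() for iv in t)

    def __len__(self) -> int:
        return sum(len(t) for t in self.trees.values())


def merge_intervals(
    intervals: Iterable[tuple[str, int, int]], name: str = ""
) -> IntervalSet:
    return IntervalSet.from_intervals(name, intervals).merge()


def overlaps_any(amplicon: tuple[str, int, int], mark: IntervalSet) -> bool:
    """True iff the amplicon shares >= 1 base with any mark interval."""
    chrom, start, end = amplicon
    tree = mark.trees.get(chrom)
    return bool(tree is not None and tree.overlap(start, end))


def overlap_flags(catalog, mark: IntervalSet) -> pd.Series:
    """Boolean overlap flag per catalog amplicon, indexed by amplicon_id."""
    flags = {
        aid: overlaps_any((chrom, start, end), mark)
        for aid, chrom, start, end in catalog.intervals()
    }
    return pd.Series(flags, name=mark.name)


@dataclass
class EnrichmentResult:
    mark_name: str
    observed_overlap: int
    n_significant: int
    n_background: int
    perm_p: float
    n_permutations: int
    seed: int


def permutation_enrichment(
    significant_ids: Sequence[str],
    background_ids: Sequence[str],
    flags: Mapping[str, bool] | pd.Series,
    n_perm: int = 20_000,
    seed: int = 0,
    mark_name: str = "",
) -> EnrichmentResult:
    """One-tailed permutation enrichment against the library background.

    The null draws ``len(significant_ids)`` amplicons without replacement from
    the background and counts mark overlaps; the add-one Monte-Carlo p

        perm_p = (#{null >= observed} + 1) / (n_perm + 1)

    is never zero and deterministic for a fixed seed.
    """
    bg = list(background_ids)
    sig = list(significant_ids)
    if not set(sig) <= set(bg):
        raise ValueError("significant_ids must be a subset of background_ids")
    flags = pd.Series(flags)
    bg_flags = flags.loc[bg].to_numpy(dtype=bool)
    observed = int(flags.loc[sig].sum())
    k, n = len(sig), len(bg)
    if k > n:
        raise ValueError("more significant amplicons than background")

    rng = np.random.default_rng(seed)
    exceed = 0
    chunk = max(1, min(n_perm, int(4_000_000 // max(n, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # k smallest random keys per row = uniform subset without replacement
        keys = rng.random((m, n))
        picks = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < n else np.tile(
            np.arange(n), (m, 1)
        )
        null = bg_flags[picks].sum(axis=1)
        exceed += int((null >= observed).sum())
        done += m
    perm_p = (exceed + 1) / (n_perm + 1)
    return EnrichmentResult(
        mark_name=mark_name or getattr(flags, "name", "") or "",
        observed_overlap=observed,
        n_significant=k,
        n_background=n,
        perm_p=perm_p,
        n_permutations=n_perm,
        seed=seed,
    )


def glm_covariate_bic(
    log2_rna, log2_dna, gc, mark_flag
) -> tuple[float, float, float, float]:
    """Does an annotation flag improve the background model?

    Fits Gaussian linear models of log2 RNA on log2 DNA + GC with and without
    the dichotomous overlap flag.  Returns (flag coefficient, its t-test p,
    BIC without, BIC with); BIC = n*ln(RSS/n) + k*ln(n) with k counting the
    coefficients plus the error variance, consistently between models.
    """
    import statsmodels.api as sm

    y = np.asarray(log2_rna, dtype=float)
    x = np.asarray(log2_dna, dtype=float)
    g = np.asarray(gc, dtype=float)
    f = np.asarray(mark_flag, dtype=float)
    if f.min() == f.max():
        raise ValueError("mark_flag is constant: degenerate covariate")
    n = len(y)

    def _fit(X):
        res = sm.OLS(y, X).fit()
        rss = float(res.ssr)
        k = X.shape[1] + 1  # coefficients + error variance
        return res, n * np.log(rss / n) + k * np.log(n)

    X0 = np.column_stack([np.ones(n), x, g])
    X1 = np.column_stack([X0, f])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise ValueError("degenerate design with mark_flag included")
    _, bic_without = _fit(X0)
    res1, bic_with = _fit(X1)
    return float(res1.params[3]), float(res1.pvalues[3]), float(bic_without), float(bic_with)


def point_biserial(z, flag) -> float:
    """Pearson correlation between a continuous score and a 0/1 flag."""
    z = np.asarray(z, dtype=float)
    f = np.asarray(flag, dtype=float)
    if f.min() == f.max():
        raise ValueError("flag has a single class")
    return float(stats.pearsonr(z, f)[0])


def enrich_marks(
    catalog,
    marks: Mapping[str, IntervalSet],
    significant_ids: Sequence[str],
    background_ids: Sequence[str],
    n_perm: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation enrichment for every mark; one TSV-ready row per mark."""
    rows = []
    for i, (name, mark) in enumerate(sorted(marks.items())):
        flags = overlap_flags(catalog, mark.merge())
        res = permutation_enrichment(
            significant_ids, background_ids, flags,
            n_perm=n_perm, seed=seed + i, mark_name=name,
        )
        rows.append(
            (
                name,
                res.observed_overlap,
                res.n_significant,
                res.n_background,
                res.perm_p,
                res.n_permutations,
                res.seed,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mark_name",
            "observed_overlap",
            "n_significant",
            "n_background",
            "perm_p",
            "n_permutations",
            "seed",
        ],
    )
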