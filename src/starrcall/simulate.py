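"""Synthetic MPRA data with ground truth.

The generator reproduces the statistical structure the analysis assumes, on a
synthetic chromosome:

* library/DNA representation: amplicon-specific log2 abundance plus a GC bias
  term (batch-cloning PCR favors particular GC content),
* reporter RNA: basal transcription proportional to delivered DNA copy number
  (``basal_slope`` on the log2 scale, near 1) with a residual GC dependence
  (``rna_gc_coeff``) and a multiplicative enhancer effect for a spiked-active
  subset,
* negative-binomial count noise at configurable overdispersion (Poisson at 0),
* replicate-specific dropout of low-abundance amplicons in RNA only,
* an optional high-cycle technical RNA replicate duplicating the last RNA
  replicate's expectation with independent noise,
* annotation interval sets preferentially overlapping true actives, and
* biallelic SNP counts with allele frequencies shared between DNA and RNA
  under the null.

Everything is bit-reproducible for a fixed seed; the four generators draw from
independent seeded streams so they can be called in any combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import GROUPS, AmpliconCatalog
from .enrichment import IntervalSet

# default group mix, proportional to the four-group design of a GWAS/LD/
# open-chromatin amplicon library (~900 bp candidates)
GROUP_WEIGHTS: Mapping[str, float] = {
    "GWAS": 0.42,
    "LD": 0.22,
    "FBDHS": 0.32,
    "PutEnh": 0.04,
}
# probability that an amplicon of each group was ascertained as a likely
# enhancer (open-chromatin evidence); SNP-driven groups are mostly negative
ASCERTAINED_PROB: Mapping[str, float] = {
    "GWAS": 0.15,
    "LD": 0.15,
    "FBDHS": 0.90,
    "PutEnh": 0.50,
}

DistSpec = tuple


@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the emulated study conditions.

    ``effect_law`` / ``gc_law`` are distribution specs: ``("fixed", v)``,
    ``("lognormal", mean_log, sd_log)`` (natural-log parameters) or
    ``("beta", a, b)``.  ``gc_bias_coeff`` is the log2 change in library/DNA
    representation per unit GC fraction; ``rna_gc_coeff`` the residual log2
    change in RNA beyond DNA proportionality; ``dispersion`` the
    negative-binomial overdispersion alpha (variance mu + alpha*mu^2);
    ``dropout_rate`` the per-replicate probability that an amplicon in the
    lowest abundance decile yields zero RNA.
    """

    n_amplicons: int = 308
    n_dna_reps: int = 4
    n_rna_reps: int = 4
    depth_dna: float = 2_000_000.0
    depth_rna: float = 2_000_000.0
    frac_active: float = 0.1
    effect_law: DistSpec = ("fixed", 4.0)
    gc_law: DistSpec = ("beta", 8.0, 8.0)
    gc_bias_coeff: float = 2.5
    rna_gc_coeff: float = 1.0
    basal_slope: float = 0.9
    log_abundance_sd: float = 1.2
    dispersion: float = 0.1
    dropout_rate: float = 0.1
    technical_replicate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_active <= 1.0:
            raise ValueError("frac_active must be in [0, 1]")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.depth_dna <= 0 or self.depth_rna <= 0:
            raise ValueError("depths must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent deterministic stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def _draw(law: DistSpec, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = law[0]
    if kind == "fixed":
        return np.full(size, float(law[1]))
    if kind == "lognormal":
        return rng.lognormal(mean=float(law[1]), sigma=float(law[2]), size=size)
    if kind == "beta":
        return rng.beta(float(law[1]), float(law[2]), size=size)
    raise ValueError(f"unknown distribution spec {law!r}")


def simulate_truth(config: SimulationConfig) -> tuple[AmpliconCatalog, pd.DataFrame]:
    """Draw an amplicon catalog and its ground-truth effect table.

    Exactly ``round(frac_active * n)`` amplicons receive a multiplicative
    ``true_effect`` drawn from ``effect_law``; the rest are inactive
    (effect 1).  The truth table is indexed by ``amplicon_id``.
    """
    rng = _rng(config.seed, 0)
    n = config.n_amplicons
    width = len(str(max(n, 1)))
    ids = [f"amp{i + 1:0{width}d}" for i in range(n)]

    gc = np.clip(_draw(config.gc_law, n, rng), 0.0, 1.0)
    groups = rng.choice(
        list(GROUP_WEIGHTS), size=n, p=np.array(list(GROUP_WEIGHTS.values()))
    )
    ascertained = rng.random(n) < np.array([ASCERTAINED_PROB[g] for g in groups])

    starts = 1000 + 2000 * np.arange(n)
    table = pd.DataFrame(
        {
            "amplicon_id": ids,
            "chrom": "chrS",
            "start": starts,
            "end": starts + 900,
            "group": pd.Categorical(groups, categories=list(GROUPS)).astype(str),
            "gc": gc,
            "ascertained_enhancer": ascertained,
        }
    )
    catalog = AmpliconCatalog(table)

    n_active = int(round(config.frac_active * n))
    effects = np.ones(n)
    active_idx = rng.choice(n, size=n_active, replace=False)
    effects[active_idx] = _draw(config.effect_law, n_active, rng)
    truth = pd.DataFrame({"amplicon_id": ids, "true_effect": effects}).set_index(
        "amplicon_id"
    )
    return catalog, truth


def _nb_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu^2 (Poisson at 0)."""
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    catalog: AmpliconCatalog, truth: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a raw count matrix and its sample sheet.

    Returns ``(counts, samples)``: counts indexed by amplicon_id with one
    column per sample (one previral library, ``n_dna_reps`` DNA, ``n_rna_reps``
    RNA, plus an optional technical RNA replicate); samples with columns
    sample_id / kind / replicate / technical_of.
    """
    ids = list(catalog.ids)
    if list(truth.index) != ids:
        raise ValueError("catalog and truth are not aligned on amplicon_id")
    rng = _rng(config.seed, 1)
    n = len(ids)
    gc = catalog.gc().to_numpy()
    effect = truth["true_effect"].to_numpy()

    log_abund = rng.normal(0.0, config.log_abundance_sd, size=n)
    log2_dna = config.gc_bias_coeff * gc + log_abund
    dna_prop = np.exp2(log2_dna)
    dna_prop /= dna_prop.sum()

    log2_rna = (
        config.basal_slope * np.log2(dna_prop)
        + config.rna_gc_coeff * gc
        + np.log2(effect)
    )
    rna_prop = np.exp2(log2_rna)
    rna_prop /= rna_prop.sum()

    # lowest abundance decile is dropout-eligible (RNA only)
    decile_cut = np.quantile(dna_prop, 0.1)
    dropout_eligible = dna_prop <= decile_cut

    cols: dict[str, np.ndarray] = {}
    rows = []
    cols["Library"] = _nb_counts(dna_prop * config.depth_dna, config.dispersion, rng)
    rows.append(("Library", "library", 0, ""))
    for r in range(1, config.n_dna_reps + 1):
        cols[f"DNA_{r}"] = _nb_counts(
            dna_prop * config.depth_dna, config.dispersion, rng
        )
        rows.append((f"DNA_{r}", "DNA", r, ""))

    def rna_sample() -> np.ndarray:
        c = _nb_counts(rna_prop * config.depth_rna, config.dispersion, rng)
        dropped = dropout_eligible & (rng.random(n) < config.dropout_rate)
        c[dropped] = 0
        return c

    for r in range(1, config.n_rna_reps + 1):
        cols[f"RNA_{r}"] = rna_sample()
        rows.append((f"RNA_{r}", "RNA", r, ""))
    if config.technical_replicate and config.n_rna_reps >= 1:
        last = config.n_rna_reps
        cols[f"RNA_{last}_tech"] = rna_sample()
        rows.append((f"RNA_{last}_tech", "RNA", last, f"RNA_{last}"))

    counts = pd.DataFrame(cols, index=pd.Index(ids, name="amplicon_id"))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "kind", "replicate", "technical_of"]
    )
    return counts, samples


def simulate_annotations(
    catalog: AmpliconCatalog,
    truth: pd.DataFrame,
    p_active: float = 0.8,
    p_inactive: float = 0.2,
    seed: int = 0,
    marks: Sequence[str] = ("DNase", "H3K4me1", "H3K4me3", "H3K27me3"),
) -> dict[str, IntervalSet]:
    """Annotation interval sets preferentially overlapping true actives.

    An amplicon overlaps a mark with probability ``p_active`` if its true
    effect exceeds 1, else ``p_inactive``; the mark interval is placed inside
    the amplicon's span (a 200 bp peak at the center).
    """
    if p_active < p_inactive:
        raise ValueError("p_active must be >= p_inactive")
    rng = _rng(seed, 2)
    active = (truth.reindex(catalog.ids)["true_effect"] > 1).to_numpy()
    out: dict[str, IntervalSet] = {}
    for mark in marks:
        p = np.where(active, p_active, p_inactive)
        hit = rng.random(len(catalog)) < p
        intervals = []
        for flag, (aid, chrom, start, end) in zip(hit, catalog.intervals()):
            if flag:
                mid = (start + end) // 2
                intervals.append((chrom, mid - 100, mid + 100))
        out[mark] = IntervalSet.from_intervals(mark, intervals).merge()
    return out


def default_sample_sheet(n_dna: int = 4, n_rna: int = 4) -> pd.DataFrame:
    rows = [("Library", "library", 0, "")]
    rows += [(f"DNA_{r}", "DNA", r, "") for r in range(1, n_dna + 1)]
    rows += [(f"RNA_{r}", "RNA", r, "") for r in range(1, n_rna + 1)]
    return pd.DataFrame(rows, columns=["sample_id", "kind", "replicate", "technical_of"])


def simulate_alleles(
    catalog: AmpliconCatalog,
    n_snps: int,
    af_law: DistSpec = ("beta", 2.0, 2.0),
    depth: int = 500,
    seed: int = 0,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Biallelic SNP counts per sample in long readcount-style format.

    One SNP per amplicon (cycling through the catalog), a reference-allele
    frequency drawn once per SNP from ``af_law`` and shared by every sample
    (the null: frequencies preserved between DNA and RNA), counts
    binomial(depth, af).  Columns: snp_id, amplicon_id, chrom, pos, sample_id,
    base, is_ref, count, mean_base_quality.
    """
    if n_snps < 0:
        raise ValueError("n_snps must be >= 0")
    rng = _rng(seed, 3)
    if samples is None:
        samples = default_sample_sheet()
    amp = catalog.table
    rows = []
    bases = ("A", "G")
    for i in range(n_snps):
        a = amp.iloc[i % len(amp)]
        snp_id = f"rs_syn{i + 1:04d}"
        pos = int(a.start) + 450
        af = float(np.clip(_draw(af_law, 1, rng)[0], 0.0, 1.0))
        for s in samples.itertuples(index=False):
            ref = int(rng.binomial(depth, af))
            alt = depth - ref
            for base, is_ref, count in ((bases[0], True, ref), (bases[1], False, alt)):
                rows.append(
                    (
                        snp_id,
                        a.amplicon_id,
                        a.chrom,
                        pos,
                        s.sample_id,
                        base,
                        is_ref,
                        count,
                        float(np.round(rng.normal(35.0, 2.0), 2)),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "amplicon_id",
            "chrom",
            "pos",
            "sample_id",
            "base",
            "is_ref",
            "count",
            "mean_base_quality",
        ],
    )
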