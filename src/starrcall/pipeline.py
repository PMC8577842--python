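"""End-to-end orchestration: catalog -> QC -> activity -> enrichment -> alleles.

``run_pipeline`` reads the inputs named in a :class:`RunConfig`, applies every
stage with the configured thresholds, and writes a TSV/text output bundle
(activity table, model fit, exclusion log, enrichment table, allele summary,
run log, summary report).  All outputs carry a provenance header (package
version, seed, config hash) and the run is byte-deterministic for a fixed
config and seed.  Stages with missing optional inputs (annotations, alleles)
are skipped with a logged notice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, activity as act, allelic, enrichment, io, qc
from .catalog import AmpliconCatalog


@dataclass
class RunConfig:
    counts: str
    samples: str
    catalog: str
    out_dir: str
    annotations: list[str] = field(default_factory=list)
    alleles: str | None = None
    min_dna_count: int = 200
    min_lib_proportion: float = 2.0 ** -15
    stabilizer: float = 1000.0
    trim_fraction: float = 0.10
    ratio_threshold: float = 1.5
    p_threshold: float = 0.05
    q_threshold: float = 0.1
    min_base_quality: float = 25.0
    min_af: float = 0.01
    maf_threshold: float = 0.1
    n_permutations: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        for name in ("p_threshold", "q_threshold", "min_af", "maf_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "annotations" in data and isinstance(data["annotations"], str):
            data["annotations"] = [
                p for p in data["annotations"].split(",") if p.strip()
            ]
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict written to summary.txt."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash identifies the analysis, not where its outputs land
    chash = io.config_hash(
        {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    )
    prov = {"version": __version__, "seed": config.seed, "config_hash": chash}
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"INFO {msg}")

    log(f"starrcall {__version__} config_hash={chash} seed={config.seed}")

    catalog = AmpliconCatalog.from_tsv(config.catalog)
    counts = io.read_counts(config.counts)
    samples = io.read_samples(config.samples)
    qc.validate_samples(samples, counts)
    if qc.biological(samples, "DNA").empty:
        raise qc.QCError("configuration error: no DNA samples")
    log(f"loaded {len(counts)} amplicons x {counts.shape[1]} samples")

    proportions = qc.compute_proportions(counts)
    retained, exclusions = qc.filter_amplicons(
        counts,
        proportions,
        samples,
        min_dna_count=config.min_dna_count,
        min_lib_proportion=config.min_lib_proportion,
    )
    by_rule = exclusions.groupby("rule")["amplicon_id"].nunique().to_dict()
    log(
        f"filter: retained {len(retained)}/{len(counts)} amplicons; "
        f"removed per rule: {by_rule}"
    )
    io.write_tsv(exclusions, out / "exclusions.tsv", prov)

    table, fit = act.activity_table(
        counts,
        samples,
        catalog,
        retained,
        stabilizer=config.stabilizer,
        trim_fraction=config.trim_fraction,
        ratio_threshold=config.ratio_threshold,
    )
    io.write_tsv(table, out / "activity.tsv", prov)
    (out / "model.txt").write_text(io.provenance_lines(prov) + fit.to_text())
    n_sig_p = int((table["p_model"] < config.p_threshold).sum())
    n_sig_q = int((table["q_model"] < config.q_threshold).sum())
    n_ratio = int(table["ratiometric_call"].sum())
    model_sig = table.loc[table["p_model"] < config.p_threshold, "amplicon_id"]
    concordant = int(
        table.set_index("amplicon_id").loc[model_sig, "ratiometric_call"].sum()
    )
    log(
        f"activity: {n_sig_p} at p<{config.p_threshold}, {n_sig_q} at "
        f"q<{config.q_threshold}, {n_ratio} ratiometric-active, "
        f"{concordant}/{n_sig_p} model calls also ratiometric"
    )

    enrich_rows = pd.DataFrame()
    if config.annotations:
        marks = {
            enrichment.IntervalSet.from_bed(p).name: enrichment.IntervalSet.from_bed(p)
            for p in config.annotations
        }
        enrich_rows = enrichment.enrich_marks(
            catalog,
            marks,
            significant_ids=model_sig.tolist(),
            background_ids=list(retained),
            n_perm=config.n_permutations,
            seed=config.seed,
        )
        io.write_tsv(enrich_rows, out / "enrichment.tsv", prov)
        for row in enrich_rows.itertuples(index=False):
            log(
                f"enrichment {row.mark_name}: {row.observed_overlap}/"
                f"{row.n_significant} overlap, perm_p={row.perm_p:.4g}"
            )
    else:
        log("enrichment: no annotation sets supplied; stage skipped")

    allele_corr = float("nan")
    if config.alleles:
        raw = io.read_tsv(config.alleles)
        filtered = allelic.filter_allele_counts(
            raw, min_base_quality=config.min_base_quality, min_af=config.min_af
        )
        snp_table, allele_corr = allelic.allele_summary(
            filtered, samples, maf_threshold=config.maf_threshold
        )
        io.write_tsv(snp_table, out / "alleles.tsv", prov)
        log(
            f"alleles: {snp_table['snp_id'].nunique()} biallelic SNPs, "
            f"{int(snp_table['eligible'].sum())} MAF-eligible, "
            f"DNA-RNA ref-AF r={allele_corr:.4f}"
        )
    else:
        log("alleles: no allele table supplied; stage skipped")

    summary = {
        "version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "n_amplicons_input": len(counts),
        "n_retained": len(retained),
        "n_significant_p": n_sig_p,
        "n_significant_q": n_sig_q,
        "n_ratiometric_active": n_ratio,
        "n_model_and_ratiometric": concordant,
        "allele_ref_af_correlation": allele_corr,
        "thresholds": {
            k: v
            for k, v in config.to_dict().items()
            if k not in {"counts", "samples", "catalog", "annotations", "alleles", "out_dir"}
        },
    }
    if len(enrich_rows):
        summary["enrichment_perm_p"] = dict(
            zip(enrich_rows["mark_name"], enrich_rows["perm_p"])
        )
    (out / "summary.txt").write_text(
        io.provenance_lines(prov) + yaml.safe_dump(summary, sort_keys=True)
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
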