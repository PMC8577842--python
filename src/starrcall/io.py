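"""TSV I/O with provenance headers.

All tabular outputs are TSV with a leading comment block of ``# key=value``
lines carrying the run's provenance (package version, seed, config hash) so
every file identifies the run that produced it.  Readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import pandas as pd


def config_hash(config: Mapping) -> str:
    """Stable short hash of a flat config mapping."""
    payload = json.dumps(
        {k: str(v) for k, v in sorted(config.items())}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def provenance_lines(provenance: Mapping | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    provenance: Mapping | None = None,
    index: bool = False,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_lines(provenance))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Count matrix TSV: first column amplicon_id, one column per sample."""
    counts = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    counts.index.name = "amplicon_id"
    return counts


def read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(
        path, sep="\t", comment="#", dtype={"technical_of": str}
    )
    if "technical_of" in samples.columns:
        samples["technical_of"] = samples["technical_of"].fillna("")
    return samples
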