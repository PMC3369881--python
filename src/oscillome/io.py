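"""Readers and writers for the pipeline's table and sequence formats.

All tables are TSV/CSV with explicit headers (decimal points, no thousands
separators; quoted fields are handled).  Writers are atomic (temp file +
rename) so partially written outputs never enter a downstream stage.
Loaders for the packaged supplementary-style CSVs validate their schemas
and the consensus-label vocabulary.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Consensus-label vocabulary: seven co-expression cohorts, low-amplitude and
#: non-consensus background classes, and "r" for genes absent from an array.
CONSENSUS_LABELS = {"A", "AB", "B", "B.C", "C", "B.D", "D",
                    "l.b", "cd.n", "cd.ab", "ab.n", "l", "n", "r"}

#: Column schemas of the packaged result tables (by schema id).
PACKAGED_SCHEMAS = {
    "genes": {"required": ["gene", "cluster"], "label_column": "cluster"},
    "meta": {"required": ["experiment", "sota_cluster"], "label_column": None},
    "gene_data": {"required": ["gene", "tss"], "label_column": None},
    "atp": {"required": ["time_min", "dO2_percent", "atp_adp"], "label_column": None},
}


def atomic_write(path, writer) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path, index: bool = True, sep: str = "\t") -> None:
    atomic_write(path, lambda tmp: df.to_csv(tmp, sep=sep, index=index))
    logger.info("wrote %s: %d rows", path, len(df))


def read_matrix(path, sep: str = "\t") -> pd.DataFrame:
    """Genes x timepoints (or genes x positions) matrix with a numeric header."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = [float(c) if "." in str(c) else int(c) for c in df.columns]
    return df


def read_table(path, sep: str = "\t", index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=index_col)


def write_fasta(sequences: dict, path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    atomic_write(path, lambda tmp: SeqIO.write(records, tmp, "fasta"))


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gmt(categories: dict, path) -> None:
    def _write(tmp):
        with open(tmp, "w") as fh:
            for term, genes in categories.items():
                fh.write("\t".join([term, term] + sorted(genes)) + "\n")
    atomic_write(path, _write)


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(parts[2:])
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_label_map(path):
    """Load a declarative consensus label map (YAML) into a LabelMap."""
    from .cluster import LabelMap
    cfg = load_config(path)
    cells = {}
    for entry in cfg.get("cells", []):
        cells[(str(entry["a"]), str(entry["b"]))] = str(entry["label"])
    return LabelMap(cells=cells,
                    fallback={str(k): str(v) for k, v in cfg.get("fallback", {}).items()},
                    default=str(cfg.get("default", "n")),
                    absent=str(cfg.get("absent", "r")))


def load_packaged(path, schema: str) -> pd.DataFrame:
    """Load one of the packaged result CSVs with schema validation.

    ``schema`` is one of ``genes`` (per-gene time series, features and
    consensus labels), ``meta`` (compendium meta-analysis), ``gene_data``
    (TSS and per-gene annotations) or ``atp`` (ATP:ADP measurements).
    Missing mandatory columns raise a schema error naming the absentees;
    unknown consensus labels are rejected.
    """
    if schema not in PACKAGED_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(PACKAGED_SCHEMAS)}")
    spec = PACKAGED_SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: schema {schema!r} is missing columns {missing}")
    col = spec["label_column"]
    if col is not None:
        unknown = sorted(set(df[col].dropna().astype(str)) - CONSENSUS_LABELS)
        if unknown:
            raise ValueError(f"{path}: unknown cluster labels {unknown}")
    logger.info("loaded %s (%s): %d rows", path, schema, len(df))
    return df


def atp_adp_ratio(atp, atp_plus_adp):
    """ATP:ADP ratio from paired luciferase measurements (concentrations, µM).

    The assay measures [ATP] directly and [ATP+ADP] after enzymatic
    conversion of ADP to ATP, so [ADP] = [ATP+ADP] - [ATP] and the ratio is
    ``atp / (atp_plus_adp - atp)``.
    """
    atp = np.asarray(atp, dtype=float)
    total = np.asarray(atp_plus_adp, dtype=float)
    if np.any(atp <= 0) or np.any(total <= atp):
        raise ValueError("inconsistent measurements: need atp_plus_adp > atp > 0")
    return atp / (total - atp)


# ---------------------------------------------------------------------------
# fixture serialization
# ---------------------------------------------------------------------------

def write_fixture(fixture, outdir) -> None:
    """Write a GenomeFixture to a directory of plain-text files."""
    outdir = Path(outdir)
    write_table(fixture.annotation, outdir / "annotation.tsv", index=False)
    write_fasta(fixture.sequences, outdir / "genome.fasta")
    write_table(fixture.tss_evidence, outdir / "tss_evidence.tsv", index=False)
    for name, track in fixture.tracks.items():
        write_table(track, outdir / f"track_{name}.tsv")
    write_gmt(fixture.categories, outdir / "categories.gmt")
    write_table(fixture.numeric_data, outdir / "numeric_data.tsv")
    write_table(fixture.compendium, outdir / "compendium.tsv")


def write_experiment(experiment, path) -> None:
    """Expression matrix TSV: genes x timepoints, header row of sample times."""
    write_table(experiment.matrix, path)


def features_to_degrees(features: pd.DataFrame) -> pd.DataFrame:
    """Feature table with phase columns converted from radians to degrees."""
    out = features.copy()
    for col in out.columns:
        if str(col).startswith("phi_"):
            out[col] = np.rad2deg(out[col]) % 360.0
    return out
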