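"""Shared readers/writers, table schemas and run manifests.

Conventions: TSV is the canonical table dialect (tab-separated, header
row, ``.`` for missing values); floats are written with 6 significant
digits and percentages to one decimal; coordinates are 1-based inclusive
everywhere in user-facing output.  Logs go to standard error; data go to
files only.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from mirkit.errors import SchemaError, ValidationError
from mirkit.locus_context import GeneFeature
from mirkit.seed_sites import MatureMiRNA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (wrapped or unwrapped) FASTA file into (id, sequence) pairs.

    Duplicate record ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"FASTA file not found: {path}")
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    ids = [r[0] for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate FASTA ids: {', '.join(dupes)}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_mirnas(path: str | Path) -> list[MatureMiRNA]:
    """Read mature miRNAs from FASTA or a two-column TSV (name, sequence)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(">"):
        return [MatureMiRNA(rid, seq) for rid, seq in read_fasta(path)]
    mirnas = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SchemaError(
                    f"{path}:{lineno}: expected two tab-separated columns "
                    "(name, sequence)"
                )
            mirnas.append(MatureMiRNA(parts[0], parts[1]))
    return mirnas


_GFF_TYPE_MAP = {
    "mRNA": "transcript",
    "ncRNA": "transcript",
    "transcript": "transcript",
    "pre_miRNA": "miRNA_gene",
    "miRNA_primary_transcript": "miRNA_gene",
    "miRNA_gene": "miRNA_gene",
    "gene": "gene",
    "exon": "exon",
}


def _prevalidate_gff3(path: Path) -> None:
    """Structural pre-check so malformed rows fail with their line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValidationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise ValidationError(f"{path}:{lineno}: end {end} < start {start}")


def read_gff3(path: str | Path, mirna_ids: set[str] | None = None) -> list[GeneFeature]:
    """Read a GFF3 file into a flat :class:`GeneFeature` collection.

    Parsing is delegated to gffutils (in-memory database).  Feature types
    are mapped onto gene/transcript/exon/miRNA_gene; a gene is treated as a
    miRNA gene when its type maps there, its ``gene_biotype``/``biotype``
    attribute is ``miRNA``, or its ID is in ``mirna_ids``.  Malformed rows
    are rejected with their line number.
    """
    import gffutils

    path = Path(path)
    if not path.exists():
        raise ValidationError(f"GFF3 file not found: {path}")
    _prevalidate_gff3(path)
    mirna_ids = mirna_ids or set()
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: list[GeneFeature] = []
    for f in db.all_features(order_by=("seqid", "start")):
        mapped = _GFF_TYPE_MAP.get(f.featuretype)
        if mapped is None:
            continue  # CDS, UTR etc. are not needed
        fid = f.attributes.get("ID", [f.id])[0]
        biotype = (
            f.attributes.get("gene_biotype", []) or f.attributes.get("biotype", ["other"])
        )[0]
        if mapped == "miRNA_gene" or (mapped == "gene" and (fid in mirna_ids or biotype == "miRNA")):
            mapped, biotype = "miRNA_gene", "miRNA"
        parents = f.attributes.get("Parent", [])
        features.append(
            GeneFeature(
                feature_id=fid,
                feature_type=mapped,
                chrom=f.seqid,
                strand=f.strand,
                start=f.start,
                end=f.end,
                parent_id=parents[0] if parents else None,
                biotype=biotype,
            )
        )
    return features


def write_gff3(features: Sequence[GeneFeature], path: str | Path) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    type_out = {"gene": "gene", "transcript": "mRNA", "exon": "exon", "miRNA_gene": "miRNA_gene"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.feature_id}"]
            if f.parent_id:
                attrs.append(f"Parent={f.parent_id}")
            attrs.append(f"gene_biotype={f.biotype}")
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "mirkit",
                        type_out.get(f.feature_type, f.feature_type),
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV/CSV table, matching required columns case-insensitively.

    Header names are lowercased; ``.`` is treated as missing.  A missing
    required column raises :class:`SchemaError` naming it.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"table not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, na_values=["."], comment="#")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in required:
        if col.lower() not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return df


def _format_value(v) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "."
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Deterministic TSV writer: stable column order, 6-sig-digit floats,
    ``.`` for missing values."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(_format_value(v) for v in row) + "\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written alongside every CLI output set."""

    subcommand: str
    parameters: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256
    version: str = ""
    rng_seed: int | None = None

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256_of(path)

    def write(self, path: str | Path) -> None:
        from mirkit import __version__

        payload = {
            "subcommand": self.subcommand,
            "parameters": self.parameters,
            "inputs": self.inputs,
            "version": self.version or __version__,
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
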