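"""Readers and writers for the standard formats the pipeline consumes.

Internal coordinates are 0-based half-open everywhere; 1-based coordinates
appear only at the VCF boundary.  All internal writers round-trip
losslessly.  Every CLI run writes a JSON manifest (command, config hash,
seed, version) so deterministic stages reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

SNP_COLUMNS = ["chrom", "pos", "ancestral", "derived", "freq", "site_class",
               "call"]


class FormatError(ValueError):
    """Malformed input file; message carries file and line."""


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED (0-based half-open): chrom, start, end [+ extra columns kept]."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: expected >= 3 BED columns")
            try:
                rows.append([parts[0], int(parts[1]), int(parts[2])] + parts[3:])
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    ncol = max(len(r) for r in rows) if rows else 3
    names = ["chrom", "start", "end"] + [f"col{k}" for k in range(4, ncol + 1)]
    return pd.DataFrame(rows, columns=names[:ncol])


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_genetic_map(path: str | Path) -> pd.DataFrame:
    """TSV with header chrom, pos, cm (cumulative cM)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"chrom", "pos", "cm"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing map columns {sorted(missing)}")
    return df


def write_genetic_map(df: pd.DataFrame, path: str | Path) -> None:
    df[["chrom", "pos", "cm"]].to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, required: list[str] | None = None) -> pd.DataFrame:
    """Generic TSV with header; validates required columns if given."""
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, required=["chrom", "pos"])


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path: str | Path) -> str:
    return Path(path).read_text().strip()


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def read_vcf_snps(path: str | Path) -> pd.DataFrame:
    """Minimal VCF subset -> SNP table (CHROM/POS/REF/ALT, INFO AF=).

    VCF positions are 1-based; the returned ``pos`` is the internal 0-based
    coordinate of the site (VCF pos 100 corresponds to interval [99, 100)).
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}:{ln}: expected >= 8 VCF columns")
            chrom, pos, _, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
            if len(ref) != 1 or len(alt) != 1:
                continue  # not a biallelic SNP
            freq = float("nan")
            for kv in parts[7].split(";"):
                if kv.startswith("AF="):
                    freq = float(kv[3:].split(",")[0])
            try:
                rows.append({"chrom": chrom, "pos": int(pos) - 1,
                             "ancestral": ref, "derived": alt, "freq": freq,
                             "site_class": "NA", "call": "NA"})
            except ValueError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(path: str | Path, command: str, seed: int | None,
                   config: dict) -> None:
    from . import __version__
    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
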