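"""Shared record types, exceptions and flat-file I/O.

Protein databases travel as FASTA with headers of the form ``id|taxon``
(taxon in {host, symbiont, contaminant}); PSM tables, sample designs and
taxon maps travel as TSV. All tabular I/O goes through pandas, all FASTA
I/O through Bio.SeqIO.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_TAXA = ("host", "symbiont", "contaminant")

#: amino-acid alphabet used throughout; X is the ambiguity placeholder
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PSM_COLUMNS = ["sample_id", "spectrum_id", "peptide", "score", "is_decoy"]
DESIGN_COLUMNS = ["sample_id", "condition", "replicate"]


class ConfigurationError(ValueError):
    """A configuration field is missing or out of range."""


class GenerationError(RuntimeError):
    """The synthetic-data generator was asked for an impossible draw."""


class ParseError(ValueError):
    """An input file or sequence string is malformed."""


class ValidationError(ValueError):
    """Input records violate a contract (duplicate ids, negative counts...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database protein with its taxon label."""

    id: str
    sequence: str
    taxon: str = "host"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein record requires a non-empty id")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, default_taxon: str = "host") -> list[ProteinRecord]:
    """Read ``id|taxon`` FASTA into ProteinRecords.

    Headers without a ``|taxon`` suffix get *default_taxon*.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, taxon = rec.id.partition("|")
        records.append(
            ProteinRecord(id=name, sequence=str(rec.seq).upper(), taxon=taxon or default_taxon)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.taxon}", description="") for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_psm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(PSM_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"PSM table {path} lacks columns: {sorted(missing)}")
    df["is_decoy"] = df["is_decoy"].astype(int)
    return df


def write_psm_table(df: pd.DataFrame, path: str | Path) -> None:
    # %.17g round-trips IEEE doubles exactly through text
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"design table {path} lacks columns: {sorted(missing)}")
    return df


def read_taxon_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"protein_id", "taxon"} <= set(df.columns):
        raise ParseError(f"taxon map {path} needs columns protein_id, taxon")
    return dict(zip(df["protein_id"], df["taxon"]))
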