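"""Search-database construction.

Builds the protein search database from nucleotide contigs: six-frame ORF
extraction under the standard genetic code, redundancy removal by greedy
identity clustering, optional contaminant concatenation, and a reversed-
sequence decoy database appended for target-decoy FDR estimation.

ORFs are stop-to-stop by default — every maximal stop-free stretch in each
of the six reading frames, matching the behaviour of classic ORF finders —
with an optional mode requiring an initiator methionine. Codons containing
N translate to X.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from . import quant
from .io import ParseError, ProteinRecord, ValidationError

logger = logging.getLogger(__name__)

DECOY_PREFIX = "rev_"
DEFAULT_MIN_ORF_LENGTH = 40  # residues

_NUCLEOTIDES = set("ACGTN")


@dataclass(frozen=True)
class OrfRecord:
    """An open reading frame located on a contig.

    Coordinates are 1-based inclusive nucleotide positions on the forward
    strand regardless of frame; ``frame`` is +1..+3 (forward) or -1..-3
    (reverse complement). The protein excludes any stop codon.
    """

    source_contig: str
    frame: int
    start: int
    end: int
    protein: str

    def __post_init__(self) -> None:
        span = self.end - self.start + 1
        if span % 3 != 0:
            raise ValidationError(f"ORF span {span} nt is not a whole number of codons")
        if "*" in self.protein:
            raise ValidationError("ORF protein must not contain a stop symbol")
        if len(self.protein) != span // 3:
            raise ValidationError("ORF protein length does not match its codon count")


def _translate(codons: str) -> str:
    """Translate under the standard code; any N-containing codon gives X."""
    prot = []
    for i in range(0, len(codons) - len(codons) % 3, 3):
        codon = codons[i : i + 3]
        prot.append("X" if "N" in codon else str(Seq(codon).translate(table=1)))
    return "".join(prot)


def extract_orfs(
    contig: str,
    min_length: int = DEFAULT_MIN_ORF_LENGTH,
    *,
    contig_id: str = "contig",
    require_start: bool = False,
) -> list[OrfRecord]:
    """Six-frame ORF extraction from one nucleotide sequence.

    Returns every maximal stop-free region of at least *min_length* residues
    in all six frames (stop-to-stop convention); with ``require_start`` each
    region is trimmed to begin at its first methionine. Reverse-frame
    coordinates are reported on the forward strand.
    """
    if min_length < 1:
        raise ValidationError("min_length must be >= 1")
    seq = contig.upper()
    bad = set(seq) - _NUCLEOTIDES
    if bad:
        raise ParseError(f"non-nucleotide characters in contig: {sorted(bad)}")
    L = len(seq)
    rc = str(Seq(seq).reverse_complement())
    orfs: list[OrfRecord] = []
    for strand, s in ((1, seq), (-1, rc)):
        for offset in range(3):
            frame = strand * (offset + 1)
            framed = s[offset:]
            framed = framed[: len(framed) - len(framed) % 3]
            protein = _translate(framed)
            # split on stops, tracking codon offsets
            pos = 0
            for segment in protein.split("*"):
                start_codon = pos
                pos += len(segment) + 1  # skip the stop
                if require_start:
                    m = segment.find("M")
                    if m < 0:
                        continue
                    start_codon += m
                    segment = segment[m:]
                if len(segment) < min_length:
                    continue
                nt_start = offset + 3 * start_codon          # 0-based on this strand
                nt_end = nt_start + 3 * len(segment) - 1
                if strand == 1:
                    start, end = nt_start + 1, nt_end + 1
                else:  # map reverse-complement coords back to the forward strand
                    start, end = L - nt_end, L - nt_start
                orfs.append(
                    OrfRecord(
                        source_contig=contig_id,
                        frame=frame,
                        start=start,
                        end=end,
                        protein=segment,
                    )
                )
    return orfs


def make_decoys(targets: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target, ids prefixed with ``rev_``."""
    if not targets:
        raise ValidationError("cannot build decoys for an empty target database")
    ids = [t.id for t in targets]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate target ids: {dupes}")
    palindromes = [t.id for t in targets if t.sequence == t.sequence[::-1]]
    if palindromes:
        logger.warning(
            "%d decoy(s) identical to their target (palindromic sequences): %s",
            len(palindromes), ", ".join(palindromes),
        )
    return [
        ProteinRecord(id=DECOY_PREFIX + t.id, sequence=t.sequence[::-1], taxon=t.taxon)
        for t in targets
    ]


def deduplicate(
    records: Sequence[ProteinRecord],
    identity_threshold: float = quant.DEFAULT_IDENTITY_THRESHOLD,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Collapse redundant sequences by greedy identity clustering.

    Returns the cluster representatives (each cluster's longest member) and
    a member-id -> representative-id map. Idempotent: re-deduplicating the
    representatives changes nothing.
    """
    if not records:
        return [], {}
    groups = quant.greedy_cluster(records, identity_threshold)
    by_id = {r.id: r for r in records}
    reps = [by_id[g.seed_id] for g in groups]
    membership = {m: g.seed_id for g in groups for m in g.member_ids}
    return reps, membership


@dataclass
class SearchDatabase:
    """Targets + contaminants with their appended reversed decoys."""

    targets: list[ProteinRecord]
    contaminants: list[ProteinRecord]
    decoys: list[ProteinRecord]

    @property
    def all_records(self) -> list[ProteinRecord]:
        return [*self.targets, *self.contaminants, *self.decoys]


def build_search_database(
    targets: Sequence[ProteinRecord],
    contaminants: Sequence[ProteinRecord] = (),
) -> SearchDatabase:
    """Concatenate targets and contaminants and append their decoys."""
    combined = [*targets, *contaminants]
    decoys = make_decoys(combined)
    ids = [r.id for r in combined] + [d.id for d in decoys]
    if len(set(ids)) != len(ids):
        raise ValidationError("id collision between targets/contaminants and decoys")
    return SearchDatabase(targets=list(targets), contaminants=list(contaminants), decoys=decoys)
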