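"""Annotation-guided residue screening.

Classifies query proteins by the state of named functional residues read
off a global alignment to an annotated reference:

* peptidoglycan recognition proteins (PGRPs): a set of conserved
  active-site residues confers amidase (peptidoglycan-cleaving) activity,
  and loss of any single one abolishes it; separate binding-groove
  residues set the preference for DAP-type peptidoglycan, the cell-wall
  type of gram-negative bacteria;
* annelid extracellular hemoglobin chains: a cysteine at a conserved
  position that is not engaged in a disulfide bond ("free cysteine") is
  associated with reversible hydrogen-sulfide binding.

Annotated positions and their expected residue sets are user data (TSV),
not hardcoded: build them from published reference alignments for the
protein family of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import ParseError, ValidationError

ROLES = ("active_site", "binding_groove", "sulfide_cysteine", "conserved_disulfide_cysteine")

_AA_OK = set("ACDEFGHIKLMNPQRSTVWYXBZ")


@dataclass(frozen=True)
class SiteAnnotation:
    position: int                 # 1-based residue index on the reference
    role: str
    expected: frozenset[str]      # acceptable residues at this position

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if not self.expected:
            raise ValidationError(f"annotation at position {self.position} has no expected residues")


@dataclass
class AnnotatedReference:
    """A reference protein with named functional positions."""

    id: str
    sequence: str
    sites: list[SiteAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for site in self.sites:
            if not 1 <= site.position <= len(self.sequence):
                raise ValidationError(
                    f"annotation position {site.position} outside reference {self.id} "
                    f"(length {len(self.sequence)})"
                )


@dataclass
class ScreenReport:
    query_id: str
    role_counts: dict[str, tuple[int, int]]   # role -> (matched, total annotated)
    amidase_call: str                         # active | inactive | indeterminate
    groove_call: str                          # DAP_type | other | indeterminate
    free_cysteine: bool
    unmapped_positions: int


def _make_aligner(gap_open: float = 10.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    query: str,
    reference: str,
    *,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> list[int | None]:
    """Needleman-Wunsch position map from reference to query.

    Returns a list of length ``len(reference)`` whose i-th entry is the
    1-based query position aligned to reference position i+1, or None when
    that reference residue is deleted in the query. Mapped positions are
    strictly increasing. The highest-scoring alignment under BLOSUM62 with
    affine gaps is used; ties resolve to the aligner's first reported
    alignment, which is deterministic for fixed inputs.
    """
    if not query or not reference:
        raise ValidationError("global_align requires two non-empty sequences")
    query, reference = query.upper(), reference.upper()
    for name, seq in (("query", query), ("reference", reference)):
        bad = set(seq) - _AA_OK
        if bad:
            raise ParseError(f"non-amino-acid characters in {name}: {sorted(bad)}")
    alignment = _make_aligner(gap_open, gap_extend).align(reference, query)[0]
    mapping: list[int | None] = [None] * len(reference)
    for (ts, te), (qs, qe) in zip(*alignment.aligned):
        for k in range(te - ts):
            mapping[ts + k] = qs + k + 1
    return mapping


def screen_sites(
    query: str,
    reference: AnnotatedReference,
    mapping: Sequence[int | None],
) -> ScreenReport:
    """Read annotated residues through an alignment map and call the query.

    The amidase call is "active" only when every active-site position maps
    and carries an expected residue; any unmapped active-site position
    (deleted or inside an indel region in the query) makes the call
    "indeterminate", and a mapped mismatch makes it "inactive" — one lost
    active-site residue abolishes amidase activity. The groove call works
    the same way over binding_groove positions (DAP_type / other /
    indeterminate). ``free_cysteine`` is true when the query carries C at
    every annotated sulfide-binding position and that query position is
    not also claimed by a conserved-disulfide annotation.
    """
    if len(mapping) != len(reference.sequence):
        raise ValidationError("alignment map must cover the full reference")
    query = query.upper()

    matched: dict[str, int] = {r: 0 for r in ROLES}
    total: dict[str, int] = {r: 0 for r in ROLES}
    mismatched: dict[str, int] = {r: 0 for r in ROLES}
    unmapped: dict[str, int] = {r: 0 for r in ROLES}
    disulfide_qpos = {
        mapping[s.position - 1]
        for s in reference.sites
        if s.role == "conserved_disulfide_cysteine" and mapping[s.position - 1] is not None
    }
    sulfide_ok: list[bool] = []
    for site in reference.sites:
        total[site.role] += 1
        qpos = mapping[site.position - 1]
        if qpos is None:
            unmapped[site.role] += 1
            if site.role == "sulfide_cysteine":
                sulfide_ok.append(False)
            continue
        residue = query[qpos - 1]
        if residue in site.expected:
            matched[site.role] += 1
        else:
            mismatched[site.role] += 1
        if site.role == "sulfide_cysteine":
            sulfide_ok.append(residue == "C" and qpos not in disulfide_qpos)

    def call(role: str, positive: str) -> str:
        if total[role] == 0 or unmapped[role] > 0:
            return "indeterminate"
        return positive if mismatched[role] == 0 else ("inactive" if role == "active_site" else "other")

    return ScreenReport(
        query_id="query",
        role_counts={r: (matched[r], total[r]) for r in ROLES if total[r]},
        amidase_call=call("active_site", "active"),
        groove_call=call("binding_groove", "DAP_type"),
        free_cysteine=bool(sulfide_ok) and all(sulfide_ok),
        unmapped_positions=sum(unmapped.values()),
    )


def screen_query(query_id: str, query: str, reference: AnnotatedReference) -> ScreenReport:
    """Align *query* to *reference* and screen its annotated sites."""
    report = screen_sites(query, reference, global_align(query, reference.sequence))
    report.query_id = query_id
    return report


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, references: Mapping[str, str]) -> dict[str, AnnotatedReference]:
    """Load an annotation TSV (ref_id, position, role, expected_residues).

    *references* maps reference ids to their sequences; every annotated id
    must be present. ``expected_residues`` is a string of acceptable
    one-letter residues (e.g. ``H`` or ``HY``).
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"ref_id", "position", "role", "expected_residues"}
    if not needed <= set(df.columns):
        raise ParseError(f"annotation file {path} needs columns {sorted(needed)}")
    out: dict[str, AnnotatedReference] = {}
    for ref_id, sub in df.groupby("ref_id"):
        if ref_id not in references:
            raise ValidationError(f"annotation references unknown protein {ref_id!r}")
        sites = [
            SiteAnnotation(
                position=int(row.position),
                role=str(row.role),
                expected=frozenset(str(row.expected_residues).upper()),
            )
            for row in sub.itertuples()
        ]
        out[ref_id] = AnnotatedReference(id=ref_id, sequence=references[ref_id], sites=sites)
    return out


def reports_to_frame(reports: Sequence[ScreenReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row: dict = {
            "query_id": r.query_id,
            "amidase_call": r.amidase_call,
            "groove_call": r.groove_call,
            "free_cysteine": r.free_cysteine,
            "unmapped_positions": r.unmapped_positions,
        }
        for role, (m, t) in r.role_counts.items():
            row[f"{role}_matched"] = m
            row[f"{role}_total"] = t
        rows.append(row)
    return pd.DataFrame(rows)
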