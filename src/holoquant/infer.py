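"""In-silico tryptic digestion, target-decoy q-values, identification filters.

Spectral identifications arrive as PSM (peptide-spectrum match) tables that
already carry a score and a target/decoy label; this module estimates
q-values from the decoy score distribution and applies the acceptance
filters: a PSM q-value ceiling, a minimum spectral count per protein group,
and the group-evidence rule (at least two distinct peptides, at least one
of them unique to the group). A protein-level FDR is reported alongside by
subjecting mirror-image decoy groups to the same filters.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ConfigurationError, ValidationError
from .quant import ProteinGroup

logger = logging.getLogger(__name__)

# trypsin cleaves C-terminal of K or R, never before proline
_TRYPSIN_SITE = re.compile(r"(?<=[KR])(?!P)")


def cleavage_fragments(protein: str) -> list[str]:
    """Minimal tryptic fragments of *protein*, in N->C order."""
    if not protein:
        return []
    return _TRYPSIN_SITE.split(protein.upper())


def digest(protein: str, missed_cleavages: int = 2, min_len: int = 5) -> set[str]:
    """Fully-tryptic peptides with up to *missed_cleavages* internal sites.

    Cleavage occurs after K or R except when the next residue is P. Both
    peptide termini are tryptic or protein termini. Peptides shorter than
    *min_len* residues are discarded.
    """
    if missed_cleavages < 0:
        raise ValidationError("missed_cleavages must be >= 0")
    frags = cleavage_fragments(protein)
    peptides: set[str] = set()
    for i in range(len(frags)):
        pep = ""
        for j in range(i, min(i + missed_cleavages + 1, len(frags))):
            pep += frags[j]
            if len(pep) >= min_len:
                peptides.add(pep)
    return peptides


def compute_qvalues(psms: pd.DataFrame) -> pd.DataFrame:
    """Assign target-decoy q-values to a PSM table.

    PSMs are ranked by score descending; at each threshold the FDR estimate
    is (#decoys at or above) / max(1, #targets at or above), capped at 1.
    The q-value is the running minimum of this estimate from the worst
    score upward, so it is non-increasing in score. Tied scores are treated
    as one block and share the q-value computed from the cumulative counts
    through the whole block. Returns a copy with a ``q_value`` column.
    """
    out = psms.copy()
    if out.empty:
        out["q_value"] = pd.Series(dtype=float)
        return out
    order = np.argsort(-out["score"].to_numpy(), kind="stable")
    scores = out["score"].to_numpy()[order]
    decoy = out["is_decoy"].to_numpy()[order].astype(bool)
    cum_d = np.cumsum(decoy)
    cum_t = np.cumsum(~decoy)
    fdr = cum_d / np.maximum(1, cum_t)
    # ties share the FDR at the end of their block
    n = len(fdr)
    is_block_end = np.append(scores[1:] != scores[:-1], True)
    idx = np.where(is_block_end, np.arange(n), n)
    block_last = np.minimum.accumulate(idx[::-1])[::-1]
    block_fdr = fdr[block_last]
    qvals = np.minimum.accumulate(np.minimum(block_fdr, 1.0)[::-1])[::-1]
    q = np.empty(len(out))
    q[order] = qvals
    out["q_value"] = q
    return out


@dataclass
class FilterPolicy:
    """Identification acceptance thresholds.

    max_q: PSM q-value ceiling. min_spectra_per_protein: minimum spectra
    per retained group. min_distinct_peptides: protein-level distinct
    peptide requirement (1 keeps small or fragmented proteins
    identifiable). min_group_distinct/min_group_unique: group-evidence
    rule. protein_fdr_report_threshold: flag level for the reported
    protein-level FDR.
    """

    max_q: float = 0.02
    min_spectra_per_protein: int = 2
    min_distinct_peptides: int = 1
    min_group_distinct: int = 2
    min_group_unique: int = 1
    protein_fdr_report_threshold: float = 0.03

    def __post_init__(self) -> None:
        for name in (
            "max_q",
            "min_spectra_per_protein",
            "min_distinct_peptides",
            "min_group_distinct",
            "min_group_unique",
            "protein_fdr_report_threshold",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"FilterPolicy.{name} must be >= 0")


def _group_evidence(
    psms: pd.DataFrame, assignment: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Per-group spectra / distinct / unique tallies from a PSM table."""
    counts = psms.groupby("peptide").size()
    rows: dict[str, dict[str, float]] = {}
    for pep, n in counts.items():
        hits = assignment.get(pep)
        if not hits:
            continue
        for gid in hits:
            row = rows.setdefault(gid, {"spectra": 0, "distinct": 0, "unique": 0})
            row["spectra"] += int(n)
            row["distinct"] += 1
            if len(hits) == 1:
                row["unique"] += 1
    if not rows:
        return pd.DataFrame(columns=["spectra", "distinct", "unique"])
    return pd.DataFrame.from_dict(rows, orient="index")


def filter_identifications(
    psms: pd.DataFrame,
    groups: Sequence[ProteinGroup],
    assignment: Mapping[str, Sequence[str]],
    policy: FilterPolicy | None = None,
    decoy_assignment: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, list[ProteinGroup], dict]:
    """Apply the identification filters; return (kept PSMs, kept groups, report).

    PSMs above the q-value ceiling are dropped first. A group is retained
    when its remaining evidence (summed over samples) reaches the spectral
    floor and satisfies the group rule: at least ``min_group_distinct``
    distinct peptides of which at least ``min_group_unique`` are unique to
    the group. When *decoy_assignment* maps reversed peptides to decoy
    groups, the same filters are run on the decoy side and the report
    carries protein-level FDR = passing decoy groups / passing target
    groups, flagged when above the report threshold.
    """
    policy = policy or FilterPolicy()
    if "q_value" not in psms.columns:
        raise ValidationError("PSMs must carry q_value; run compute_qvalues first")
    kept_psms = psms[psms["q_value"] <= policy.max_q]
    targets = kept_psms[kept_psms["is_decoy"] == 0]

    evidence = _group_evidence(targets, assignment)
    passing_ids = set(
        evidence[
            (evidence["spectra"] >= policy.min_spectra_per_protein)
            & (evidence["distinct"] >= max(policy.min_distinct_peptides, policy.min_group_distinct))
            & (evidence["unique"] >= policy.min_group_unique)
        ].index
    )
    kept_groups = [g for g in groups if g.group_id in passing_ids]

    report: dict = {
        "psms_total": int(len(psms)),
        "psms_passing_q": int(len(kept_psms)),
        "target_groups_passing": len(kept_groups),
        "protein_fdr": None,
        "protein_fdr_flagged": False,
    }
    if decoy_assignment is not None:
        decoys = kept_psms[kept_psms["is_decoy"] == 1]
        dev = _group_evidence(decoys, decoy_assignment)
        n_decoy_pass = int(
            (
                (dev["spectra"] >= policy.min_spectra_per_protein)
                & (dev["distinct"] >= max(policy.min_distinct_peptides, policy.min_group_distinct))
                & (dev["unique"] >= policy.min_group_unique)
            ).sum()
        ) if not dev.empty else 0
        fdr = n_decoy_pass / max(1, len(kept_groups))
        report["decoy_groups_passing"] = n_decoy_pass
        report["protein_fdr"] = fdr
        if fdr > policy.protein_fdr_report_threshold:
            report["protein_fdr_flagged"] = True
            logger.warning(
                "protein-level FDR %.3f exceeds the report threshold %.3f",
                fdr, policy.protein_fdr_report_threshold,
            )
    return kept_psms, kept_groups, report


def decoy_group_assignment(
    peptides: Sequence[str], assignment: Mapping[str, Sequence[str]]
) -> dict[str, list[str]]:
    """Map decoy (reversed) peptides onto mirror-image decoy groups.

    Reversing every target sequence reverses its peptides in place, so the
    decoy database inherits the target grouping structure; a decoy peptide
    therefore belongs to the decoy mirrors of the groups its reversal
    belongs to.
    """
    out: dict[str, list[str]] = {}
    for pep in dict.fromkeys(peptides):
        hits = assignment.get(pep[::-1])
        if hits:
            out[pep] = list(hits)
    return out
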