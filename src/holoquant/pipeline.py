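"""End-to-end quantification pipeline.

Chains the post-search stages in the order the analysis runs: q-value
assignment, protein grouping, peptide-uniqueness re-assessment,
identification filtering, shared-spectra balancing, nSpC normalization and
host/symbiont aggregation. Each stage remains individually callable from
its own module; this wrapper fixes the data flow between them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import infer, quant
from .infer import FilterPolicy
from .io import ProteinRecord
from .quant import ProteinGroup, QuantMatrix


@dataclass
class PipelineResult:
    groups: list[ProteinGroup]          # groups retained by the filters
    psms: pd.DataFrame                  # PSMs passing the q-value ceiling
    balanced: pd.DataFrame              # group x sample balanced counts
    quant: QuantMatrix
    fractions: pd.DataFrame             # per-sample host/symbiont totals and fraction
    filter_report: dict


def run_quantification(
    database: Sequence[ProteinRecord],
    psms: pd.DataFrame,
    *,
    design: pd.DataFrame | None = None,
    policy: FilterPolicy | None = None,
    identity_threshold: float = quant.DEFAULT_IDENTITY_THRESHOLD,
    universe: str = "all",
    scale: str = "fraction",
    weight_by: str = "spectra",
    length_mode: str = "seed",
    groups: list[ProteinGroup] | None = None,
    assignment: Mapping[str, Sequence[str]] | None = None,
) -> PipelineResult:
    """Run the post-search analysis on a database and its PSM table.

    *database* holds target (non-decoy) proteins; decoy matches are
    expected only as rows of *psms* with ``is_decoy == 1`` and are used for
    q-value and protein-FDR estimation, then discarded. Precomputed
    *groups* and peptide->group *assignment* (covering at least the
    observed peptides) may be passed to amortize clustering and substring
    search across repeated simulations on the same database.
    """
    qpsms = infer.compute_qvalues(psms)
    if groups is None:
        groups = quant.greedy_cluster(database, identity_threshold)

    target_peptides = qpsms.loc[qpsms["is_decoy"] == 0, "peptide"].unique()
    if assignment is None:
        assignment = quant.reassess_uniqueness(target_peptides, groups)
    else:
        assignment = {p: assignment[p] for p in target_peptides if p in assignment}
    decoy_peptides = qpsms.loc[qpsms["is_decoy"] == 1, "peptide"].unique()
    decoy_assignment = infer.decoy_group_assignment(list(decoy_peptides), assignment)

    kept_psms, kept_groups, report = infer.filter_identifications(
        qpsms, groups, assignment, policy, decoy_assignment
    )
    kept_targets = kept_psms[kept_psms["is_decoy"] == 0]

    # uniqueness is re-assessed against the retained groups so that the
    # balancing weights reflect the groups actually quantified
    kept_ids = {g.group_id for g in kept_groups}
    final_assignment = {}
    for pep, hits in assignment.items():
        hits = [g for g in hits if g in kept_ids]
        if hits:
            final_assignment[pep] = hits
    for g in kept_groups:
        g.distinct_peptides = set()
        g.unique_peptides = set()
    by_id = {g.group_id: g for g in kept_groups}
    for pep, hits in final_assignment.items():
        for gid in hits:
            by_id[gid].distinct_peptides.add(pep)
        if len(hits) == 1:
            by_id[hits[0]].unique_peptides.add(pep)

    counts = (
        kept_targets.groupby(["sample_id", "peptide"], sort=False)
        .size()
        .rename("count")
        .reset_index()
    )
    balanced = quant.balance_spectra(counts, final_assignment, kept_groups, weight_by=weight_by)
    qm = quant.compute_nspc(
        balanced,
        quant.group_lengths(kept_groups, length_mode),
        {g.group_id: g.taxon for g in kept_groups},
        universe=universe,
        scale=scale,
    )
    fractions = quant.taxon_fractions(qm, design)
    return PipelineResult(
        groups=kept_groups,
        psms=kept_psms,
        balanced=balanced,
        quant=qm,
        fractions=fractions,
        filter_report=report,
    )


def digest_assignment(
    database: Sequence[ProteinRecord],
    groups: Sequence[ProteinGroup],
    missed_cleavages: int = 2,
    min_len: int = 5,
) -> dict[str, list[str]]:
    """Peptide->group map for every fully-tryptic peptide of the database.

    Convenience for repeated simulations: computes the uniqueness
    assignment once over the whole digest universe instead of once per
    observed PSM table.
    """
    peptides = sorted(
        {p for rec in database for p in infer.digest(rec.sequence, missed_cleavages, min_len)}
    )
    return quant.reassess_uniqueness(peptides, list(groups))
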