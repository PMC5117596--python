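"""Protein grouping and spectral-count quantification.

The quantification core of the pipeline:

1. greedy centroid clustering of database proteins at >=90% global-alignment
   identity, each group represented by its longest member (the seed);
2. re-assessment of peptide uniqueness at the group level;
3. balancing of shared-peptide spectral counts among sharing groups in
   proportion to their unique evidence;
4. conversion of balanced counts to normalized spectral counts (nSpC), the
   length-corrected relative abundance measure derived from NSAF:
   ``nSpC_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)`` over a configurable
   normalization universe (all groups, host-only, or within each taxon);
5. aggregation to per-sample host/symbiont abundance fractions.

Identity between two proteins is computed from a global (Needleman-Wunsch)
alignment under BLOSUM62 with affine gaps (open 10, extend 1) and reported
as identical aligned residues divided by the length of the shorter
sequence — the centroid-clustering convention, which makes a fragment that
matches part of a longer protein 100% identical to it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io import ProteinRecord, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.9

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner(gap_open: float = 10.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class ProteinGroup:
    """A cluster of proteins quantified as one unit.

    The seed is the longest member; every member aligns to the seed at or
    above the clustering identity threshold.
    """

    group_id: str
    seed_id: str
    seed_sequence: str
    member_ids: list[str] = field(default_factory=list)
    member_sequences: dict[str, str] = field(default_factory=dict)
    taxon: str = "host"
    distinct_peptides: set[str] = field(default_factory=set)
    unique_peptides: set[str] = field(default_factory=set)

    @property
    def seed_length(self) -> int:
        return len(self.seed_sequence)

    @property
    def mean_member_length(self) -> float:
        return float(np.mean([len(s) for s in self.member_sequences.values()]))


# ---------------------------------------------------------------------------
# pairwise identity and greedy clustering
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity on the scale of the shorter sequence.

    Identity = identical aligned residue pairs / len(shorter). The ambiguity
    residue X never counts as identical, even against another X. Symmetric in
    its arguments; raises ValidationError on empty input.
    """
    if not a or not b:
        raise ValidationError("pairwise_identity requires two non-empty sequences")
    a, b = a.upper(), b.upper()
    min_len = min(len(a), len(b))
    if a == b:
        return sum(c != "X" for c in a) / len(a)
    # exact containment: the shorter aligns gap-free inside the longer
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    if short in long_:
        return sum(c != "X" for c in short) / min_len
    alignment = _ALIGNER.align(a, b)[0]
    ident = 0
    for (ts, te), (qs, qe) in zip(*alignment.aligned):
        for ca, cb in zip(a[ts:te], b[qs:qe]):
            if ca == cb and ca != "X":
                ident += 1
    return ident / min_len


def _identity_upper_bound(a: str, b: str) -> float:
    """Cheap upper bound on pairwise_identity via unit-cost edit distance.

    Any alignment has at most (|a|+|b|-d)/2 matching columns, d being the
    Levenshtein distance; used to skip full alignments during clustering.
    """
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return ((len(a) + len(b) - d) / 2) / min(len(a), len(b))


def greedy_cluster(
    records: Sequence[ProteinRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> list[ProteinGroup]:
    """Greedy centroid clustering in length-descending order.

    Records are visited sorted by length descending (ties broken by id);
    each record joins the first seed, in founding order, with identity >=
    *threshold*, otherwise it founds a new group. The first (longest)
    member of a group is therefore always its seed.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValidationError(f"identity threshold must be in (0, 1], got {threshold}")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    groups: list[ProteinGroup] = []
    for rec in ordered:
        home = None
        for grp in groups:
            seed = grp.seed_sequence
            if _identity_upper_bound(rec.sequence, seed) < threshold:
                continue
            if pairwise_identity(rec.sequence, seed) >= threshold:
                home = grp
                break
        if home is None:
            home = ProteinGroup(
                group_id=rec.id,
                seed_id=rec.id,
                seed_sequence=rec.sequence,
                taxon=rec.taxon,
            )
            groups.append(home)
        home.member_ids.append(rec.id)
        home.member_sequences[rec.id] = rec.sequence
    return groups


# ---------------------------------------------------------------------------
# peptide uniqueness and spectral balancing
# ---------------------------------------------------------------------------

def reassess_uniqueness(
    peptides: Iterable[str],
    groups: Sequence[ProteinGroup],
) -> dict[str, list[str]]:
    """Map each peptide to the protein groups whose members contain it.

    Membership is substring search against every member sequence. A peptide
    is *unique* when the returned list has length one, *shared* otherwise.
    Peptides matching no protein are orphans: excluded from the map with a
    logged warning. Also refreshes each group's distinct/unique peptide sets.
    """
    assignment: dict[str, list[str]] = {}
    orphans = []
    for grp in groups:
        grp.distinct_peptides = set()
        grp.unique_peptides = set()
    for pep in dict.fromkeys(peptides):  # preserve order, drop duplicates
        hits = [
            grp.group_id
            for grp in groups
            if any(pep in seq for seq in grp.member_sequences.values())
        ]
        if not hits:
            orphans.append(pep)
            continue
        assignment[pep] = hits
    if orphans:
        logger.warning(
            "%d peptide(s) matched no database protein and were excluded: %s%s",
            len(orphans), ", ".join(orphans[:5]), "..." if len(orphans) > 5 else "",
        )
    by_id = {g.group_id: g for g in groups}
    for pep, hits in assignment.items():
        for gid in hits:
            by_id[gid].distinct_peptides.add(pep)
        if len(hits) == 1:
            by_id[hits[0]].unique_peptides.add(pep)
    return assignment


def balance_spectra(
    peptide_counts: pd.DataFrame,
    assignment: Mapping[str, Sequence[str]],
    groups: Sequence[ProteinGroup],
    *,
    weight_by: str = "spectra",
) -> pd.DataFrame:
    """Distribute spectral counts over protein groups, balancing shared peptides.

    Parameters
    ----------
    peptide_counts
        Long-format table with columns ``sample_id``, ``peptide``, ``count``.
    assignment
        Peptide -> sharing group ids, from :func:`reassess_uniqueness`.
        Peptides absent from the map are ignored (orphans).
    groups
        The protein groups; defines the row universe of the result.
    weight_by
        ``"spectra"`` (default) weights each sharing group by its unique
        spectral counts in that sample; ``"peptides"`` weights by its number
        of unique peptide species observed in that sample.

    Per sample, each group first receives the counts of its unique peptides
    (U_g); every shared peptide's count is then split among its sharing
    groups proportionally to U_g, or equally when all sharing groups have
    U_g = 0. Total counts are conserved per sample.
    """
    if weight_by not in ("spectra", "peptides"):
        raise ValidationError(f"weight_by must be 'spectra' or 'peptides', got {weight_by!r}")
    required = {"sample_id", "peptide", "count"}
    if not required <= set(peptide_counts.columns):
        raise ValidationError(f"peptide_counts needs columns {sorted(required)}")
    if (peptide_counts["count"] < 0).any():
        raise ValidationError("negative spectral counts are not allowed")

    group_ids = [g.group_id for g in groups]
    gid_row = {g: i for i, g in enumerate(group_ids)}
    samples = list(pd.unique(peptide_counts["sample_id"]))
    out = np.zeros((len(group_ids), len(samples)))

    for j, sample in enumerate(samples):
        sub = peptide_counts[peptide_counts["sample_id"] == sample]
        counts = dict(sub.groupby("peptide")["count"].sum())
        unique_spectra = np.zeros(len(group_ids))
        unique_species = np.zeros(len(group_ids))
        shared: list[tuple[float, Sequence[str]]] = []
        for pep, n in counts.items():
            hits = assignment.get(pep)
            if hits is None:
                continue
            if len(hits) == 1:
                row = gid_row[hits[0]]
                unique_spectra[row] += float(n)
                if n > 0:
                    unique_species[row] += 1.0
            else:
                shared.append((float(n), hits))
        weights = unique_spectra if weight_by == "spectra" else unique_species
        col = unique_spectra.copy()
        for n, hits in shared:
            rows = [gid_row[g] for g in hits]
            total = weights[rows].sum()
            if total > 0:
                col[rows] += n * weights[rows] / total
            else:  # no unique evidence anywhere: split equally
                col[rows] += n / len(rows)
        out[:, j] = col
    return pd.DataFrame(out, index=pd.Index(group_ids, name="group_id"), columns=samples)


# ---------------------------------------------------------------------------
# nSpC normalization
# ---------------------------------------------------------------------------

@dataclass
class QuantMatrix:
    """Protein-group x sample matrix of nSpC values."""

    values: pd.DataFrame          # groups x samples
    taxa: pd.Series               # group_id -> host|symbiont|contaminant
    universe: str                 # all | host | per_taxon
    scale: str                    # fraction | per_10000


def group_lengths(groups: Sequence[ProteinGroup], mode: str = "seed") -> dict[str, float]:
    """Group length used for the NSAF length correction (seed or mean member)."""
    if mode == "seed":
        return {g.group_id: float(g.seed_length) for g in groups}
    if mode == "mean":
        return {g.group_id: g.mean_member_length for g in groups}
    raise ValidationError(f"length mode must be 'seed' or 'mean', got {mode!r}")


def compute_nspc(
    balanced: pd.DataFrame,
    lengths: Mapping[str, float],
    taxa: Mapping[str, str],
    *,
    universe: str = "all",
    scale: str = "fraction",
) -> QuantMatrix:
    """Convert balanced spectral counts to normalized spectral counts.

    SAF_i = SpC_i / L_i; nSpC_i = SAF_i / sum of SAF over the normalization
    universe in the same sample. ``universe="all"`` normalizes over every
    group, ``"host"`` over host groups only (groups outside the universe are
    reported on the same scale factor), ``"per_taxon"`` normalizes each
    taxon within itself. ``scale="per_10000"`` multiplies by 10,000, the
    convention under which host-universe nSpC sums to 10,000 per sample.
    """
    if universe not in ("all", "host", "per_taxon"):
        raise ValidationError(f"unknown universe {universe!r}")
    if scale not in ("fraction", "per_10000"):
        raise ValidationError(f"unknown scale {scale!r}")
    L = pd.Series({g: float(lengths[g]) for g in balanced.index}, name="length")
    if (L <= 0).any():
        raise ValidationError("all group lengths must be positive")
    taxa_s = pd.Series({g: taxa[g] for g in balanced.index}, name="taxon")
    saf = balanced.div(L, axis=0)

    if universe == "per_taxon":
        denom = saf.groupby(taxa_s).transform("sum")
    else:
        rows = saf.index if universe == "all" else saf.index[taxa_s == "host"]
        denom_row = saf.loc[rows].sum(axis=0)
        denom = pd.DataFrame(
            np.broadcast_to(denom_row.to_numpy(), saf.shape), index=saf.index, columns=saf.columns
        )
    zero_cols = (denom == 0).all(axis=0) if universe != "per_taxon" else (denom == 0).any(axis=0)
    if zero_cols.any():
        logger.warning(
            "zero total SAF in the normalization universe for sample(s) %s; emitting zeros",
            list(denom.columns[zero_cols]),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        nspc = saf.div(denom).fillna(0.0).replace([np.inf, -np.inf], 0.0)
    if scale == "per_10000":
        nspc = nspc * 10_000.0
    return QuantMatrix(values=nspc, taxa=taxa_s, universe=universe, scale=scale)


def taxon_fractions(quant: QuantMatrix, design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-sample symbiont fraction of the holobiont (host + symbiont) signal.

    Contaminant groups are excluded from both numerator and denominator.
    Returns one row per sample with columns ``symbiont_fraction``,
    ``host_total`` and ``symbiont_total``; samples with zero holobiont
    signal get NaN. With a *design* table the per-condition mean, sd and n
    of the fraction are attached as a ``.attrs['condition_summary']`` frame.
    """
    taxa = quant.taxa
    host_total = quant.values.loc[taxa == "host"].sum(axis=0)
    sym_total = quant.values.loc[taxa == "symbiont"].sum(axis=0)
    holo = host_total + sym_total
    frac = sym_total.where(holo > 0) / holo.where(holo > 0)
    out = pd.DataFrame(
        {"host_total": host_total, "symbiont_total": sym_total, "symbiont_fraction": frac}
    )
    out.index.name = "sample_id"
    if design is not None:
        merged = out.reset_index().merge(design, on="sample_id", how="left")
        summary = (
            merged.groupby("condition")["symbiont_fraction"]
            .agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
            .reset_index()
        )
        out.attrs["condition_summary"] = summary
    return out
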