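"""Synthetic holobiont metaproteome generator.

Emulates the statistical structure the downstream analysis assumes: a
two-taxon (host + symbiont) protein database containing near-redundant
variant families, and per-sample PSM tables for a two-condition design
(freshly collected vs starved animals, three biological replicates each)
in which the symbiont share of total spectra is higher in fresh samples
than in starved ones, with replicate-level sampling noise.

The generative model, per sample:

1. the sample's symbiont spectral fraction is the condition value perturbed
   by multiplicative Gaussian noise (sd ``replicate_noise_sd``), clamped to
   [0, 1];
2. each of ``spectra_per_sample`` spectra first draws a taxon by that
   fraction, then a protein within the taxon with probability proportional
   to abundance weight x protein length (longer proteins yield more
   spectra — the premise of the NSAF length correction), then one of the
   protein's observable fully-tryptic peptides uniformly;
3. decoy matches (reversed peptides, scores stochastically below the
   target score distribution) are appended at a configurable fraction of
   all matches.

Per-protein abundance weights are log-normal within taxon. Ground truth
(weights, family membership, realized per-sample fractions) is returned
for recovery tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .infer import digest
from .io import ConfigurationError, GenerationError, ProteinRecord

#: log-scale sd of within-taxon protein abundance weights
ABUNDANCE_SIGMA = 0.8
#: target PSM score distribution; decoys sit two sds below
TARGET_SCORE_MEAN = 10.0
SCORE_SD = 1.0
#: search-like digestion settings for observable peptides
MISSED_CLEAVAGES = 2
MIN_PEPTIDE_LENGTH = 5


@dataclass
class GeneratorConfig:
    n_host_proteins: int = 120
    n_symbiont_proteins: int = 80
    n_variant_families: int = 12
    variant_identity: float = 0.95
    protein_length_range: tuple[int, int] = (150, 450)
    conditions: list[tuple[str, float]] = field(
        default_factory=lambda: [("fresh", 0.295), ("starved", 0.187)]
    )
    n_replicates: int = 3
    spectra_per_sample: int = 50_000
    replicate_noise_sd: float = 0.03
    decoy_fraction_of_matches: float = 0.05
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("n_host_proteins", "n_symbiont_proteins", "n_replicates", "spectra_per_sample"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.n_variant_families < 0:
            raise ConfigurationError("n_variant_families must be >= 0")
        if not 0.0 <= self.variant_identity <= 1.0:
            raise ConfigurationError("variant_identity must lie in [0, 1]")
        lo, hi = self.protein_length_range
        if lo < 20 or hi < lo:
            raise ConfigurationError(
                "protein_length_range must satisfy 20 <= min <= max"
            )
        if not self.conditions:
            raise ConfigurationError("conditions must list at least one (name, fraction) pair")
        for name, frac in self.conditions:
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(
                    f"conditions: symbiont fraction for {name!r} must lie in [0, 1]"
                )
        if self.replicate_noise_sd < 0:
            raise ConfigurationError("replicate_noise_sd must be >= 0")
        if not 0.0 <= self.decoy_fraction_of_matches < 1.0:
            raise ConfigurationError("decoy_fraction_of_matches must lie in [0, 1)")
        if self.n_variant_families > self.n_host_proteins + self.n_symbiont_proteins:
            raise ConfigurationError(
                "n_variant_families cannot exceed the number of base proteins"
            )


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""

    weights: dict[str, float]                    # protein id -> raw abundance weight
    family_map: dict[str, str]                   # variant id -> base id
    condition_abundance: dict[str, dict[str, float]]  # condition -> id -> abundance (sums to 1)
    realized_spectral_fraction: dict[str, float] = field(default_factory=dict)
    sample_abundance_fraction: dict[str, float] = field(default_factory=dict)
    sample_condition: dict[str, str] = field(default_factory=dict)


@lru_cache(maxsize=8192)
def _peptide_menu(sequence: str) -> tuple[str, ...]:
    """Observable peptides of one protein, cached across repeated simulations."""
    return tuple(sorted(digest(sequence, MISSED_CLEAVAGES, MIN_PEPTIDE_LENGTH)))


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(hio.AMINO_ACIDS), size=length))


def _abundance_fractions(
    records: list[ProteinRecord], weights: dict[str, float], sym_fraction: float
) -> dict[str, float]:
    """True relative abundances given a symbiont spectral fraction.

    A protein's spectra are proportional to (taxon fraction) x weight x
    length within its taxon; its underlying abundance is that divided by
    length, renormalized — the quantity nSpC estimates.
    """
    taxon_frac = {"host": 1.0 - sym_fraction, "symbiont": sym_fraction}
    wl_total = {
        t: sum(weights[r.id] * len(r) for r in records if r.taxon == t) for t in taxon_frac
    }
    alpha = {}
    for r in records:
        denom = wl_total[r.taxon]
        alpha[r.id] = taxon_frac[r.taxon] * weights[r.id] / denom if denom > 0 else 0.0
    total = sum(alpha.values())
    return {k: v / total for k, v in alpha.items()} if total > 0 else alpha


def generate_database(config: GeneratorConfig) -> tuple[list[ProteinRecord], GroundTruth]:
    """Generate the two-taxon protein database with variant families.

    Base proteins are uniform random sequences over the 20-letter alphabet
    with lengths uniform in ``protein_length_range``. ``n_variant_families``
    base proteins (chosen at random) each gain one variant produced by
    point-substituting a (1 - variant_identity) fraction of positions, so
    each variant pair has pairwise identity >= variant_identity and
    co-clusters with its base at any threshold <= variant_identity.
    Deterministic given ``rng_seed``.
    """
    config.validate()
    rng = _rng(config.rng_seed, 0)
    lo, hi = config.protein_length_range
    records: list[ProteinRecord] = []
    for taxon, n in (("host", config.n_host_proteins), ("symbiont", config.n_symbiont_proteins)):
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            records.append(
                ProteinRecord(id=f"{taxon[0].upper()}{i:04d}", sequence=_random_protein(rng, length), taxon=taxon)
            )
    family_map: dict[str, str] = {}
    if config.n_variant_families:
        base_idx = rng.choice(len(records), size=config.n_variant_families, replace=False)
        aa = np.array(list(hio.AMINO_ACIDS))
        for bi in sorted(base_idx):
            base = records[bi]
            n_sub = math.floor((1.0 - config.variant_identity) * len(base.sequence))
            seq = list(base.sequence)
            if n_sub > 0:
                positions = rng.choice(len(seq), size=n_sub, replace=False)
                for p in positions:
                    choices = aa[aa != seq[p]]
                    seq[p] = str(rng.choice(choices))
            var_id = base.id + "v"
            records.append(ProteinRecord(id=var_id, sequence="".join(seq), taxon=base.taxon))
            family_map[var_id] = base.id

    log_w = rng.normal(0.0, ABUNDANCE_SIGMA, size=len(records))
    weights = {r.id: float(np.exp(w)) for r, w in zip(records, log_w)}
    condition_abundance = {
        name: _abundance_fractions(records, weights, frac) for name, frac in config.conditions
    }
    truth = GroundTruth(weights=weights, family_map=family_map, condition_abundance=condition_abundance)
    return records, truth


def simulate_psm_table(
    database: list[ProteinRecord],
    truth: GroundTruth,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate PSM tables for every sample of the design.

    Returns ``(psms, design)``: a tidy PSM table (sample_id, spectrum_id,
    peptide, score, is_decoy) covering all samples, and the matching design
    table (sample_id, condition, replicate). Updates *truth* with each
    sample's realized symbiont spectral fraction and true abundance-level
    symbiont fraction. Deterministic given ``rng_seed``.
    """
    config.validate()
    if not database:
        raise GenerationError("cannot simulate PSMs from an empty database")
    by_taxon = {
        t: [r for r in database if r.taxon == t] for t in ("host", "symbiont")
    }
    taxon_of = {r.id: r.taxon for r in database}
    for name, frac in config.conditions:
        for taxon, tf in (("symbiont", frac), ("host", 1.0 - frac)):
            if tf > 0 and not by_taxon[taxon]:
                raise GenerationError(
                    f"condition {name!r} gives {taxon} spectra but the database has no {taxon} proteins"
                )
    peptide_menu = {r.id: _peptide_menu(r.sequence) for r in database}
    for rid, menu in peptide_menu.items():
        if not menu:
            raise GenerationError(f"protein {rid} has no observable tryptic peptide")
    all_target_peptides = sorted({p for menu in peptide_menu.values() for p in menu})

    psm_frames = []
    design_rows = []
    for ci, (condition, base_frac) in enumerate(config.conditions):
        for rep in range(1, config.n_replicates + 1):
            sample = f"{condition}_{rep}"
            rng = _rng(config.rng_seed, 1, ci, rep)
            noise = rng.normal(0.0, config.replicate_noise_sd)
            f_sym = float(np.clip(base_frac * (1.0 + noise), 0.0, 1.0))
            n_sym = int(rng.binomial(config.spectra_per_sample, f_sym))
            n_by_taxon = {"symbiont": n_sym, "host": config.spectra_per_sample - n_sym}

            peptides: list[str] = []
            for taxon in ("host", "symbiont"):
                n_tax = n_by_taxon[taxon]
                if n_tax == 0:
                    continue
                recs = by_taxon[taxon]
                probs = np.array([truth.weights[r.id] * len(r) for r in recs], dtype=float)
                probs /= probs.sum()
                counts = rng.multinomial(n_tax, probs)
                for rec, k in zip(recs, counts):
                    if k == 0:
                        continue
                    menu = peptide_menu[rec.id]
                    idx = rng.integers(0, len(menu), size=k)
                    peptides.extend(menu[i] for i in idx)
            n_targets = len(peptides)
            scores = rng.normal(TARGET_SCORE_MEAN, SCORE_SD, size=n_targets)

            fd = config.decoy_fraction_of_matches
            n_decoys = int(round(fd / (1.0 - fd) * n_targets)) if fd > 0 else 0
            if n_decoys:
                picks = rng.integers(0, len(all_target_peptides), size=n_decoys)
                decoy_peps = [all_target_peptides[i][::-1] for i in picks]
                decoy_scores = rng.normal(TARGET_SCORE_MEAN - 2.0 * SCORE_SD, SCORE_SD, size=n_decoys)
            else:
                decoy_peps, decoy_scores = [], np.empty(0)

            n_total = n_targets + n_decoys
            frame = pd.DataFrame(
                {
                    "sample_id": sample,
                    "spectrum_id": [f"{sample}_s{i:06d}" for i in range(n_total)],
                    "peptide": peptides + decoy_peps,
                    "score": np.concatenate([scores, decoy_scores]),
                    "is_decoy": [0] * n_targets + [1] * n_decoys,
                }
            )
            psm_frames.append(frame)
            design_rows.append({"sample_id": sample, "condition": condition, "replicate": rep})

            truth.realized_spectral_fraction[sample] = f_sym
            truth.sample_condition[sample] = condition
            alpha = _abundance_fractions(database, truth.weights, f_sym)
            truth.sample_abundance_fraction[sample] = sum(
                a for rid, a in alpha.items() if taxon_of[rid] == "symbiont"
            )
    psms = pd.concat(psm_frames, ignore_index=True)
    design = pd.DataFrame(design_rows)
    return psms, design


# ---------------------------------------------------------------------------
# fixture bundles on disk
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    outdir: str | Path,
    database: list[ProteinRecord],
    truth: GroundTruth,
    psms: pd.DataFrame,
    design: pd.DataFrame,
) -> dict[str, Path]:
    """Write a complete fixture (FASTA, PSM/design/taxon TSVs, truth JSON)."""
    if not database:
        raise GenerationError("refusing to write a fixture with an empty database")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "database": outdir / "database.faa",
        "psms": outdir / "psms.tsv",
        "design": outdir / "design.tsv",
        "taxon_map": outdir / "taxon_map.tsv",
        "truth": outdir / "truth.json",
    }
    hio.write_fasta(database, paths["database"])
    hio.write_psm_table(psms, paths["psms"])
    design.to_csv(paths["design"], sep="\t", index=False)
    pd.DataFrame(
        {"protein_id": [r.id for r in database], "taxon": [r.taxon for r in database]}
    ).to_csv(paths["taxon_map"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(asdict(truth), indent=1))
    return paths


def read_fixture_bundle(
    outdir: str | Path,
) -> tuple[list[ProteinRecord], GroundTruth, pd.DataFrame, pd.DataFrame]:
    """Read back a fixture bundle; inverse of :func:`write_fixture_bundle`."""
    outdir = Path(outdir)
    database = hio.read_fasta(outdir / "database.faa")
    truth = GroundTruth(**json.loads((outdir / "truth.json").read_text()))
    psms = hio.read_psm_table(outdir / "psms.tsv")
    design = hio.read_design(outdir / "design.tsv")
    return database, truth, psms, design
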