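"""Synthetic cohorts and null simulations.

Every stage of the pipeline is exercisable without any external download:
``simulate_cohort`` generates a somatic mutation table (protein dialect) with
planted hotspot residues, suppressor-like deleterious/synonymous mixes,
interface-enriched backgrounds and common-variant contamination, together
with the truth tables needed to score recovery.  ``simulate_uniform_null``
reproduces the negative control in which mutations are reassigned uniformly
along a titin-length protein, and ``simulate_codon_substitutions`` estimates
how often particular amino-acid changes arise from random single-nucleotide
events.

All generators are driven by a single integer seed and are bit-reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .filters import PopulationVariant
from .hotspots import HotspotParams, ResidueMutationProfile, build_residue_profile, detect_hotspots
from .mutmap import MutationRecord

__all__ = [
    "HotspotSpec",
    "GeneSpec",
    "CohortSpec",
    "SimulatedCohort",
    "simulate_cohort",
    "simulate_region_profile",
    "CodonSimulation",
    "simulate_codon_substitutions",
    "analytic_codon_distribution",
    "simulate_uniform_null",
    "toy_filter_fixture",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STOP = "*"

#: Sense codons grouped by encoded amino acid (standard code).
CODONS_BY_AA: Dict[str, List[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _aa in CODONS_BY_AA:
    CODONS_BY_AA[_aa].sort()
SENSE_CODONS = sorted(standard_dna_table.forward_table)
_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _c in standard_dna_table.stop_codons:
    _CODON_TO_AA[_c] = _STOP
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass(frozen=True)
class HotspotSpec:
    """A hotspot planted so its expected share of window mutations is ``share``.

    The share is defined against the largest detection window (300 residues,
    clipped at the termini); the smaller window's expected share is higher.
    ``tumor_bias`` optionally weights which tumor types carry the events.
    """

    position: int
    share: float
    tumor_bias: Optional[Dict[str, float]] = None

    def __post_init__(self):
        if not 0 < self.share <= 1:
            raise ValueError("share must lie in (0, 1]")
        if self.share >= 1.0:
            raise ValueError("share of exactly 1 leaves no room for background")


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    length: int
    background_rate: float = 0.0       # missense events per residue per sample
    hotspots: Tuple[HotspotSpec, ...] = ()
    deleterious_rate: float = 0.0      # truncating events per sample (gene-wide)
    synonymous_rate: float = 0.0       # synonymous events per sample (gene-wide)
    interface_mask: Optional[Tuple[int, ...]] = None  # 0/1 per residue
    interface_enrichment: float = 1.0
    common_variants: Tuple[Tuple[int, float], ...] = ()  # (position, frequency)

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("protein length must be >= 1")
        for rate in (self.background_rate, self.deleterious_rate, self.synonymous_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        for h in self.hotspots:
            if not 1 <= h.position <= self.length:
                raise ValueError(f"hotspot position {h.position} outside protein")
        if self.interface_mask is not None and len(self.interface_mask) != self.length:
            raise ValueError("interface mask length must equal protein length")


@dataclass(frozen=True)
class CohortSpec:
    n_samples: int
    genes: Tuple[GeneSpec, ...]
    tumor_types: Tuple[Tuple[str, float], ...] = (("PANCAN", 1.0),)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("need at least one sample")
        total = sum(p for _, p in self.tumor_types)
        if not np.isclose(total, 1.0):
            raise ValueError("tumor-type proportions must sum to 1")


@dataclass
class SimulatedCohort:
    mutations: List[MutationRecord]
    manifest: pd.DataFrame                       # sample, tumor_type
    truth_hotspots: pd.DataFrame                 # gene, position, share, planted_events
    truth_variants: List[PopulationVariant]
    gene_specs: Tuple[GeneSpec, ...]


_DETECTION_WINDOW = 300  # largest default detection window; defines planted shares


def _clipped_window(position: int, length: int, window: int = _DETECTION_WINDOW) -> int:
    half = window // 2
    lo = max(1, position - half)
    hi = min(length, position + half)
    return hi - lo + 1


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a protein-dialect mutation table with planted structure.

    Background missense events are Bernoulli per residue per sample (weighted
    up inside interface masks); each planted hotspot receives
    ``share/(1-share) * E[background in its 300-residue window]`` extra
    events in distinct samples, so its expected window share matches the
    spec.  Truncating and synonymous events are Poisson with the stated
    per-sample rates.  Identical seeds give identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"S{i:05d}" for i in range(1, spec.n_samples + 1)]
    type_labels = [t for t, _ in spec.tumor_types]
    type_probs = np.array([p for _, p in spec.tumor_types])
    assignments = rng.choice(len(type_labels), size=spec.n_samples, p=type_probs)
    sample_types = {s: type_labels[a] for s, a in zip(samples, assignments)}
    manifest = pd.DataFrame({"sample": samples,
                             "tumor_type": [sample_types[s] for s in samples]})

    mutations: List[MutationRecord] = []
    truth_rows = []
    variants: List[PopulationVariant] = []
    samples_arr = np.array(samples, dtype=object)

    for gene in spec.genes:
        seq_idx = rng.integers(0, 20, size=gene.length)
        protein = "".join(_AA20[i] for i in seq_idx)

        weights = np.full(gene.length, gene.background_rate)
        if gene.interface_mask is not None:
            mask = np.asarray(gene.interface_mask, dtype=bool)
            weights[mask] *= gene.interface_enrichment
        hotspot_positions = {h.position for h in gene.hotspots}

        for pos in range(1, gene.length + 1):
            rate = min(weights[pos - 1], 1.0)
            if rate <= 0:
                continue
            n_mut = rng.binomial(spec.n_samples, rate)
            if n_mut == 0:
                continue
            chosen = rng.choice(spec.n_samples, size=n_mut, replace=False)
            ref = protein[pos - 1]
            for ci in chosen:
                alt = _AA20[rng.integers(0, 20)]
                while alt == ref:
                    alt = _AA20[rng.integers(0, 20)]
                s = samples_arr[ci]
                mutations.append(MutationRecord(
                    sample_id=s, tumor_type=sample_types[s], gene_id=gene.gene_id,
                    residue_position=pos, ref_aa=ref, alt_aa=alt,
                    consequence="missense",
                ))

        for hs in gene.hotspots:
            w_eff = _clipped_window(hs.position, gene.length)
            window_weights = weights[
                max(0, hs.position - 1 - _DETECTION_WINDOW // 2):
                min(gene.length, hs.position + _DETECTION_WINDOW // 2)
            ]
            exp_bg = float(np.minimum(window_weights, 1.0).sum()) * spec.n_samples
            n_events = max(1, int(round(hs.share / (1 - hs.share) * exp_bg)))
            n_events = min(n_events, spec.n_samples)
            if hs.tumor_bias:
                probs = np.array([hs.tumor_bias.get(sample_types[s], 0.0) for s in samples])
                if probs.sum() == 0:
                    raise ValueError("tumor bias assigns zero weight to every sample")
                probs = probs / probs.sum()
                chosen = rng.choice(spec.n_samples, size=n_events, replace=False, p=probs)
            else:
                chosen = rng.choice(spec.n_samples, size=n_events, replace=False)
            ref = protein[hs.position - 1]
            alt = _AA20[(_AA20.index(ref) + 1) % 20]  # one recurrent substitution
            for ci in chosen:
                s = samples_arr[ci]
                mutations.append(MutationRecord(
                    sample_id=s, tumor_type=sample_types[s], gene_id=gene.gene_id,
                    residue_position=hs.position, ref_aa=ref, alt_aa=alt,
                    consequence="missense",
                ))
            truth_rows.append({
                "gene": gene.gene_id, "position": hs.position,
                "share": hs.share, "planted_events": n_events,
                "expected_background_window": exp_bg, "window_length": w_eff,
            })

        for rate, classes in (
            (gene.deleterious_rate, ("nonsense", "frameshift_indel")),
            (gene.synonymous_rate, ("synonymous",)),
        ):
            if rate <= 0:
                continue
            n_events = rng.poisson(rate * spec.n_samples)
            for _ in range(n_events):
                pos = int(rng.integers(1, gene.length + 1))
                cls = classes[rng.integers(0, len(classes))]
                s = samples_arr[rng.integers(0, spec.n_samples)]
                ref = protein[pos - 1]
                mutations.append(MutationRecord(
                    sample_id=s, tumor_type=sample_types[s], gene_id=gene.gene_id,
                    residue_position=pos, ref_aa=ref,
                    alt_aa=_STOP if cls == "nonsense" else (ref if cls == "synonymous" else None),
                    consequence=cls,
                ))

        for pos, freq in gene.common_variants:
            variants.append(PopulationVariant(
                max_population_frequency=freq, source="synthetic",
                gene_id=gene.gene_id, residue_position=pos,
            ))

    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "position", "share", "planted_events",
                 "expected_background_window", "window_length"],
    )
    return SimulatedCohort(
        mutations=mutations, manifest=manifest, truth_hotspots=truth,
        truth_variants=variants, gene_specs=spec.genes,
    )


def simulate_region_profile(
    length: int,
    n_mutations: int,
    interface_mask: np.ndarray,
    enrichment: float = 1.0,
    gene_id: str = "SIM",
    seed: Optional[int] = None,
) -> ResidueMutationProfile:
    """Place ``n_mutations`` missense events with interface-weighted odds.

    Residue weights are 1 outside the mask and ``enrichment`` inside; events
    are multinomial over residues.  Used by the region-test calibration and
    power simulations.
    """
    mask = np.asarray(interface_mask, dtype=bool)
    if mask.shape != (length,):
        raise ValueError("mask length must equal protein length")
    if enrichment < 0:
        raise ValueError("enrichment must be >= 0")
    rng = np.random.default_rng(seed)
    weights = np.where(mask, enrichment, 1.0).astype(float)
    probs = weights / weights.sum()
    counts = rng.multinomial(n_mutations, probs)
    return ResidueMutationProfile(gene_id=gene_id, length=length, counts=counts)


# ---------------------------------------------------------------------------
# Codon substitution simulation


@dataclass
class CodonSimulation:
    """Tally of simulated single-nucleotide codon substitutions."""

    n_events: int
    weighting: str
    outcomes: Counter            # (ref_aa, outcome) -> count; outcome aa, '*' or ref (syn)
    n_synonymous: int
    n_nonsense: int
    n_missense: int

    def frequency(self, ref_aa: str, alt_aa: str, among: str = "all") -> float:
        """Observed frequency of ref->alt events, over all or changing events."""
        count = self.outcomes.get((ref_aa, alt_aa), 0)
        if among == "all":
            return count / self.n_events
        if among == "changing":
            changing = self.n_missense + self.n_nonsense
            return count / changing if changing else 0.0
        raise ValueError("among must be 'all' or 'changing'")


def simulate_codon_substitutions(
    n_events: int = 10_000,
    weighting: str = "amino-acid-equal",
    seed: Optional[int] = None,
) -> CodonSimulation:
    """Simulate random single-nucleotide substitutions in sense codons.

    Each event draws an amino acid with equal probability (or a sense codon
    with equal probability under ``weighting='codon-equal'``), a codon of
    that amino acid uniformly, and one of the codon's nine single-nucleotide
    changes uniformly; the outcome amino acid (or stop) is tallied.
    """
    if weighting not in {"amino-acid-equal", "codon-equal"}:
        raise ValueError("weighting must be 'amino-acid-equal' or 'codon-equal'")
    rng = np.random.default_rng(seed)
    outcomes: Counter = Counter()
    n_syn = n_non = n_mis = 0
    aas = sorted(CODONS_BY_AA)
    for _ in range(n_events):
        if weighting == "amino-acid-equal":
            ref_aa = aas[rng.integers(0, len(aas))]
            codons = CODONS_BY_AA[ref_aa]
            codon = codons[rng.integers(0, len(codons))]
        else:
            codon = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS))]
            ref_aa = _CODON_TO_AA[codon]
        pos = int(rng.integers(0, 3))
        alternatives = [b for b in _BASES if b != codon[pos]]
        new_base = alternatives[rng.integers(0, 3)]
        alt_codon = codon[:pos] + new_base + codon[pos + 1:]
        alt_aa = _CODON_TO_AA[alt_codon]
        outcomes[(ref_aa, alt_aa)] += 1
        if alt_aa == _STOP:
            n_non += 1
        elif alt_aa == ref_aa:
            n_syn += 1
        else:
            n_mis += 1
    return CodonSimulation(
        n_events=n_events, weighting=weighting, outcomes=outcomes,
        n_synonymous=n_syn, n_nonsense=n_non, n_missense=n_mis,
    )


def analytic_codon_distribution(weighting: str = "amino-acid-equal") -> Dict[Tuple[str, str], float]:
    """Exact outcome distribution by enumeration over the 61 sense codons.

    Under amino-acid-equal weighting P(Glu->Lys) = (1/20)(1/9) = 1/180; under
    codon-equal weighting it is 2/(61*9).
    """
    if weighting not in {"amino-acid-equal", "codon-equal"}:
        raise ValueError("weighting must be 'amino-acid-equal' or 'codon-equal'")
    dist: Dict[Tuple[str, str], float] = {}
    for codon in SENSE_CODONS:
        ref_aa = _CODON_TO_AA[codon]
        if weighting == "amino-acid-equal":
            codon_w = (1 / 20) * (1 / len(CODONS_BY_AA[ref_aa]))
        else:
            codon_w = 1 / len(SENSE_CODONS)
        for pos in range(3):
            for base in _BASES:
                if base == codon[pos]:
                    continue
                alt_codon = codon[:pos] + base + codon[pos + 1:]
                alt_aa = _CODON_TO_AA[alt_codon]
                key = (ref_aa, alt_aa)
                dist[key] = dist.get(key, 0.0) + codon_w / 9
    return dist


# ---------------------------------------------------------------------------
# Uniform null (titin negative control)


def simulate_uniform_null(
    n_mutations: int,
    protein_length: int = 34_350,
    n_reps: int = 1000,
    params: HotspotParams = HotspotParams(),
    seed: Optional[int] = None,
) -> np.ndarray:
    """Hotspot calls per replicate when mutations are placed uniformly.

    The default length is that of the titin protein, the most heavily
    mutated human gene; under uniform placement the detector should call
    nothing at realistic mutation loads.
    """
    if n_mutations < 1:
        raise ValueError("need at least one mutation per replicate")
    rng = np.random.default_rng(seed)
    out = np.zeros(n_reps, dtype=np.int64)
    for i in range(n_reps):
        positions = rng.integers(0, protein_length, size=n_mutations)
        counts = np.bincount(positions, minlength=protein_length)
        if counts.max() < params.min_count:
            continue
        profile = ResidueMutationProfile(gene_id="NULL", length=protein_length,
                                         counts=counts)
        calls = detect_hotspots(profile, params)
        out[i] = sum(1 for c in calls if c.passed)
    return out


# ---------------------------------------------------------------------------
# Packaged toy fixture for the filter funnel


def toy_filter_fixture():
    """Deterministic 12-hotspot fixture for the filter funnel.

    Twelve genes each carry one genuine window-passing hotspot (6 events at
    residue 100 of a 400-residue protein plus sparse background).  Three
    hotspots coincide with common population variants (frequency 5%), two
    have only benign predictions, one has no prediction at all; the
    remaining six survive both filters.

    Returns (calls, variants, predictions).
    """
    calls = []
    for i in range(1, 13):
        gene = f"G{i:02d}"
        counts = np.zeros(400, dtype=np.int64)
        counts[99] = 6
        counts[[29, 179, 259, 339]] = 1
        profile = ResidueMutationProfile(gene_id=gene, length=400, counts=counts)
        (call,) = [c for c in detect_hotspots(profile) if c.passed]
        calls.append(call)

    variants = [
        PopulationVariant(max_population_frequency=0.05, source="synthetic",
                          gene_id=f"G{i:02d}", residue_position=100)
        for i in (1, 2, 3)
    ]
    predictions = {}
    for i in range(1, 13):
        gene = f"G{i:02d}"
        if i in (4, 5):
            predictions[(gene, 100)] = ["benign", "benign"]
        elif i == 6:
            continue  # unscored
        else:
            predictions[(gene, 100)] = ["benign", "probably_damaging"]
    return calls, variants, predictions
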