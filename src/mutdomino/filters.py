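"""Post-detection filters and functional annotation of hotspot calls.

Two false-positive sources dominate raw hotspot lists: common germline
polymorphisms that were not removed by tumor/normal pairing, and recurrent
artifacts without functional support.  ``filter_common_variants`` removes
residues matching a population variant above 1% frequency;
``apply_deleteriousness_filter`` keeps a residue only when at least one
underlying change is predicted damaging (PolyPhen-2-style labels).  Filters
flag rather than delete, so every input call appears in the output with its
full flag history, and the two filters commute.

``overlap_features`` annotates surviving hotspots with domains, binding
sites, phosphosites etc.; when a feature comes with its source protein
sequence, ``check_sequence_agreement`` guards the coordinate transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .hotspots import HotspotCall

__all__ = [
    "PopulationVariant",
    "FeatureAnnotation",
    "AgreementReport",
    "read_variant_table",
    "filter_common_variants",
    "apply_deleteriousness_filter",
    "check_sequence_agreement",
    "overlap_features",
    "surviving",
]

FEATURE_TYPES = {
    "domain", "ligand_binding", "interface", "phosphosite",
    "transmembrane", "motif", "other",
}

#: PolyPhen-2-style labels counted as damaging; configurable per call.
DAMAGING_LABELS = frozenset({"possibly_damaging", "probably_damaging"})
PREDICTION_VOCABULARY = frozenset({"benign", "possibly_damaging", "probably_damaging"})


@dataclass(frozen=True)
class PopulationVariant:
    """A known population variant keyed genomically or at protein level."""

    max_population_frequency: float
    source: str = ""
    gene_id: Optional[str] = None
    residue_position: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    chromosome: Optional[str] = None
    position: Optional[int] = None
    alt_base: Optional[str] = None

    def __post_init__(self):
        if not 0 <= self.max_population_frequency <= 1:
            raise ValueError("population frequency must lie in [0, 1]")
        if self.gene_id is None and self.chromosome is None:
            raise ValueError("variant needs a protein or genomic key")


@dataclass(frozen=True)
class FeatureAnnotation:
    """A protein feature interval (1-based inclusive residues)."""

    gene_id: str
    start: int
    end: int
    feature_type: str
    source: str = ""
    source_sequence: Optional[str] = None

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad feature interval [{self.start},{self.end}]")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(
                f"unknown feature type {self.feature_type!r}; known: {sorted(FEATURE_TYPES)}"
            )


@dataclass
class AgreementReport:
    passed: bool
    identity: float
    mismatch_positions: List[int]
    reason: str = ""


def read_variant_table(path) -> List[PopulationVariant]:
    """Read a variant TSV (gene/residue or chrom/pos keyed, max_freq, source)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "max_freq" not in df.columns:
        raise KeyError("variant table requires a 'max_freq' column")
    out = []
    for _, row in df.iterrows():
        out.append(
            PopulationVariant(
                max_population_frequency=float(row["max_freq"]),
                source=str(row.get("source", "")),
                gene_id=row.get("gene"),
                residue_position=int(row["residue"]) if "residue" in df.columns and pd.notna(row["residue"]) else None,
                ref_aa=row.get("ref_aa"),
                alt_aa=row.get("alt_aa"),
                chromosome=row.get("chrom"),
                position=int(row["pos"]) if "pos" in df.columns and pd.notna(row["pos"]) else None,
                alt_base=row.get("alt"),
            )
        )
    return out


def filter_common_variants(
    calls: Iterable[HotspotCall],
    variants: Sequence[PopulationVariant],
    max_freq: float = 0.01,
) -> List[HotspotCall]:
    """Flag calls matching a common population variant (frequency > max_freq).

    Matching prefers protein keys (gene, residue); the comparison is strictly
    greater, so a variant at exactly the threshold is retained.  Unmatched
    calls pass through untouched.  Calls are returned in input order with
    flags updated in place.
    """
    by_protein: Dict[Tuple[str, int], List[PopulationVariant]] = {}
    for v in variants:
        if v.gene_id is not None and v.residue_position is not None:
            by_protein.setdefault((v.gene_id, v.residue_position), []).append(v)

    calls = list(calls)
    for call in calls:
        matches = by_protein.get((call.gene_id, call.residue_position), [])
        if any(v.max_population_frequency > max_freq for v in matches):
            call.flags.add("common_variant")
    return calls


def apply_deleteriousness_filter(
    calls: Iterable[HotspotCall],
    predictions: Dict[Tuple[str, int], Sequence[str]],
    damaging_labels: frozenset = DAMAGING_LABELS,
    vocabulary: frozenset = PREDICTION_VOCABULARY,
    exclude_unscored: bool = True,
) -> List[HotspotCall]:
    """Keep calls with at least one damaging-labelled underlying change.

    ``predictions`` maps (gene, residue) to the labels of all nucleotide
    changes observed at the residue.  A residue with no prediction is flagged
    ``unscored`` and excluded by default.
    """
    calls = list(calls)
    for call in calls:
        labels = predictions.get((call.gene_id, call.residue_position))
        if not labels:
            if exclude_unscored:
                call.flags.add("unscored")
            continue
        unknown = set(labels) - vocabulary
        if unknown:
            raise ValueError(
                f"unknown prediction labels {sorted(unknown)}; vocabulary: {sorted(vocabulary)}"
            )
        if not set(labels) & damaging_labels:
            call.flags.add("not_damaging")
    return calls


def surviving(calls: Iterable[HotspotCall]) -> List[HotspotCall]:
    """Calls not excluded by any filter flag."""
    return [c for c in calls if not c.excluded]


def check_sequence_agreement(
    annotation_seq: str,
    reference_seq: str,
    hotspot_position: int,
    min_identity: float = 0.95,
) -> AgreementReport:
    """Positional identity check between annotation-source and reference protein.

    Passes when global identity (matches over the longer length) reaches
    ``min_identity`` *and* the hotspot residue itself is identical in both
    sequences -- coordinate transfer onto a diverged or shifted sequence
    would silently relocate the hotspot.
    """
    if not annotation_seq or not reference_seq:
        raise ValueError("sequences must be non-empty")
    n = max(len(annotation_seq), len(reference_seq))
    m = min(len(annotation_seq), len(reference_seq))
    mismatches = [
        i + 1 for i in range(m) if annotation_seq[i] != reference_seq[i]
    ]
    matches = m - len(mismatches)
    identity = matches / n
    if hotspot_position > m:
        return AgreementReport(False, identity, mismatches,
                               reason="hotspot position beyond a sequence end")
    if annotation_seq[hotspot_position - 1] != reference_seq[hotspot_position - 1]:
        return AgreementReport(False, identity, mismatches,
                               reason="hotspot residue differs between sequences")
    if identity < min_identity:
        return AgreementReport(False, identity, mismatches,
                               reason=f"identity {identity:.3f} below {min_identity}")
    return AgreementReport(True, identity, mismatches)


def overlap_features(
    calls: Iterable[HotspotCall],
    features: Sequence[FeatureAnnotation],
    reference_sequences: Optional[Dict[str, str]] = None,
) -> List[HotspotCall]:
    """Attach containing features and nearest-feature distances to each call.

    A feature contains a call when start <= residue <= end (distance 0);
    otherwise the distance to the closest feature of each type is recorded.
    Features carrying a source sequence are used only if the agreement check
    against the reference sequence passes.
    """
    calls = list(calls)
    by_gene: Dict[str, List[FeatureAnnotation]] = {}
    for f in features:
        by_gene.setdefault(f.gene_id, []).append(f)

    for call in calls:
        pos = call.residue_position
        annotations = []
        nearest: Dict[str, int] = {}
        for f in by_gene.get(call.gene_id, []):
            if f.source_sequence is not None and reference_sequences is not None:
                ref = reference_sequences.get(call.gene_id)
                if ref is not None:
                    rep = check_sequence_agreement(f.source_sequence, ref, pos)
                    if not rep.passed:
                        continue
            if f.start <= pos <= f.end:
                dist = 0
                annotations.append((f, 0))
            else:
                dist = min(abs(pos - f.start), abs(pos - f.end))
            if f.feature_type not in nearest or dist < nearest[f.feature_type]:
                nearest[f.feature_type] = dist
        call.features = annotations
        call.feature_distances = nearest  # type: ignore[attr-defined]
    return calls
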