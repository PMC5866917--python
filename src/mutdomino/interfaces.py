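"""Interaction-interface extraction, coordinate transfer and cluster testing.

Structure-derived per-residue tables (PDBePISA-style) give, for every residue
of a crystallized chain, its accessible and buried surface area and the
complexation significance score (CSS) of the interface it belongs to.
Biologically meaningful interfaces are kept when CSS > 0.3 for
protein-protein contacts or CSS > 0.05 for ligand / nucleic-acid contacts,
and residues burying more than 25 A^2 within them are interface residues.

Structure chains rarely match the reference protein exactly, so interface
segments are transferred by Smith-Waterman local alignment (BLOSUM62, gap
open 10 / extend 0.5): segments shorter than five residues are padded with
flanking sequence, and a transfer is accepted when identity >= 80%, or >= 60%
for alignments longer than ten columns.

Mutation clustering inside the mapped interfaces is tested per protein with a
binomial-logistic regression: each residue contributes (mutated samples,
unmutated samples) and the model is

    mutated ~ intercept + beta_interface * I(interface) + beta_disorder * I(disorder)

with a one-sided likelihood-ratio test of beta_interface > 0.  Intrinsic
disorder enters as a covariate because disordered regions have systematically
different mutation observability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .hotspots import ResidueMutationProfile, adjust_pvalues

__all__ = [
    "InterfaceAnnotation",
    "AlignmentResult",
    "ClusterTestResult",
    "extract_interface_residues",
    "local_align",
    "map_interface_to_protein",
    "interface_cluster_test",
    "select_significant",
]

CSS_PROTEIN_MIN = 0.3
CSS_OTHER_MIN = 0.05
BSA_MIN = 25.0


@dataclass
class InterfaceAnnotation:
    """Interface segments of one partner on one structure chain."""

    target_gene: str
    structure_id: str
    chain: str
    interface_id: str
    partner_class: str  # protein | ligand | nucleic_acid
    partner_id: str
    css: float
    segments: List[Tuple[int, int]]            # residue intervals on the chain
    residue_bsa: Dict[int, float] = field(default_factory=dict)
    mapped_segments: List[Tuple[int, int]] = field(default_factory=list)
    mapped_residues: Dict[int, int] = field(default_factory=dict)
    unmapped_segments: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class AlignmentResult:
    """A local alignment with its structure->target residue offset map."""

    score: float
    identity: float          # identical columns / all alignment columns
    length: int              # alignment columns including gaps
    query_aligned: str
    target_aligned: str
    offset_map: Dict[int, int]   # 1-based query position -> target position


@dataclass
class ClusterTestResult:
    target_gene: str
    n_residues_in: int
    n_residues_out: int
    mutated_in: int
    mutated_out: int
    intercept: float
    beta_interface: float
    beta_disorder: float
    p: float
    p_adjusted: Optional[float] = None
    untestable: bool = False


def extract_interface_residues(
    residue_table: pd.DataFrame,
    css_protein_min: float = CSS_PROTEIN_MIN,
    css_other_min: float = CSS_OTHER_MIN,
    bsa_min: float = BSA_MIN,
    target_gene_column: str = "target_gene",
) -> List[InterfaceAnnotation]:
    """Extract interface residues from a PISA-like per-residue table.

    Expected columns: structure_id, chain, residue_index, residue_aa, ASA,
    BSA, interface_id, partner_class, partner_id, CSS (plus a target-gene
    column naming the reference protein the chain represents).  An interface
    is dropped wholesale when its CSS fails the partner-class threshold
    (strict >); within passing interfaces, residues with BSA > bsa_min are
    kept and contiguous residues merged into segments.
    """
    required = {"structure_id", "chain", "residue_index", "BSA",
                "interface_id", "partner_class", "partner_id", "CSS"}
    missing = required - set(residue_table.columns)
    if missing:
        raise KeyError(f"residue table missing columns: {sorted(missing)}")
    if (residue_table["BSA"].astype(float) < 0).any():
        raise ValueError("negative buried surface area")
    if "ASA" in residue_table.columns and (residue_table["ASA"].astype(float) < 0).any():
        raise ValueError("negative accessible surface area")

    annotations: List[InterfaceAnnotation] = []
    group_cols = ["structure_id", "chain", "interface_id"]
    for (structure_id, chain, interface_id), grp in residue_table.groupby(group_cols):
        css = float(grp["CSS"].iloc[0])
        partner_class = str(grp["partner_class"].iloc[0])
        threshold = css_protein_min if partner_class == "protein" else css_other_min
        if not css > threshold:
            continue
        keep = grp[grp["BSA"].astype(float) > bsa_min]
        if keep.empty:
            continue
        residues = sorted(int(r) for r in keep["residue_index"])
        bsa = {int(r): float(b) for r, b in zip(keep["residue_index"], keep["BSA"])}
        annotations.append(
            InterfaceAnnotation(
                target_gene=str(grp[target_gene_column].iloc[0])
                if target_gene_column in grp.columns else str(structure_id),
                structure_id=str(structure_id),
                chain=str(chain),
                interface_id=str(interface_id),
                partner_class=partner_class,
                partner_id=str(grp["partner_id"].iloc[0]),
                css=css,
                segments=_merge_contiguous(residues),
                residue_bsa=bsa,
            )
        )
    return annotations


def _merge_contiguous(residues: Sequence[int]) -> List[Tuple[int, int]]:
    segments: List[Tuple[int, int]] = []
    for r in residues:
        if segments and r == segments[-1][1] + 1:
            segments[-1] = (segments[-1][0], r)
        else:
            segments.append((r, r))
    return segments


_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


def _aligner(open_gap: float, extend_gap: float, matrix_name: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -abs(open_gap)
    aligner.extend_gap_score = -abs(extend_gap)
    return aligner


def local_align(
    query: str,
    target: str,
    open_gap: float = 10.0,
    extend_gap: float = 0.5,
    matrix: str = "BLOSUM62",
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two peptides.

    Identity is computed over all alignment columns including gap columns
    (the EMBOSS definition).  The offset map relates aligned (non-gap)
    query residues to target residues, 1-based, and is strictly increasing.
    An all-negative scoring situation yields a zero-score empty alignment.
    """
    for name, seq in (("query", query), ("target", target)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - _AA20
        if bad:
            raise ValueError(f"{name} contains non-standard residues: {sorted(bad)}")
    aligner = _aligner(open_gap, extend_gap, matrix)
    alignments = aligner.align(query.upper(), target.upper())
    try:
        best = alignments[0]
    except IndexError:
        return AlignmentResult(0.0, 0.0, 0, "", "", {})
    if best.score <= 0:
        return AlignmentResult(0.0, 0.0, 0, "", "", {})

    offset_map: Dict[int, int] = {}
    identical = 0
    columns = int(best.length)
    q_blocks, t_blocks = best.aligned
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for dq in range(qe - qs):
            qpos, tpos = int(qs) + dq, int(ts) + dq
            offset_map[qpos + 1] = tpos + 1
            if query[qpos].upper() == target[tpos].upper():
                identical += 1
    return AlignmentResult(
        score=float(best.score),
        identity=identical / columns if columns else 0.0,
        length=columns,
        query_aligned=str(best[0]),
        target_aligned=str(best[1]),
        offset_map=offset_map,
    )


def map_interface_to_protein(
    annotation: InterfaceAnnotation,
    structure_seq: str,
    target_seq: str,
    min_segment: int = 5,
    identity_short: float = 0.8,
    identity_long: float = 0.6,
    long_alignment: int = 10,
) -> InterfaceAnnotation:
    """Transfer interface segments onto the reference protein coordinates.

    Each segment (padded symmetrically to >= ``min_segment`` residues, clipped
    at the chain ends) is locally aligned to the target; the transfer is
    accepted when identity >= 80%, or when the alignment spans more than ten
    columns and identity >= 60%.  Only the original (unpadded) interface
    residues are mapped.  Two structure residues never map to one target
    residue; a colliding segment is recorded as unmapped.
    """
    mapped: Dict[int, int] = {}
    unmapped: List[Tuple[int, int]] = []
    L = len(structure_seq)
    for start, end in annotation.segments:
        if start < 1 or end > L:
            raise ValueError(f"segment [{start},{end}] outside the structure chain")
        pstart, pend = _pad_segment(start, end, min_segment, L)
        peptide = structure_seq[pstart - 1 : pend]
        try:
            aln = local_align(peptide, target_seq)
        except ValueError:
            unmapped.append((start, end))
            continue
        accepted = aln.identity >= identity_short or (
            aln.length > long_alignment and aln.identity >= identity_long
        )
        if not accepted or not aln.offset_map:
            unmapped.append((start, end))
            continue
        segment_map = {}
        for res in range(start, end + 1):
            within = res - pstart + 1
            if within in aln.offset_map:
                segment_map[res] = aln.offset_map[within]
        if set(segment_map.values()) & set(mapped.values()):
            unmapped.append((start, end))
            continue
        if not segment_map:
            unmapped.append((start, end))
            continue
        mapped.update(segment_map)

    annotation.mapped_residues = mapped
    annotation.mapped_segments = _merge_contiguous(sorted(set(mapped.values())))
    annotation.unmapped_segments = unmapped
    return annotation


def _pad_segment(start: int, end: int, min_len: int, L: int) -> Tuple[int, int]:
    """Extend a short segment equally left/right to min_len, clipped to [1,L]."""
    while end - start + 1 < min_len:
        grew = False
        if start > 1:
            start -= 1
            grew = True
        if end - start + 1 < min_len and end < L:
            end += 1
            grew = True
        if not grew:
            break
    return start, end


def interface_cluster_test(
    profile: ResidueMutationProfile,
    interface_mask: np.ndarray,
    disorder_mask: Optional[np.ndarray] = None,
    cohort_size: int = 0,
) -> ClusterTestResult:
    """Test whether mutations cluster in the interface region of one protein.

    Per-residue binomial response (mutated samples, cohort - mutated) against
    interface and disorder indicators; p is the one-sided likelihood-ratio
    tail for interface enrichment (beta_interface > 0).  A protein with no
    mutations is untestable and reported with p = 1.
    """
    counts = profile.counts
    L = profile.length
    interface_mask = np.asarray(interface_mask, dtype=bool)
    if interface_mask.shape != (L,):
        raise ValueError("interface mask length must equal protein length")
    if disorder_mask is None:
        disorder_mask = np.zeros(L, dtype=bool)
    disorder_mask = np.asarray(disorder_mask, dtype=bool)
    if disorder_mask.shape != (L,):
        raise ValueError("disorder mask length must equal protein length")
    if cohort_size < int(counts.max(initial=0)):
        raise ValueError("cohort size smaller than the largest residue count")

    mutated_in = int(counts[interface_mask].sum())
    mutated_out = int(counts[~interface_mask].sum())
    base = dict(
        target_gene=profile.gene_id,
        n_residues_in=int(interface_mask.sum()),
        n_residues_out=int((~interface_mask).sum()),
        mutated_in=mutated_in,
        mutated_out=mutated_out,
    )
    if counts.sum() == 0:
        return ClusterTestResult(**base, intercept=np.nan, beta_interface=np.nan,
                                 beta_disorder=np.nan, p=1.0, untestable=True)

    endog = np.column_stack([counts, cohort_size - counts])
    X_full = np.column_stack([
        np.ones(L), interface_mask.astype(float), disorder_mask.astype(float)
    ])
    X_null = X_full[:, [0, 2]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(endog, X_full, family=sm.families.Binomial()).fit()
        null = sm.GLM(endog, X_null, family=sm.families.Binomial()).fit()
    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    p_two = float(stats.chi2.sf(lrt, df=1))
    beta = float(full.params[1])
    p = p_two / 2.0 if beta > 0 else 1.0 - p_two / 2.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return ClusterTestResult(
        **base,
        intercept=float(full.params[0]),
        beta_interface=beta,
        beta_disorder=float(full.params[2]),
        p=p,
    )


def select_significant(
    results: Sequence[ClusterTestResult], alpha: float = 0.05
) -> List[ClusterTestResult]:
    """BH-adjust the per-protein cluster tests and keep p_adjusted < alpha."""
    results = list(results)
    if not results:
        return []
    adjusted = adjust_pvalues([r.p for r in results])
    for r, padj in zip(results, adjusted):
        r.p_adjusted = float(padj)
    return [r for r in results if r.p_adjusted < alpha]
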