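"""Tumor-suppressor mutation signatures.

Tumor suppressors are commonly inactivated by truncating changes, so a gene
whose mutation spectrum is dominated by nonsense and frameshift events
relative to its synonymous (neutral, background-rate) events carries a
suppressor-like signature.  A gene qualifies when it has at least
``min_deleterious`` truncating events and a deleterious/synonymous ratio
strictly above ``min_ratio`` (defaults 25 and 0.7).

Missense and in-frame indels enter neither count; events are deduplicated per
sample exactly like hotspot counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List

from .mutmap import MutationRecord

__all__ = ["GeneMutationSignature", "suppressor_signature", "suppressor_signatures"]

_DELETERIOUS = {"nonsense", "frameshift_indel"}


@dataclass
class GeneMutationSignature:
    gene_id: str
    n_deleterious: int
    n_synonymous: int
    ratio: float  # +inf when no synonymous events
    is_suppressor_candidate: bool


def suppressor_signature(
    records: Iterable[MutationRecord],
    min_deleterious: int = 25,
    min_ratio: float = 0.7,
) -> GeneMutationSignature:
    """Classify one gene's records; all records must share a gene id."""
    records = list(records)
    genes = {r.gene_id for r in records}
    if len(genes) != 1:
        raise ValueError(f"expected records for exactly one gene, got {sorted(genes)}")
    gene_id = genes.pop()

    seen = set()
    n_del = n_syn = 0
    for rec in records:
        if rec.consequence not in _DELETERIOUS and rec.consequence != "synonymous":
            continue
        key = (rec.sample_id, rec.residue_position, rec.consequence, rec.alt_aa)
        if key in seen:
            continue
        seen.add(key)
        if rec.consequence in _DELETERIOUS:
            n_del += 1
        else:
            n_syn += 1

    ratio = n_del / n_syn if n_syn else math.inf
    candidate = n_del >= min_deleterious and ratio > min_ratio
    return GeneMutationSignature(gene_id, n_del, n_syn, ratio, candidate)


def suppressor_signatures(
    records: Iterable[MutationRecord],
    min_deleterious: int = 25,
    min_ratio: float = 0.7,
) -> List[GeneMutationSignature]:
    """Group a cohort's records by gene and classify each."""
    by_gene: Dict[str, list] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_id, []).append(rec)
    return [
        suppressor_signature(recs, min_deleterious, min_ratio)
        for _, recs in sorted(by_gene.items())
    ]
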