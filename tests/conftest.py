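import numpy as np
import pytest

from mutdomino.mutmap import MutationRecord, TranscriptModel

# A 3-residue protein (MEK) encoded forward and on the reverse strand.
# Forward: CDS ATG GAA AAA TAA at chrF:1-12.
# Reverse: the same cDNA, so the genomic strand holds its reverse complement.
MEK_CDS = "ATGGAAAAATAA"
MEK_PROTEIN = "MEK"


@pytest.fixture
def genome():
    rc = MEK_CDS.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    return {"chrF": MEK_CDS, "chrR": rc}


@pytest.fixture
def tx_forward():
    return TranscriptModel(
        gene_id="TOY", transcript_id="TOY-F", chromosome="chrF", strand="+",
        cds_intervals=((1, 12),), protein_sequence=MEK_PROTEIN,
    )


@pytest.fixture
def tx_reverse():
    return TranscriptModel(
        gene_id="TOY", transcript_id="TOY-R", chromosome="chrR", strand="-",
        cds_intervals=((1, 12),), protein_sequence=MEK_PROTEIN,
    )


def genomic_record(chrom, pos, ref, alt, sample="S1", gene="TOY"):
    return MutationRecord(
        sample_id=sample, tumor_type="T", gene_id=gene,
        genomic=(chrom, pos, ref, alt),
    )


def missense(gene, pos, sample, alt="K", ref="E", tumor_type="T"):
    return MutationRecord(
        sample_id=sample, tumor_type=tumor_type, gene_id=gene,
        residue_position=pos, ref_aa=ref, alt_aa=alt, consequence="missense",
    )


def brute_force_hotspots(counts, min_count=5, windows=(200, 300), min_fraction=0.15):
    """Independent per-residue scan used as the detector oracle.

    Recomputes window sums by direct slicing for every candidate, including
    terminal clipping; returns {residue: {W: (n_window, share)}} for passing
    candidates only.
    """
    counts = np.asarray(counts)
    L = len(counts)
    called = {}
    for i in range(L):
        k = counts[i]
        if k < min_count:
            continue
        stats = {}
        ok = True
        for W in windows:
            lo = max(1, (i + 1) - W // 2)
            hi = min(L, (i + 1) + W // 2)
            n_w = int(counts[lo - 1: hi].sum())
            share = k / n_w
            stats[W] = (n_w, share)
            ok = ok and share >= min_fraction
        if ok:
            called[i + 1] = stats
    return called
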