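"""Hotspot residue detection: dual-window share criterion + Poisson test.

A hotspot is a single residue that concentrates a disproportionate share of a
protein's missense mutations.  Candidates are residues carrying at least
``min_count`` distinct mutation events; each candidate is evaluated inside
windows of 200 and 300 residues centered on it (clipped at the protein
termini), and is called when its share of the window's mutations reaches
``min_fraction`` in *every* window.  Window lengths of 200-300 residues
bracket the typical size of a protein domain, so the test asks whether one
position stands out from its own domain-scale neighbourhood rather than from
the whole protein.

Each call carries a per-window Poisson tail probability: under a uniform
within-window background the count at one residue is ~Poisson(n_w / W_eff),
and p = P(X >= k).  The reported p is the maximum over window lengths (the
most conservative window governs) and is Benjamini-Hochberg adjusted across
all candidates of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mutmap import MutationRecord

__all__ = [
    "ResidueMutationProfile",
    "HotspotParams",
    "WindowStats",
    "HotspotCall",
    "build_residue_profile",
    "detect_hotspots",
    "poisson_hotspot_pvalue",
    "adjust_pvalues",
    "call_hotspots",
]


@dataclass
class ResidueMutationProfile:
    """Per-protein vector of missense events per residue.

    ``counts`` is 0-based internally (``counts[i]`` = events at residue i+1);
    ``class_totals`` tallies the non-missense consequence classes.
    """

    gene_id: str
    length: int
    counts: np.ndarray
    class_totals: Dict[str, int] = field(default_factory=dict)
    ref_aa: Optional[str] = None  # unused placeholder for profiles built without sequence

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (self.length,):
            raise ValueError(
                f"counts length {self.counts.shape} does not match protein length {self.length}"
            )
        if (self.counts < 0).any():
            raise ValueError("negative residue counts")

    @property
    def n_missense(self) -> int:
        return int(self.counts.sum())


def build_residue_profile(
    records: Iterable[MutationRecord], length: int, gene_id: Optional[str] = None
) -> ResidueMutationProfile:
    """Count distinct (sample, alt_aa) missense events per residue.

    The same sample reporting the same substitution twice counts once; other
    consequence classes are tallied into ``class_totals``.
    """
    records = list(records)
    genes = {r.gene_id for r in records}
    if gene_id is None:
        if len(genes) > 1:
            raise ValueError(f"records span multiple genes: {sorted(genes)}")
        gene_id = next(iter(genes)) if genes else "NA"
    elif genes and genes != {gene_id}:
        raise ValueError(f"records for {sorted(genes)} do not match gene {gene_id}")

    counts = np.zeros(length, dtype=np.int64)
    totals: Dict[str, int] = {}
    seen = set()
    for rec in records:
        if rec.consequence == "missense":
            pos = rec.residue_position
            if pos is None or pos < 1 or pos > length:
                raise ValueError(
                    f"record {rec.sample_id}/{rec.gene_id} position {pos} "
                    f"outside protein of length {length}"
                )
            key = (rec.sample_id, pos, rec.alt_aa)
            if key in seen:
                continue
            seen.add(key)
            counts[pos - 1] += 1
        else:
            totals[rec.consequence] = totals.get(rec.consequence, 0) + 1
    return ResidueMutationProfile(gene_id=gene_id, length=length, counts=counts,
                                  class_totals=totals)


@dataclass(frozen=True)
class HotspotParams:
    """Tunable thresholds of the window detector (defaults are the tool's)."""

    min_count: int = 5
    window_lengths: Tuple[int, ...] = (200, 300)
    min_fraction: float = 0.15
    mode: str = "fraction"
    overrep_factor: float = 10.0
    alpha: float = 0.05

    def __post_init__(self):
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if any(w < 1 for w in self.window_lengths):
            raise ValueError("window lengths must be >= 1")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if self.mode not in {"fraction", "overrepresentation"}:
            raise ValueError("mode must be 'fraction' or 'overrepresentation'")


@dataclass
class WindowStats:
    """Statistics of one detection window around a candidate residue."""

    window_length: int
    effective_length: int
    n_window: int
    share: float
    lam: float
    p: float
    passed: bool


@dataclass
class HotspotCall:
    """A candidate hotspot residue with its window statistics and p-values."""

    gene_id: str
    residue_position: int
    ref_aa: Optional[str]
    count: int
    windows: Dict[int, WindowStats]
    passed: bool
    p_reported: Optional[float] = None
    p_adjusted: Optional[float] = None
    flags: set = field(default_factory=set)
    features: list = field(default_factory=list)

    @property
    def excluded(self) -> bool:
        return bool(self.flags & {"common_variant", "not_damaging", "unscored"})


def poisson_hotspot_pvalue(k: int, n_window: int, effective_length: int) -> float:
    """Upper Poisson tail P(X >= k) with rate n_window / effective_length.

    The candidate's own events are part of ``n_window``, which inflates the
    expectation and keeps the test conservative.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if effective_length < 1:
        raise ValueError("effective window length must be >= 1")
    if n_window < k:
        raise ValueError(f"window total {n_window} smaller than residue count {k}")
    if k == 0:
        return 1.0
    lam = n_window / effective_length
    p = float(stats.poisson.sf(k - 1, lam))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def adjust_pvalues(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, clamped to <= 1."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if ((pvals <= 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def _window_bounds(center: int, window: int, length: int) -> Tuple[int, int]:
    """Clipped 1-based inclusive window [c - W/2, c + W/2] ∩ [1, L]."""
    half = window // 2
    return max(1, center - half), min(length, center + half)


def detect_hotspots(
    profile: ResidueMutationProfile, params: HotspotParams = HotspotParams()
) -> List[HotspotCall]:
    """Scan one protein for hotspot residues.

    Returns a call object for every candidate (count >= min_count) with
    ``passed`` indicating whether the share (or overrepresentation) criterion
    held in every window; Poisson p-values are computed for passing
    candidates and ``p_reported`` is the maximum across windows.
    BH adjustment across a whole run is applied by :func:`call_hotspots`.
    """
    counts = profile.counts
    L = profile.length
    candidates = np.flatnonzero(counts >= params.min_count) + 1
    if candidates.size == 0:
        return []
    csum = np.concatenate([[0], np.cumsum(counts)])

    calls: List[HotspotCall] = []
    for c in candidates:
        k = int(counts[c - 1])
        windows: Dict[int, WindowStats] = {}
        passed_all = True
        for W in params.window_lengths:
            lo, hi = _window_bounds(int(c), W, L)
            n_w = int(csum[hi] - csum[lo - 1])
            w_eff = hi - lo + 1
            share = k / n_w if n_w else 0.0
            lam = n_w / w_eff
            if params.mode == "fraction":
                ok = share >= params.min_fraction
            else:
                ok = k >= params.overrep_factor * lam
            windows[W] = WindowStats(
                window_length=W, effective_length=w_eff, n_window=n_w,
                share=share, lam=lam, p=1.0, passed=ok,
            )
            passed_all = passed_all and ok
        p_reported = None
        if passed_all:
            for W, ws in windows.items():
                ws.p = poisson_hotspot_pvalue(k, ws.n_window, ws.effective_length)
            p_reported = max(ws.p for ws in windows.values())
        calls.append(
            HotspotCall(
                gene_id=profile.gene_id,
                residue_position=int(c),
                ref_aa=None,
                count=k,
                windows=windows,
                passed=passed_all,
                p_reported=p_reported,
            )
        )
    return calls


def call_hotspots(
    profiles: Iterable[ResidueMutationProfile],
    params: HotspotParams = HotspotParams(),
) -> List[HotspotCall]:
    """Run the detector over many proteins and BH-adjust one joint call list.

    Only candidates that passed the window criterion enter the adjustment;
    the returned list contains exactly those calls, p_adjusted filled in.
    """
    passing: List[HotspotCall] = []
    for profile in profiles:
        passing.extend(c for c in detect_hotspots(profile, params) if c.passed)
    if passing:
        adjusted = adjust_pvalues([c.p_reported for c in passing])
        for call, padj in zip(passing, adjusted):
            call.p_adjusted = float(padj)
    return passing
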