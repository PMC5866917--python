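"""Cohort-level analyses: tumor-type frequency matrices, bootstrap
hierarchical clustering, heatmap transforms, coverage resampling and
network-neighborhood enrichment.

The central object is the hotspot x tumor-type matrix of patient mutation
fractions: for each detected hotspot and each tumor type with at least 50
sequenced patients, the fraction of that type's patients carrying the
hotspot mutation.  Tumor types are clustered on 1 - Pearson correlation
distances with median linkage, and cluster stability is scored by
bootstrap-resampling the hotspot rows (10,000 replicates by default):
the support of a clade is the fraction of replicate dendrograms containing
the identical leaf set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .hotspots import HotspotCall, adjust_pvalues
from .mutmap import MutationRecord

__all__ = [
    "TumorFrequencyMatrix",
    "ClusterSupport",
    "build_frequency_matrix",
    "bootstrap_cluster",
    "heatmap_transform",
    "patient_coverage",
    "coverage_null",
    "neighborhood_enrichment",
    "compare_set_fractions",
    "compare_set_fractions_batch",
]


@dataclass
class TumorFrequencyMatrix:
    """Hotspot x tumor-type matrix of patient mutation fractions."""

    fractions: pd.DataFrame        # rows: "GENE_pos" hotspot ids; cols: tumor types
    n_patients: pd.Series          # per tumor type
    min_patients: int = 50

    def __post_init__(self):
        if ((self.fractions < 0) | (self.fractions > 1)).any().any():
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class ClusterSupport:
    linkage: np.ndarray                    # scipy linkage matrix over tumor types
    labels: List[str]                      # column order used for the linkage
    support: Dict[FrozenSet[str], float]   # clade leaf set -> bootstrap probability
    n_bootstrap: int
    dropped_columns: List[str] = field(default_factory=list)

    def to_newick(self) -> str:
        """Export the dendrogram as a Newick string (heights as branch lengths)."""
        tree = hierarchy.to_tree(self.linkage)

        def _fmt(node, parent_height):
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = _fmt(node.left, node.dist)
            right = _fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return _fmt(tree, tree.dist) + ";"


def build_frequency_matrix(
    calls: Sequence[HotspotCall],
    mutations: Iterable[MutationRecord],
    manifest: pd.DataFrame,
    min_patients: int = 50,
) -> TumorFrequencyMatrix:
    """Fraction of each tumor type's patients mutated at each hotspot.

    ``manifest`` maps every sample to exactly one tumor type (columns
    ``sample`` and ``tumor_type``); cohorts under ``min_patients`` are
    excluded.  Source cohorts sharing a tumor-type abbreviation are merged
    simply by carrying the same label.
    """
    if not {"sample", "tumor_type"} <= set(manifest.columns):
        raise KeyError("manifest requires 'sample' and 'tumor_type' columns")
    if manifest["sample"].duplicated().any():
        dupes = manifest.loc[manifest["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"samples mapped more than once: {dupes[:5]}")
    sample_type = dict(zip(manifest["sample"], manifest["tumor_type"]))

    sizes = manifest["tumor_type"].value_counts()
    kept_types = sorted(sizes[sizes >= min_patients].index)

    hotspot_ids = [f"{c.gene_id}_{c.residue_position}" for c in calls]
    hotspot_keys = {(c.gene_id, c.residue_position): f"{c.gene_id}_{c.residue_position}"
                    for c in calls}

    carriers: Dict[Tuple[str, str], Set[str]] = {}
    for rec in mutations:
        if rec.consequence != "missense" or rec.residue_position is None:
            continue
        hid = hotspot_keys.get((rec.gene_id, rec.residue_position))
        if hid is None:
            continue
        if rec.sample_id not in sample_type:
            raise ValueError(f"sample {rec.sample_id!r} missing from the manifest")
        ttype = sample_type[rec.sample_id]
        if ttype not in kept_types:
            continue
        carriers.setdefault((hid, ttype), set()).add(rec.sample_id)

    data = pd.DataFrame(0.0, index=sorted(set(hotspot_ids)), columns=kept_types)
    for (hid, ttype), samples in carriers.items():
        data.loc[hid, ttype] = len(samples) / sizes[ttype]
    return TumorFrequencyMatrix(
        fractions=data, n_patients=sizes[kept_types], min_patients=min_patients
    )


def _correlation_condensed(values: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson correlation distances between columns."""
    corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return squareform(dist, checks=False)


def _clades(Z: np.ndarray, labels: Sequence[str]) -> Set[FrozenSet[str]]:
    n = len(labels)
    members: Dict[int, FrozenSet[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    clades: Set[FrozenSet[str]] = set()
    for i, (a, b, _h, _c) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        clades.add(merged)
    return clades


def bootstrap_cluster(
    matrix: TumorFrequencyMatrix,
    linkage_method: str = "median",
    n_bootstrap: int = 10_000,
    seed: Optional[int] = None,
) -> ClusterSupport:
    """Cluster tumor types with bootstrap support over resampled hotspots.

    Distance between tumor-type columns is 1 - Pearson correlation; linkage
    is median by default (height inversions are tolerated).  Each bootstrap
    replicate resamples hotspot rows with replacement; a clade's support is
    the fraction of replicates whose dendrogram contains the same leaf set.
    Constant columns (undefined correlation) are dropped with a warning.
    """
    df = matrix.fractions
    if df.shape[1] < 3 or df.shape[0] < 2:
        raise ValueError("need at least 3 tumor types and 2 hotspots")
    std = df.std(axis=0, ddof=0)
    dropped = [c for c in df.columns if std[c] == 0]
    if dropped:
        warnings.warn(f"dropping constant tumor-type columns: {dropped}")
        df = df.drop(columns=dropped)
    labels = list(df.columns)
    values = df.to_numpy(dtype=float)

    Z = hierarchy.linkage(_correlation_condensed(values), method=linkage_method)
    reference = _clades(Z, labels)
    counts = {clade: 0 for clade in reference}

    rng = np.random.default_rng(seed)
    n_rows = values.shape[0]
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n_rows, size=n_rows)
        sample = values[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            if np.any(sample.std(axis=0) == 0):
                continue  # replicate with a constant column contributes no clades
            Zb = hierarchy.linkage(_correlation_condensed(sample), method=linkage_method)
        for clade in _clades(Zb, labels):
            if clade in counts:
                counts[clade] += 1
    support = {clade: c / n_bootstrap for clade, c in counts.items()}
    return ClusterSupport(Z, labels, support, n_bootstrap, dropped)


def heatmap_transform(
    matrix: TumorFrequencyMatrix | pd.DataFrame,
    display_min_fraction: float = 1 / 3,
) -> pd.DataFrame:
    """Display transform: keep rows reaching the display threshold, log2 scale.

    Rows are kept when the hotspot is mutated in at least one third of the
    patients of some tumor type; fractions become percentages and are
    log2-transformed (so 78% maps to 6.29, 1% to 0).  Zeros are shown as the
    minimum positive display value minus one log2 unit.
    """
    df = matrix.fractions if isinstance(matrix, TumorFrequencyMatrix) else matrix
    kept = df[df.max(axis=1) >= display_min_fraction]
    pct = kept * 100.0
    with np.errstate(divide="ignore"):
        logged = np.log2(pct.to_numpy(dtype=float))
    positives = logged[np.isfinite(logged)]
    floor = (positives.min() - 1.0) if positives.size else 0.0
    logged[~np.isfinite(logged)] = floor
    return pd.DataFrame(logged, index=kept.index, columns=kept.columns)


def _carrier_samples(
    mutations: Sequence[MutationRecord],
    gene_set: Optional[Set[str]] = None,
    position_set: Optional[Set[Tuple[str, int]]] = None,
) -> Set[str]:
    hit = set()
    for rec in mutations:
        if gene_set is not None and rec.gene_id in gene_set:
            hit.add(rec.sample_id)
        elif position_set is not None and rec.residue_position is not None and (
            (rec.gene_id, rec.residue_position) in position_set
        ):
            hit.add(rec.sample_id)
    return hit


def patient_coverage(
    target_set: Iterable,
    mutations: Sequence[MutationRecord],
    manifest: pd.DataFrame,
) -> float:
    """Fraction of all manifest samples carrying >= 1 event in the target set.

    ``target_set`` may contain gene ids (strings) or (gene, residue) pairs;
    a sample with several hits counts once.
    """
    if manifest.empty:
        raise ValueError("empty sample manifest")
    target_set = set(target_set)
    genes = {t for t in target_set if isinstance(t, str)}
    positions = {t for t in target_set if isinstance(t, tuple)}
    hit = _carrier_samples(mutations, gene_set=genes or None,
                           position_set=positions or None)
    samples = set(manifest["sample"])
    return len(hit & samples) / len(samples)


@dataclass
class ResamplingResult:
    observed: float
    null_values: np.ndarray
    z: float
    p: float

    @property
    def null_mean(self) -> float:
        return float(self.null_values.mean())


def coverage_null(
    mutations: Sequence[MutationRecord],
    manifest: pd.DataFrame,
    set_size: int,
    observed: float,
    n_draws: int = 1000,
    min_count: int = 5,
    unit: str = "gene",
    seed: Optional[int] = None,
) -> ResamplingResult:
    """Null distribution of patient coverage for random candidate sets.

    The candidate pool is genes (default) containing at least one residue
    with >= ``min_count`` distinct mutation events, or such (gene, residue)
    positions with ``unit='position'``.  ``n_draws`` random same-size sets
    give the null; the returned p is the normal upper tail of the observed
    coverage against the null mean and standard deviation.
    """
    if unit not in {"gene", "position"}:
        raise ValueError("unit must be 'gene' or 'position'")
    tallies: Dict[Tuple[str, int], Set[Tuple[str, Optional[str]]]] = {}
    for rec in mutations:
        if rec.consequence == "missense" and rec.residue_position is not None:
            tallies.setdefault((rec.gene_id, rec.residue_position), set()).add(
                (rec.sample_id, rec.alt_aa)
            )
    qualifying = [key for key, events in tallies.items() if len(events) >= min_count]
    if unit == "gene":
        pool = sorted({g for g, _ in qualifying})
    else:
        pool = sorted(qualifying)
    if len(pool) <= set_size:
        raise ValueError(
            f"candidate pool ({len(pool)}) not larger than set size ({set_size})"
        )
    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws)
    pool_arr = np.array(pool, dtype=object)
    for i in range(n_draws):
        chosen = rng.choice(len(pool_arr), size=set_size, replace=False)
        subset = [pool_arr[j] for j in chosen]
        draws[i] = patient_coverage(
            [tuple(s) if unit == "position" else s for s in subset],
            mutations, manifest,
        )
    sd = draws.std(ddof=1)
    if sd == 0:
        p = 0.5 if observed == draws.mean() else (0.0 if observed > draws.mean() else 1.0)
        z = np.inf if observed > draws.mean() else -np.inf
        if observed == draws.mean():
            z = 0.0
    else:
        z = (observed - draws.mean()) / sd
        p = float(stats.norm.sf(z))
    return ResamplingResult(observed=observed, null_values=draws, z=float(z), p=float(p))


def neighborhood_enrichment(
    edges: Iterable[Tuple[str, str]],
    queries: Sequence[str],
    labels: Iterable[str],
    n_resamples: int = 1000,
    seed: Optional[int] = None,
) -> ResamplingResult:
    """Enrichment of labelled proteins among the first neighbors of queries.

    Observed statistic: number of distinct labelled proteins adjacent to any
    query.  Null: each query keeps its degree but draws that many interactors
    uniformly (without replacement, per query) from all non-query nodes;
    the z-score and normal upper-tail p compare observed to this null.
    Queries absent from the graph are skipped with a warning.
    """
    import networkx as nx

    G = nx.Graph()
    G.add_edges_from(edges)
    labels = set(labels)
    present = []
    for q in queries:
        if q in G:
            present.append(q)
        else:
            warnings.warn(f"query {q!r} absent from the network; skipped")
    neighbor_union: Set[str] = set()
    for q in present:
        neighbor_union.update(G.neighbors(q))
    neighbor_union -= set(present)
    observed = len(neighbor_union & labels)

    nodes = [n for n in G.nodes if n not in set(present)]
    degrees = [min(G.degree(q), len(nodes)) for q in present]
    rng = np.random.default_rng(seed)
    null = np.empty(n_resamples)
    nodes_arr = np.array(nodes, dtype=object)
    for i in range(n_resamples):
        drawn: Set[str] = set()
        for d in degrees:
            idx = rng.choice(len(nodes_arr), size=d, replace=False)
            drawn.update(nodes_arr[j] for j in idx)
        null[i] = len(drawn & labels)
    sd = null.std(ddof=1)
    if sd == 0:
        z = 0.0 if observed == null.mean() else np.sign(observed - null.mean()) * np.inf
        p = float(stats.norm.sf(z)) if np.isfinite(z) else (0.0 if z > 0 else 1.0)
        if z == 0.0:
            p = 0.5
    else:
        z = float((observed - null.mean()) / sd)
        p = float(stats.norm.sf(z))
    return ResamplingResult(observed=float(observed), null_values=null, z=z, p=p)


def compare_set_fractions(
    set_a: Tuple[int, int], set_b: Tuple[int, int]
) -> Tuple[float, float, str]:
    """Compare two proportions (hits, total) with chi-squared or Fisher.

    Chi-squared with continuity correction when all expected counts are
    >= 5, Fisher's exact test otherwise; a degenerate (zero-margin) table
    falls back to Fisher with p = 1.  Returns (statistic, p, method).
    """
    (k1, n1), (k2, n2) = set_a, set_b
    if min(k1, n1 - k1, k2, n2 - k2) < 0 or n1 <= 0 or n2 <= 0:
        raise ValueError("counts must be nonnegative with positive totals")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0, "fisher"
    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
        return float(chi2), float(p), "chi2"
    odds, p = stats.fisher_exact(table)
    return float(odds), float(p), "fisher"


def compare_set_fractions_batch(
    pairs: Sequence[Tuple[Tuple[int, int], Tuple[int, int]]]
) -> pd.DataFrame:
    """Run :func:`compare_set_fractions` on a batch and BH-adjust the p-values."""
    rows = [compare_set_fractions(a, b) for a, b in pairs]
    df = pd.DataFrame(rows, columns=["statistic", "p", "method"])
    df["p_adjusted"] = adjust_pvalues(df["p"].clip(lower=np.nextafter(0, 1)))
    return df
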