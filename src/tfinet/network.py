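"""ChIP peak filtering, regulatory-domain assignment and network statistics.

The chain mirrors a standard genomic-interaction-network construction:
peaks are filtered by requiring their ChIP RPKM to exceed the RPKM observed
in the input (control) track over the same regions; surviving peaks are
assigned to genes through basal-plus-extension regulatory domains (5 kb
upstream / 1 kb downstream of the TSS, extended toward neighbours up to
1 Mb); a directed TF -> gene edge exists when any filtered peak of the TF
overlaps the gene's extended domain. On top of the edge set sit the
descriptive statistics: per-gene bound-TF combinations, indegree
distributions, over-representation of a gene set among bound genes, and
fully connected triads among the TF-encoding genes themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from collections import Counter

import numpy as np
import pandas as pd

from . import enrich
from .intervals import count_overlaps, overlap_pairs


# ---------------------------------------------------------------------------
# coverage and filtering
# ---------------------------------------------------------------------------

def region_rpkm(reads: pd.DataFrame, regions: pd.DataFrame,
                library_size: int | None = None) -> np.ndarray:
    """RPKM of each region: overlapping reads * 1e9 / (library * length).

    A read counts once per region it overlaps. ``library_size`` defaults to
    the number of reads in the track.
    """
    if len(regions) == 0:
        return np.zeros(0)
    library_size = len(reads) if library_size is None else library_size
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    lengths = (regions["end"] - regions["start"]).to_numpy(float)
    if (lengths <= 0).any():
        raise ValueError("regions must have positive length")
    counts = count_overlaps(regions, reads)
    return counts * 1e9 / (library_size * lengths)


def filter_peaks(peaks: pd.DataFrame, chip_reads: pd.DataFrame,
                 input_reads: pd.DataFrame, percentile: float = 99.0,
                 mode: str = "percentile") -> pd.DataFrame:
    """Retain peaks whose ChIP RPKM clears the input-track background.

    mode="percentile" (default): one threshold per track — the
    ``percentile``-th percentile (linear interpolation) of the input RPKM
    computed over all peak regions; peaks pass when ChIP RPKM exceeds it.
    mode="per-region": a peak passes when its ChIP RPKM exceeds
    ``percentile/100`` times the input RPKM over that same region.
    """
    if len(chip_reads) == 0 or len(input_reads) == 0:
        raise ValueError("read tracks must be nonempty")
    if len(peaks) == 0:
        return peaks.copy()
    chip = region_rpkm(chip_reads, peaks)
    inp = region_rpkm(input_reads, peaks)
    if mode == "percentile":
        threshold = float(np.percentile(inp, percentile))
        keep = chip > threshold
    elif mode == "per-region":
        keep = chip > (percentile / 100.0) * inp
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = peaks.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("all peaks removed by the input filter", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# regulatory domains
# ---------------------------------------------------------------------------

def regulatory_domains(genes: pd.DataFrame, basal_up: int = 5000,
                       basal_down: int = 1000, max_ext: int = 1_000_000,
                       chrom_sizes: dict[str, int] | None = None
                       ) -> pd.DataFrame:
    """Basal-plus-extension regulatory domains for a stranded annotation.

    The basal domain spans TSS-basal_up .. TSS+basal_down in transcription
    orientation. The extended domain grows from the basal domain in both
    genomic directions up to the nearer of (a) the adjacent gene's basal
    domain edge and (b) max_ext from the TSS, never retracting inside the
    gene's own basal domain; overlapping basal domains are left overlapping.
    Coordinates are clipped to [0, chromosome size).
    """
    if (~genes["strand"].isin(["+", "-"])).any():
        bad = genes.loc[~genes["strand"].isin(["+", "-"]), "name"].tolist()
        raise ValueError(f"unstranded genes: {bad[:5]}")
    chrom_sizes = chrom_sizes or {}
    out = []
    for chrom, grp in genes.groupby("chrom", sort=False):
        size = int(chrom_sizes.get(chrom, 2**62))
        tss = np.where(grp["strand"] == "+", grp["start"], grp["end"]).astype(np.int64)
        b_start = np.where(grp["strand"] == "+", tss - basal_up, tss - basal_down)
        b_end = np.where(grp["strand"] == "+", tss + basal_down, tss + basal_up)
        b_start = np.clip(b_start, 0, size).astype(np.int64)
        b_end = np.clip(b_end, 0, size).astype(np.int64)
        order = np.argsort(b_start, kind="stable")
        bs, be, ts = b_start[order], b_end[order], tss[order]
        # left boundary: max basal end among genes with strictly smaller
        # basal start (ties, e.g. from clipping, block neither side)
        cummax_be = np.maximum.accumulate(be)
        left_idx = np.searchsorted(bs, bs, side="left") - 1
        prev_end = np.where(left_idx >= 0, cummax_be[np.maximum(left_idx, 0)], 0)
        # right boundary: nearest strictly greater basal start
        right_idx = np.searchsorted(bs, bs, side="right")
        next_start = np.where(right_idx < len(bs),
                              bs[np.minimum(right_idx, len(bs) - 1)], size)
        e_start = np.minimum(bs, np.maximum(np.maximum(ts - max_ext, 0),
                                            prev_end))
        e_end = np.maximum(be, np.minimum(np.minimum(ts + max_ext, size),
                                          next_start))
        df = grp.iloc[order].copy()
        df["tss"] = ts
        df["basal_start"], df["basal_end"] = bs, be
        df["ext_start"] = e_start.astype(np.int64)
        df["ext_end"] = e_end.astype(np.int64)
        out.append(df)
    res = pd.concat(out, ignore_index=True)
    return res[["chrom", "name", "strand", "tss", "basal_start", "basal_end",
                "ext_start", "ext_end"]]


def assign_peaks(peaks_by_tf: dict[str, pd.DataFrame],
                 domains: pd.DataFrame) -> pd.DataFrame:
    """Directed TF -> gene edges from peak / extended-domain overlap.

    A peak may create edges to several genes; duplicate (tf, gene) pairs
    collapse to one edge. Returns a DataFrame with columns tf, gene.
    """
    dom = domains.rename(columns={"ext_start": "start", "ext_end": "end"})
    dom = dom[["chrom", "start", "end", "name"]].reset_index(drop=True)
    edges = set()
    for tf, peaks in peaks_by_tf.items():
        p = peaks.reset_index(drop=True)
        for pi, di in overlap_pairs(p, dom):
            edges.add((tf, dom.at[di, "name"]))
    return pd.DataFrame(sorted(edges), columns=["tf", "gene"])


# ---------------------------------------------------------------------------
# network statistics
# ---------------------------------------------------------------------------

def bound_tf_sets(edges: pd.DataFrame) -> dict[str, frozenset[str]]:
    """gene -> set of TFs with at least one assigned binding event."""
    out: dict[str, set[str]] = {}
    for tf, gene in edges.itertuples(index=False):
        out.setdefault(gene, set()).add(tf)
    return {g: frozenset(s) for g, s in out.items()}


def binding_combinations(edges: pd.DataFrame, gene_set
                         ) -> Counter:
    """Count genes per distinct bound-TF combination within ``gene_set``.

    Genes without any bound TF contribute the empty combination.
    """
    bound = bound_tf_sets(edges)
    return Counter(bound.get(g, frozenset()) for g in gene_set)


def any_of_fraction(edges: pd.DataFrame, gene_set, tf_subset) -> float:
    """Fraction of ``gene_set`` bound by at least one TF in ``tf_subset``."""
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    bound = bound_tf_sets(edges)
    tf_subset = set(tf_subset)
    hits = sum(1 for g in gene_set if bound.get(g, frozenset()) & tf_subset)
    return hits / len(gene_set)


def indegree_distribution(edges: pd.DataFrame, gene_set, background_set,
                          n_tfs: int | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized indegree histograms (0..n_tfs) for a set and a background."""
    bound = bound_tf_sets(edges)
    n_tfs = n_tfs if n_tfs is not None else edges["tf"].nunique()

    def hist(genes):
        genes = list(genes)
        if not genes:
            raise ValueError("empty gene set")
        deg = [len(bound.get(g, frozenset())) for g in genes]
        h = np.bincount(deg, minlength=n_tfs + 1).astype(float)
        return h / h.sum()

    return hist(gene_set), hist(background_set)


def bound_set_enrichment(edges: pd.DataFrame, tf: str, gene_set, universe
                         ) -> enrich.EnrichmentResult:
    """Over-representation of ``gene_set`` among genes bound by ``tf``."""
    bound_genes = set(edges.loc[edges["tf"] == tf, "gene"])
    return enrich.set_overrepresentation(universe, bound_genes, gene_set,
                                         term_id=f"bound_by_{tf}")


def core_circuitry(edges: pd.DataFrame, tf_gene_map: dict[str, str]) -> dict:
    """Autoregulation, mutual pairs and fully connected triads among TFs.

    A triad of TFs is fully connected when all nine possible edges among
    the genes encoding them are present: three autoregulatory plus all six
    cross edges. TFs without a mapped encoding gene are excluded with a
    warning.
    """
    tfs_in_edges = set(edges["tf"].unique())
    mapped = {}
    for tf in sorted(tfs_in_edges | set(tf_gene_map)):
        if tf not in tf_gene_map:
            warnings.warn(f"TF {tf} has no mapped encoding gene; excluded",
                          stacklevel=2)
            continue
        mapped[tf] = tf_gene_map[tf]
    edge_set = {(t, g) for t, g in edges.itertuples(index=False)}

    def has(tf_a: str, tf_b: str) -> bool:
        return (tf_a, mapped[tf_b]) in edge_set

    auto = {tf: has(tf, tf) for tf in mapped}
    mutual = {tuple(sorted((a, b))): has(a, b) and has(b, a)
              for a, b in combinations(mapped, 2)}
    triads = []
    for trio in combinations(sorted(mapped), 3):
        if all(auto[t] for t in trio) and \
           all(has(a, b) and has(b, a) for a, b in combinations(trio, 2)):
            triads.append(tuple(trio))
    return {"autoregulatory": auto, "mutual_pairs": mutual,
            "fully_connected_triads": triads}


# ---------------------------------------------------------------------------
# one-call network construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkParams:
    percentile: float = 99.0
    filter_mode: str = "percentile"
    basal_up: int = 5000
    basal_down: int = 1000
    max_ext: int = 1_000_000


def build_network(peaks_by_tf: dict[str, pd.DataFrame],
                  reads_by_tf: dict[str, pd.DataFrame],
                  input_reads: pd.DataFrame, annotation: pd.DataFrame,
                  params: NetworkParams | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter peaks per TF, build domains and assign edges.

    Returns (edges, domains). The input-percentile threshold is computed
    per TF track over that TF's peak regions.
    """
    params = params or NetworkParams()
    domains = regulatory_domains(annotation, params.basal_up,
                                 params.basal_down, params.max_ext)
    filtered = {tf: filter_peaks(peaks, reads_by_tf[tf], input_reads,
                                 params.percentile, params.filter_mode)
                for tf, peaks in peaks_by_tf.items()}
    edges = assign_peaks(filtered, domains)
    return edges, domains
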