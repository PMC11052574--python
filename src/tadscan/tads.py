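"""TAD geometry: membership, enrichment, loop coordinates, search profiles.

TADs are chromatin loops whose two boundaries are held together by the
CTCF/cohesin complex; for loop-relative geometry the two boundary ends are
identified as a single joined point, making positions inside a TAD live on a
circle of circumference L (the TAD length). The loop distance between two
intra-TAD positions is the shorter arc, min(|a-b|, L-|a-b|), bounded by L/2.

Anchors: a gene is its strand-aware TSS, a variant its locus, a peak its
midpoint. Inter-TAD regions (between consecutive TADs, and chromosome ends
outside the first/last TAD) are first-class membership targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scan import _enumerate_regions  # shared region partition


@dataclass(frozen=True)
class TadInterval:
    """One TAD: chrom, [start, end) in bp."""

    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("TAD end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class EnrichmentResult:
    """2x2 intra/extra x interacting/non-interacting contingency outcome."""

    contingency: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    haldane_corrected: bool = False
    n_boundary_proximal_excluded: int = 0


def assign_to_tads(features: pd.DataFrame, tads: pd.DataFrame,
                   chrom_lengths: dict[str, int] | None = None) -> pd.Series:
    """Map each feature anchor position to a TAD id or inter-TAD region id.

    ``features`` needs columns chrom, pos. Positions inside [start, end) of a
    TAD map to ``tad:<name>``; all others to ``inter:<chrom>:<k>`` region ids.
    Raises for features on chromosomes absent from the TAD table (unless the
    chromosome appears in ``chrom_lengths``, in which case it is one big
    inter-TAD region).
    """
    known = set(tads["chrom"]) | set(chrom_lengths or {})
    bad = sorted(set(features["chrom"]) - known)
    if bad:
        raise ValueError(f"features on unknown chromosomes: {bad}")

    out = pd.Series(index=features.index, dtype=object)
    for chrom, grp in features.groupby("chrom"):
        clen = (chrom_lengths or {}).get(
            chrom, max(int(grp["pos"].max()) + 1, int(tads.loc[tads["chrom"] == chrom, "end"].max() if (tads["chrom"] == chrom).any() else 0))
        )
        regions = _enumerate_regions(tads, chrom, clen)
        if regions.empty:
            out.loc[grp.index] = f"inter:{chrom}:0"
            continue
        starts = regions["start"].to_numpy()
        idx = np.searchsorted(starts, grp["pos"].to_numpy(), side="right") - 1
        idx = np.clip(idx, 0, len(regions) - 1)
        ids = regions["region_id"].to_numpy()[idx]
        # positions beyond the last region end (ragged chrom length guess)
        beyond = grp["pos"].to_numpy() >= regions["end"].to_numpy()[idx]
        if beyond.any():
            ids = ids.copy()
            ids[beyond] = f"inter:{chrom}:end"
        out.loc[grp.index] = ids
    return out


def loop_distance(pos_a: int, pos_b: int, tad: TadInterval) -> int:
    """Circular distance on the TAD loop; maximum attainable value is L/2."""
    for p in (pos_a, pos_b):
        if p not in tad:
            raise ValueError(f"position {p} outside TAD [{tad.start}, {tad.end})")
    d = abs(pos_a - pos_b)
    return min(d, tad.length - d)


def _peak_mid(peaks: pd.DataFrame) -> pd.Series:
    return (peaks["start"] + peaks["end"]) // 2


def _anchor_maps(dataset):
    genes = dataset.genes.set_index("name")
    peaks = dataset.peaks.set_index("name")
    markers = dataset.markers.set_index("name")
    return (
        genes["tss"].to_dict(),
        dict(zip(peaks.index, (peaks["start"] + peaks["end"]) // 2)),
        markers["start"].to_dict(),
        genes["chrom"].to_dict(),
        genes["strand"].to_dict(),
    )


def _tad_lookup(tads: pd.DataFrame):
    by_id = {}
    for _, t in tads.iterrows():
        by_id[f"tad:{t['name']}"] = TadInterval(t["chrom"], int(t["start"]), int(t["end"]), t["name"])
    return by_id


def boundary_window_enrichment(
    model_table: pd.DataFrame,
    peaks: pd.DataFrame,
    tads: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 200_000,
    exclude_boundary_proximal: bool = True,
    chrom_lengths: dict[str, int] | None = None,
) -> EnrichmentResult:
    """Fisher-exact enrichment of interacting pairs among intra-TAD pairs.

    Units are deduplicated tested (gene, peak) pairs from ``model_table``.
    A pair is *intra* when the peak midpoint falls in the same TAD as the
    gene's TSS, and *interacting* when it appears in at least one significant
    interacting model. Peaks within ``window_bp`` of a TAD boundary are
    tagged boundary-proximal and excluded by default (their TAD assignment is
    ambiguous at boundary resolution); pass
    ``exclude_boundary_proximal=False`` to keep them.
    """
    pairs = model_table[["gene_id", "peak_id"]].drop_duplicates()
    sig = model_table[model_table["significant"] & (model_table["model_class"] == "interacting")]
    sig_pairs = set(zip(sig["gene_id"], sig["peak_id"]))

    gene_pos = genes.set_index("name")
    peak_pos = peaks.set_index("name")
    pmid = ((peak_pos["start"] + peak_pos["end"]) // 2).to_dict()
    gtss = gene_pos["tss"].to_dict()
    gchrom = gene_pos["chrom"].to_dict()
    pchrom = peak_pos["chrom"].to_dict()

    feats = pd.DataFrame({
        "chrom": [gchrom[g] for g in pairs["gene_id"]],
        "pos": [gtss[g] for g in pairs["gene_id"]],
    })
    gene_region = assign_to_tads(feats, tads, chrom_lengths).to_numpy()
    pfeats = pd.DataFrame({
        "chrom": [pchrom[p] for p in pairs["peak_id"]],
        "pos": [pmid[p] for p in pairs["peak_id"]],
    })
    peak_region = assign_to_tads(pfeats, tads, chrom_lengths).to_numpy()

    # boundary proximity of the peak midpoint
    boundaries: dict[str, np.ndarray] = {}
    for chrom, grp in tads.groupby("chrom"):
        boundaries[chrom] = np.sort(np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy()]))
    prox = np.zeros(len(pairs), dtype=bool)
    for i, (c, p) in enumerate(zip(pfeats["chrom"], pfeats["pos"])):
        b = boundaries.get(c)
        if b is not None and b.size:
            prox[i] = np.min(np.abs(b - p)) <= window_bp

    intra = (gene_region == peak_region) & np.char.startswith(gene_region.astype(str), "tad:")
    interacting = np.array([
        (g, p) in sig_pairs for g, p in zip(pairs["gene_id"], pairs["peak_id"])
    ])

    keep = ~prox if exclude_boundary_proximal else np.ones(len(pairs), dtype=bool)
    a = int((intra & interacting & keep).sum())       # intra, interacting
    b_ = int((~intra & interacting & keep).sum())     # extra, interacting
    c = int((intra & ~interacting & keep).sum())      # intra, non-interacting
    d = int((~intra & ~interacting & keep).sum())     # extra, non-interacting

    table = [[a, b_], [c, d]]
    haldane = False
    if min(a, b_, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b_ + 0.5) * (c + 0.5))
        haldane = True
    else:
        odds = (a * d) / (b_ * c)
    _, p_value = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        contingency=((a, b_), (c, d)),
        odds_ratio=float(odds),
        p_value=float(p_value),
        haldane_corrected=haldane,
        n_boundary_proximal_excluded=int(prox.sum()) if exclude_boundary_proximal else 0,
    )


def standardize_tad_coords(
    model_table: pd.DataFrame,
    tads: pd.DataFrame,
    genes: pd.DataFrame,
    peaks: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Gene-relative loop offsets on a standard scale for intra-TAD models.

    For each model whose gene TSS and peak midpoint share a TAD, returns the
    signed standardized offset in [-0.5, 0.5]: magnitude = loop distance / L,
    sign positive when the peak lies downstream of the TSS along the linear
    sequence. Models whose gene and peak occupy different TADs are excluded
    and counted (second return value).
    """
    gene_pos = genes.set_index("name")
    peak_pos = peaks.set_index("name")
    pmid = ((peak_pos["start"] + peak_pos["end"]) // 2).to_dict()
    gtss = gene_pos["tss"].to_dict()
    gchrom = gene_pos["chrom"].to_dict()

    tad_by_id = _tad_lookup(tads)
    feats_g = pd.DataFrame({
        "chrom": [gchrom[g] for g in model_table["gene_id"]],
        "pos": [gtss[g] for g in model_table["gene_id"]],
    })
    feats_p = pd.DataFrame({
        "chrom": [peak_pos.loc[p, "chrom"] for p in model_table["peak_id"]],
        "pos": [pmid[p] for p in model_table["peak_id"]],
    })
    greg = assign_to_tads(feats_g, tads, chrom_lengths).to_numpy()
    preg = assign_to_tads(feats_p, tads, chrom_lengths).to_numpy()

    rows, excluded = [], 0
    for i in range(len(model_table)):
        if greg[i] != preg[i] or not str(greg[i]).startswith("tad:"):
            excluded += 1
            continue
        tad = tad_by_id[greg[i]]
        tss, mid = int(feats_g["pos"].iloc[i]), int(feats_p["pos"].iloc[i])
        d = loop_distance(tss, mid, tad)
        sign = 1.0 if mid >= tss else -1.0
        rows.append({
            "gene_id": model_table["gene_id"].iloc[i],
            "peak_id": model_table["peak_id"].iloc[i],
            "tad_id": tad.id,
            "loop_offset": sign * d / tad.length,
        })
    return pd.DataFrame(rows, columns=["gene_id", "peak_id", "tad_id", "loop_offset"]), excluded


def _oriented_offset(tss: int, pos: int, strand: str) -> int:
    """Signed bp offset of pos from TSS, positive downstream of transcription."""
    off = pos - tss
    return off if strand == "+" else -off


def capture_window(
    model_table: pd.DataFrame,
    genes: pd.DataFrame,
    markers: pd.DataFrame,
    peaks: pd.DataFrame,
    q: float = 0.95,
    min_models: int = 20,
) -> tuple[float, float]:
    """Smallest (upstream_bp, downstream_bp) window around the TSS covering a
    fraction >= q of significant interacting models on each side.

    A model's upstream extent is how far upstream of the TSS its farthest
    element (variant locus or peak midpoint) lies (0 when both are
    downstream), and symmetrically downstream. The returned pair are the
    ``q``-th order-statistic quantiles of those two distributions. Refuses
    when fewer than ``min_models`` significant interacting models exist.
    """
    sig = model_table[model_table["significant"] & (model_table["model_class"] == "interacting")]
    if len(sig) < min_models:
        raise ValueError(
            f"only {len(sig)} significant interacting models (< {min_models}); "
            "quantile estimate would be unstable"
        )
    gene_pos = genes.set_index("name")
    pmid = peaks.set_index("name")
    pmid = ((pmid["start"] + pmid["end"]) // 2).to_dict()
    mpos = markers.set_index("name")["start"].to_dict()

    ups, downs = [], []
    for _, row in sig.iterrows():
        tss = int(gene_pos.loc[row["gene_id"], "tss"])
        strand = gene_pos.loc[row["gene_id"], "strand"]
        offs = [
            _oriented_offset(tss, int(mpos[row["variant_id"]]), strand),
            _oriented_offset(tss, int(pmid[row["peak_id"]]), strand),
        ]
        ups.append(max(0, -min(offs)))
        downs.append(max(0, max(offs)))
    up = float(np.quantile(ups, q, method="higher"))
    down = float(np.quantile(downs, q, method="higher"))
    return up, down


def search_efficiency_profiles(
    dataset,
    model_table: pd.DataFrame,
    max_radius: int = 2_500_000,
    bin_bp: int = 100_000,
) -> pd.DataFrame:
    """Per-distance-bin interacting percentage and pair density, comparing a
    linear-sequence search with a TAD-limited search.

    For every (gene, peak) pair with the peak midpoint within ``max_radius``
    of the gene TSS (same chromosome), the signed TSS offset is binned.
    Linear mode counts all such pairs; TAD mode only pairs sharing the gene's
    TAD. A pair is interacting when it appears in at least one significant
    interacting model. Returns a tidy frame (bin_start, bin_end, mode,
    n_pairs, n_interacting, pct_interacting).
    """
    if bin_bp <= 0:
        raise ValueError("bin width must be positive")
    chrom_lengths = dict(dataset.layout.chromosomes)
    genes, peaks, tads = dataset.genes, dataset.peaks, dataset.tads
    pmid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()

    sig = model_table[model_table["significant"] & (model_table["model_class"] == "interacting")]
    sig_pairs = set(zip(sig["gene_id"], sig["peak_id"]))

    greg = assign_to_tads(
        pd.DataFrame({"chrom": genes["chrom"], "pos": genes["tss"]}), tads, chrom_lengths
    ).to_numpy()
    preg = assign_to_tads(
        pd.DataFrame({"chrom": peaks["chrom"], "pos": pmid}), tads, chrom_lengths
    ).to_numpy()

    edges = np.arange(-max_radius, max_radius + bin_bp, bin_bp)
    n_bins = len(edges) - 1
    counts = {m: np.zeros(n_bins, dtype=int) for m in ("linear", "tad")}
    hits = {m: np.zeros(n_bins, dtype=int) for m in ("linear", "tad")}

    for gi, gene in genes.iterrows():
        same = np.flatnonzero((peaks["chrom"] == gene["chrom"]).to_numpy())
        offs = pmid[same] - int(gene["tss"])
        within = np.abs(offs) <= max_radius
        same, offs = same[within], offs[within]
        if len(same) == 0:
            continue
        b = np.clip(np.searchsorted(edges, offs, side="right") - 1, 0, n_bins - 1)
        is_sig = np.array([
            (gene["name"], peaks["name"].iloc[pi]) in sig_pairs for pi in same
        ])
        np.add.at(counts["linear"], b, 1)
        np.add.at(hits["linear"], b, is_sig.astype(int))
        shared = (preg[same] == greg[gi]) & str(greg[gi]).startswith("tad:")
        np.add.at(counts["tad"], b[shared], 1)
        np.add.at(hits["tad"], b[shared], is_sig[shared].astype(int))

    rows = []
    for mode in ("linear", "tad"):
        for k in range(n_bins):
            n_pairs = int(counts[mode][k])
            n_int = int(hits[mode][k])
            rows.append({
                "bin_start": int(edges[k]),
                "bin_end": int(edges[k + 1]),
                "mode": mode,
                "n_pairs": n_pairs,
                "n_interacting": n_int,
                "pct_interacting": (100.0 * n_int / n_pairs) if n_pairs else 0.0,
            })
    return pd.DataFrame(rows)


def gene_boundary_proximity(
    genes: pd.DataFrame, tads: pd.DataFrame, near_bp: int
) -> tuple[float, pd.Series]:
    """Fraction of genes with a TAD boundary within ``near_bp`` upstream of
    the TSS (upstream defined by strand). Returns (fraction, per-gene flags).
    """
    boundaries = {
        chrom: np.sort(np.concatenate([grp["start"].to_numpy(), grp["end"].to_numpy()]))
        for chrom, grp in tads.groupby("chrom")
    }
    flags = pd.Series(False, index=genes.index)
    if near_bp <= 0:
        return 0.0, flags
    for i, gene in genes.iterrows():
        b = boundaries.get(gene["chrom"])
        if b is None or not b.size:
            continue
        tss = int(gene["tss"])
        if gene["strand"] == "+":
            up = b[(b <= tss) & (b >= tss - near_bp)]
        else:
            up = b[(b >= tss) & (b <= tss + near_bp)]
        flags.iloc[i] = bool(up.size)
    return float(flags.mean()) if len(flags) else 0.0, flags
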