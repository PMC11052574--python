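"""PWM motif scanning, peak annotation and SNP-in-motif profiles.

Scanning scores every sequence window on both strands with the log2
likelihood ratio of a position-weight matrix against a background base
composition. P-values are exact tail probabilities of the score under the
background, computed by dynamic programming over a score-discretized matrix:
the log-odds matrix is rounded to integer multiples of a small bin width
(1000 bins over the matrix's score range by default), and the distribution
of integer window scores under the background is accumulated position by
position. The p-value attached to a hit uses the same rounded matrix, so it
is exact for the discretized score; the only approximation is the matrix
rounding itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

# floor applied to log-odds of zero-probability bases (documented stand-in
# for -inf; far below any attainable passing score)
_LOG_FLOOR = -64.0


@dataclass
class PWM:
    """Position probability matrix over A, C, G, T plus a background."""

    matrix: np.ndarray                      # (L, 4) probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (L, 4)")
        if (self.matrix < 0).any() or (self.background < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM row must sum to 1 (tol 1e-6)")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASE_ORDER[i] for i in np.argmax(self.matrix, axis=1))

    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p_ij / bg_j), floored for zero probabilities."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.matrix / self.background)
        return np.maximum(lo, _LOG_FLOOR)

    def reverse_complement(self) -> "PWM":
        rc = self.matrix[::-1, ::-1].copy()
        return PWM(rc, self.background[::-1].copy(), name=self.name + "_rc")

    @classmethod
    def from_file(cls, path: str) -> "PWM":
        """Read the plain-text probability format written by :meth:`write`.

        Format: an optional ``>name`` header, optional ``#background: a c g t``
        line, then one whitespace-separated row of four probabilities
        (A C G T order) per motif position. Counts matrices from other
        dialects should be converted to row-normalised probabilities first.
        """
        name, bg, rows = "motif", np.full(4, 0.25), []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].strip()
                elif line.startswith("#background:"):
                    bg = np.array([float(v) for v in line.split(":", 1)[1].split()])
                elif line.startswith("#"):
                    continue
                else:
                    rows.append([float(v) for v in line.split()])
        return cls(np.array(rows), bg, name=name)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            fh.write("#background: " + " ".join(f"{v:.6f}" for v in self.background) + "\n")
            for row in self.matrix:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


@dataclass(frozen=True)
class MotifHit:
    """One PWM match: [start, end) on chrom/sequence, strand, score, p."""

    chrom: str
    start: int
    end: int
    strand: str
    score: float
    p_value: float


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    out = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def _discretize(log_odds: np.ndarray, n_bins: int) -> tuple[np.ndarray, float]:
    """Round the log-odds matrix to integer multiples of a bin width chosen
    so the full score range spans ``n_bins`` bins."""
    span = float(log_odds.max() - log_odds.min())
    delta = span / n_bins if span > 0 else 1.0
    return np.rint(log_odds / delta).astype(np.int64), delta


def score_pvalue_table(pwm: PWM, n_bins: int = 1000) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact background tail distribution of discretized window scores.

    Returns (int_matrix, tail, delta): ``int_matrix`` the rounded log-odds
    matrix (L, 4) in units of ``delta``; ``tail[s - smin]`` the probability
    that a background window scores >= s (integer scores smin..smax).
    """
    imat, delta = _discretize(pwm.log_odds(), n_bins)
    lo = imat.min(axis=1).sum()
    hi = imat.max(axis=1).sum()
    # convolve per-position score distributions under the background
    cur = np.array([1.0])
    cur_lo = 0
    for pos in range(pwm.length):
        row = imat[pos]
        rlo, rhi = row.min(), row.max()
        new = np.zeros(len(cur) + (rhi - rlo))
        for b in range(4):
            new[row[b] - rlo : row[b] - rlo + len(cur)] += pwm.background[b] * cur
        cur = new
        cur_lo += rlo
    assert cur_lo == lo and len(cur) == hi - lo + 1
    tail = np.cumsum(cur[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return imat, tail, delta


def scan_pwm(
    sequence: str,
    pwm: PWM,
    p_threshold: float = 1e-4,
    chrom: str = "seq",
    n_bins: int = 1000,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan a sequence for PWM matches with exact-DP score p-values.

    Windows containing N (or any non-ACGT base) are skipped. Hits with
    p <= ``p_threshold`` on either strand are returned sorted by position;
    a motif longer than the sequence yields an empty list.
    """
    if pwm.length > 20:
        raise ValueError("motif length must be <= 20")
    L = pwm.length
    enc = _encode(sequence)
    if L > len(enc):
        return []

    imat, tail, delta = score_pvalue_table(pwm, n_bins)
    smin = imat.min(axis=1).sum()

    strands = [("+", imat)]
    if both_strands:
        rc = imat[::-1, ::-1]
        strands.append(("-", rc))

    # windowed integer scores; invalid bases poison their windows
    valid = enc >= 0
    enc_safe = np.where(valid, enc, 0)
    n_win = len(enc) - L + 1
    win_valid = np.ones(n_win, dtype=bool)
    for k in range(L):
        win_valid &= valid[k : k + n_win]

    hits: list[MotifHit] = []
    for strand, mat in strands:
        scores = np.zeros(n_win, dtype=np.int64)
        for k in range(L):
            scores += mat[k, enc_safe[k : k + n_win]]
        pvals = tail[np.clip(scores - smin, 0, len(tail) - 1)]
        for w in np.flatnonzero(win_valid & (pvals <= p_threshold)):
            hits.append(
                MotifHit(chrom, int(w), int(w) + L, strand,
                         float(scores[w] * delta), float(pvals[w]))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def hits_to_bed(hits: list[MotifHit], path: str, name: str = "motif") -> None:
    """Write hits as BED6+ (chrom start end name score strand p_value)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{name}\t{h.score:.4f}\t{h.strand}\t{h.p_value:.3g}\n"
            )


# ---------------------------------------------------------------------------
# peak annotation
# ---------------------------------------------------------------------------

def annotate_peaks(peaks: pd.DataFrame, **categories: pd.DataFrame | None):
    """Midpoint overlap of peaks against named interval categories.

    ``categories`` maps a name (gene_bodies, exons, promoters, enhancers, ...)
    to an interval table (chrom, start, end). A peak counts for a category
    when its midpoint lies inside any interval of that category; categories
    are non-exclusive. ``None`` categories are skipped with a warning.
    Returns (percentages dict, per-peak boolean flag DataFrame).
    """
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    chroms = peaks["chrom"].to_numpy()
    flags = pd.DataFrame(index=peaks.index)
    pct: dict[str, float] = {}
    for name, table in categories.items():
        if table is None:
            warnings.warn(f"annotation category {name!r} missing; skipped")
            continue
        trees: dict[str, IntervalTree] = {}
        for chrom, grp in table.groupby("chrom"):
            ivs = [(int(s), int(e)) for s, e in zip(grp["start"], grp["end"]) if e > s]
            trees[chrom] = IntervalTree.from_tuples(ivs) if ivs else IntervalTree()
        hit = np.array([
            bool(trees[c][m]) if c in trees else False for c, m in zip(chroms, mids)
        ])
        flags[name] = hit
        pct[name] = float(100.0 * hit.mean()) if len(hit) else 0.0
    return pct, flags


def snp_motif_density(hits: list[MotifHit], snp_positions) -> tuple[np.ndarray, float]:
    """Per-motif-position SNP counts across hits, strand-aware.

    SNPs are point coordinates on the same sequence/chromosome namespace as
    the hits. Offsets within a hit are measured from the motif's 5' end on
    its own strand (a minus-strand hit mirrors the coordinate). Returns
    (counts array of motif length, fraction of hits containing >= 1 SNP).
    """
    if not hits:
        return np.zeros(0, dtype=int), 0.0
    L = hits[0].end - hits[0].start
    counts = np.zeros(L, dtype=int)
    snps = pd.DataFrame(snp_positions, columns=["chrom", "pos"]) if not isinstance(
        snp_positions, pd.DataFrame
    ) else snp_positions
    by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in snps.groupby("chrom")}
    n_with = 0
    for h in hits:
        pos = by_chrom.get(h.chrom, np.array([], dtype=int))
        inside = pos[(pos >= h.start) & (pos < h.end)]
        if inside.size:
            n_with += 1
        for s in inside:
            off = int(s - h.start) if h.strand == "+" else int(h.end - 1 - s)
            counts[off] += 1
    return counts, n_with / len(hits)


def negative_effector_peaks(
    model_table: pd.DataFrame,
    min_models: int = 10,
    min_negative_fraction: float = 0.5,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Split heavily-modelled peaks by the sign balance of their ATAC effects.

    Among significant interacting models, a peak participating in at least
    ``min_models`` of them is a *negative effector* when at least
    ``min_negative_fraction`` of those models have b2 < 0, and a *positive
    effector* otherwise. Returns (negative ids, positive ids, per-peak stats).
    """
    sig = model_table[model_table["significant"] & (model_table["model_class"] == "interacting")]
    stats_rows = []
    neg, pos = [], []
    for peak_id, grp in sig.groupby("peak_id"):
        n = len(grp)
        frac_neg = float((grp["beta2"] < 0).mean())
        stats_rows.append({"peak_id": peak_id, "n_models": n, "frac_negative": frac_neg})
        if n >= min_models:
            (neg if frac_neg >= min_negative_fraction else pos).append(str(peak_id))
    return sorted(neg), sorted(pos), pd.DataFrame(
        stats_rows, columns=["peak_id", "n_models", "frac_negative"]
    )
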