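"""Genotype-by-accessibility interaction regression scan.

Each tested trio (gene, variant, peak) is fit by ordinary least squares to

    y = b0 + b1*x1 + b2*x2 + b3*x1*x2 + eps

with y the gene's expression (log2 TPM), x1 the dosage genotype (0/1/2) and
x2 the peak intensity (TMM scale). Terms are retained by backward elimination
on AIC (honouring marginality: the interaction drops before its main
effects), the interaction is tested against the additive null with a partial
F-test on 1 and n-4 degrees of freedom, and raw p-values are Bonferroni
adjusted over the number of successfully fit trios in the batch.

Model classes follow term retention:
{x1,x2,x1x2} interacting / {x1,x2} additive / {x1} genotype_only /
{x2} atac_only / {} null.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import SyntheticDataset

TERMS = ("x1", "x2", "x1x2")
MODEL_CLASSES = ("null", "genotype_only", "atac_only", "additive", "interacting")

# hierarchical submodels as design-column subsets (column 0 is the intercept)
_SUBMODELS = {
    frozenset(): (0,),
    frozenset({"x1"}): (0, 1),
    frozenset({"x2"}): (0, 2),
    frozenset({"x1", "x2"}): (0, 1, 2),
    frozenset({"x1", "x2", "x1x2"}): (0, 1, 2, 3),
}

_AIC_TIE_TOL = 1e-12
# Relative floor applied to RSS inside AIC so that numerically-zero residuals
# (noiseless planted data) compare as equal and the simpler model wins.
_RSS_FLOOR = 1e-12


class DegenerateInputError(ValueError):
    """Constant genotype or intensity vector: the trio cannot be fit."""


@dataclass
class TrioFit:
    """One gene-variant-peak regression fit."""

    gene_id: str | None
    variant_id: str | None
    peak_id: str | None
    betas: tuple[float, float, float, float]
    bse: tuple[float, float, float, float] | None
    retained: frozenset | None
    rss_full: float
    rss_null: float
    f_stat: float
    p_raw: float
    p_adj: float | None = None
    model_class: str | None = None
    n: int = 0
    flagged_collinear: bool = False


@dataclass
class ScanPlan:
    """What to enumerate: random intrachromosomal trios or TAD-constrained."""

    mode: str = "random_intrachromosomal"
    n_models: int | None = 100_000
    seed: int | None = 0
    alpha: float = 1e-7

    def __post_init__(self):
        if self.mode not in ("random_intrachromosomal", "tad_constrained"):
            raise ValueError(f"unknown scan mode {self.mode!r}")
        if self.mode == "random_intrachromosomal" and self.seed is None:
            raise ValueError("random mode requires a seed")


def _validate_vectors(y, g, a):
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    a = np.asarray(a, dtype=float)
    if not (len(y) == len(g) == len(a)):
        raise ValueError("y, g, a must have equal length")
    if len(y) < 8:
        raise ValueError("need at least 8 samples")
    if np.ptp(g) == 0:
        raise DegenerateInputError("constant genotype vector")
    if np.ptp(a) == 0:
        raise DegenerateInputError("constant peak-intensity vector")
    return y, g, a


def _design(g, a):
    return np.column_stack([np.ones_like(g), g, a, g * a])


def _rss(y, X, cols):
    beta, _, _, _ = np.linalg.lstsq(X[:, cols], y, rcond=None)
    resid = y - X[:, cols] @ beta
    return float(resid @ resid), beta


def fit_trio(y, g, a, gene_id=None, variant_id=None, peak_id=None) -> TrioFit:
    """OLS fit of the 4-term interaction model plus the partial F-test of the
    interaction against the 3-term additive null.

    Raises :class:`DegenerateInputError` for constant ``g`` or ``a``. A design
    whose interaction column is collinear with the main effects is returned
    flagged with ``f_stat``/``p_raw`` undefined (NaN).
    """
    y, g, a = _validate_vectors(y, g, a)
    n = len(y)
    X = _design(g, a)
    yty = float(y @ y)
    tol = _RSS_FLOOR * (yty + 1.0)

    rank = np.linalg.matrix_rank(X)
    rss_full, beta = _rss(y, X, (0, 1, 2, 3))
    rss_null, _ = _rss(y, X, (0, 1, 2))
    rss_full = max(rss_full, 0.0)
    rss_null = max(rss_null, rss_full)

    if rank < 4:
        return TrioFit(
            gene_id, variant_id, peak_id,
            betas=tuple(beta), bse=None, retained=None,
            rss_full=rss_full, rss_null=rss_null,
            f_stat=float("nan"), p_raw=float("nan"),
            n=n, flagged_collinear=True,
        )

    num = max(rss_null - rss_full, 0.0)
    if rss_full <= tol:
        if num <= tol:
            f_stat, p_raw = 0.0, 1.0
        else:
            f_stat, p_raw = float("inf"), 0.0
    else:
        f_stat = num / (rss_full / (n - 4))
        p_raw = float(stats.f.sf(f_stat, 1, n - 4))

    sigma2 = rss_full / (n - 4)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    bse = tuple(np.sqrt(np.diag(cov)))

    return TrioFit(
        gene_id, variant_id, peak_id,
        betas=tuple(beta), bse=bse, retained=None,
        rss_full=rss_full, rss_null=rss_null,
        f_stat=f_stat, p_raw=p_raw, n=n,
    )


def aic(rss: float, n: int, k: int, yty: float | None = None) -> float:
    """AIC = n*ln(RSS/n) + 2k with a relative floor on RSS (see module doc)."""
    floor = _RSS_FLOOR * ((yty if yty is not None else 0.0) + 1.0)
    return n * math.log(max(rss, floor) / n) + 2 * k


def _droppable(current: frozenset) -> list[str]:
    if "x1x2" in current:
        return ["x1x2"]  # marginality: interaction must drop first
    return [t for t in ("x1", "x2") if t in current]


def stepwise_select(y, g, a) -> frozenset:
    """Backward elimination from the full model on AIC, marginality-honouring.

    At each step the drop that most decreases AIC is taken; ties within 1e-12
    prefer dropping the interaction, then x2. Stops when no drop decreases AIC.
    """
    y, g, a = _validate_vectors(y, g, a)
    n = len(y)
    X = _design(g, a)
    yty = float(y @ y)

    aics = {}
    for terms, cols in _SUBMODELS.items():
        rss, _ = _rss(y, X, cols)
        aics[terms] = aic(rss, n, len(cols), yty)

    current = frozenset(TERMS)
    while True:
        candidates = _droppable(current)
        if not candidates:
            break
        scored = [(aics[current - {t}], t) for t in candidates]
        best_aic = min(s[0] for s in scored)
        tied = [t for s_aic, t in scored if s_aic - best_aic <= _AIC_TIE_TOL]
        drop = "x1x2" if "x1x2" in tied else ("x2" if "x2" in tied else tied[0])
        if best_aic < aics[current]:
            current = current - {drop}
        else:
            break
    return current


def classify_model(retained: Iterable[str]) -> str:
    """Map a marginality-respecting retained-term set to its model class."""
    r = frozenset(retained)
    if not r <= frozenset(TERMS):
        raise ValueError(f"unknown terms in retained set: {set(r) - set(TERMS)}")
    if "x1x2" in r and not {"x1", "x2"} <= r:
        raise ValueError(f"non-hierarchical retained set: {set(r)}")
    if r == frozenset(TERMS):
        return "interacting"
    if r == frozenset({"x1", "x2"}):
        return "additive"
    if r == frozenset({"x1"}):
        return "genotype_only"
    if r == frozenset({"x2"}):
        return "atac_only"
    return "null"


def bonferroni_adjust(p_values: Sequence[float], m: int) -> np.ndarray:
    """p -> min(1, p*m) for family size m (m >= number of p-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if m < p.size:
        raise ValueError(f"family size {m} smaller than number of tests {p.size}")
    return np.minimum(1.0, p * m)


def fit_and_classify(y, g, a, **ids) -> TrioFit:
    """Full single-trio pipeline: OLS + F-test + AIC selection + class label."""
    fit = fit_trio(y, g, a, **ids)
    if fit.flagged_collinear:
        return fit
    fit.retained = stepwise_select(y, g, a)
    fit.model_class = classify_model(fit.retained)
    return fit


# ---------------------------------------------------------------------------
# batched scan machinery
# ---------------------------------------------------------------------------

_CODE_TO_RETAINED = {
    0: frozenset(),
    1: frozenset({"x1"}),
    2: frozenset({"x2"}),
    3: frozenset({"x1", "x2"}),
    4: frozenset({"x1", "x2", "x1x2"}),
}
_CODE_TO_CLASS = {c: classify_model(r) for c, r in _CODE_TO_RETAINED.items()}
_SUBSET_COLS = [(0,), (0, 1), (0, 2), (0, 1, 2), (0, 1, 2, 3)]


def _batch_rss(Y, G, A):
    """RSS of all five hierarchical submodels for a batch of trios.

    Y, G, A: (m, n). Returns (rss (m,5), betas_full (m,4), yty (m,),
    singular mask (m,))."""
    m, n = Y.shape
    ones = np.ones_like(G)
    X = np.stack([ones, G, A, G * A], axis=2)  # (m, n, 4)
    Gram = np.einsum("mnp,mnq->mpq", X, X)
    Xty = np.einsum("mnp,mn->mp", X, Y)
    yty = np.einsum("mn,mn->m", Y, Y)

    rss = np.empty((m, 5))
    betas_full = np.zeros((m, 4))
    singular = np.zeros(m, dtype=bool)
    for si, cols in enumerate(_SUBSET_COLS):
        cg = Gram[np.ix_(np.arange(m), cols, cols)]
        cx = Xty[:, cols]
        try:
            beta = np.linalg.solve(cg, cx[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.empty_like(cx)
            for i in range(m):
                try:
                    beta[i] = np.linalg.solve(cg[i], cx[i])
                except np.linalg.LinAlgError:
                    beta[i] = (np.linalg.pinv(cg[i]) @ cx[i])
                    if si == 4:
                        singular[i] = True
        if si == 4:
            # flag near-singular full designs via condition estimate
            with np.errstate(all="ignore"):
                cond = np.linalg.cond(cg)
            singular |= ~np.isfinite(cond) | (cond > 1e12)
            betas_full = beta
        rss[:, si] = np.maximum(yty - np.einsum("mp,mp->m", beta, cx), 0.0)
    # enforce monotonicity of nested models
    rss[:, 4] = np.minimum(rss[:, 4], rss[:, 3])
    rss[:, 3] = np.minimum(rss[:, 3], np.minimum(rss[:, 1], rss[:, 2]))
    return rss, betas_full, yty, singular


def _batch_select(rss, yty, n):
    """Vectorised backward-AIC path over the five hierarchical submodels.

    Returns the retained-model code per trio (index into _CODE_TO_RETAINED)."""
    m = rss.shape[0]
    floor = _RSS_FLOOR * (yty + 1.0)
    ks = np.array([1, 2, 2, 3, 4])
    aics = n * np.log(np.maximum(rss, floor[:, None]) / n) + 2 * ks  # (m,5)

    code = np.full(m, 4, dtype=np.int8)
    # step 1: full -> additive (only legal drop is the interaction)
    move = aics[:, 3] < aics[:, 4]
    code[move] = 3
    at_add = code == 3
    # step 2: additive -> {x1} (drop x2) or {x2} (drop x1); tie drops x2
    a_g, a_a = aics[:, 1], aics[:, 2]
    prefer_g = (a_g <= a_a + _AIC_TIE_TOL)  # dropping x2 keeps x1
    best = np.where(prefer_g, a_g, a_a)
    move2 = at_add & (best < aics[:, 3])
    code[move2 & prefer_g] = 1
    code[move2 & ~prefer_g] = 2
    # step 3: single term -> null
    for c in (1, 2):
        at = code == c
        move3 = at & (aics[:, 0] < aics[:, c])
        code[move3] = 0
    return code, aics


def _enumerate_regions(tads: pd.DataFrame, chrom: str, chrom_len: int) -> pd.DataFrame:
    """Contiguous partition of a chromosome into TAD and inter-TAD regions."""
    sub = tads[tads["chrom"] == chrom].sort_values("start")
    rows, pos, k = [], 0, 0
    for _, t in sub.iterrows():
        if t["start"] > pos:
            rows.append((chrom, pos, int(t["start"]), f"inter:{chrom}:{k}", "inter"))
            k += 1
        rows.append((chrom, int(t["start"]), int(t["end"]), f"tad:{t['name']}", "tad"))
        pos = int(t["end"])
    if pos < chrom_len:
        rows.append((chrom, pos, chrom_len, f"inter:{chrom}:{k}", "inter"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id", "kind"])


class ScanResults:
    """Container for a completed scan: per-trio table + run manifest.

    ``table`` columns: gene_id, variant_id, peak_id, chrom, beta0..beta3,
    retained, model_class, rss_full, rss_null, f_stat, p_raw, p_adj,
    significant, n.
    """

    def __init__(self, table: pd.DataFrame, manifest: dict):
        self.table = table
        self.manifest = manifest

    @property
    def alpha(self) -> float:
        return self.manifest["alpha"]

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def significant_interacting(self) -> pd.DataFrame:
        t = self.table
        return t[t["significant"] & (t["model_class"] == "interacting")]

    def class_counts(self) -> pd.Series:
        return self.table["model_class"].value_counts().reindex(MODEL_CLASSES, fill_value=0)

    def unique_feature_counts(self) -> pd.DataFrame:
        rows = []
        for cls, grp in self.table.groupby("model_class"):
            rows.append({
                "model_class": cls,
                "n_models": len(grp),
                "n_genes": grp["gene_id"].nunique(),
                "n_variants": grp["variant_id"].nunique(),
                "n_peaks": grp["peak_id"].nunique(),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        man = self.manifest
        lines = [
            "Genotype-by-accessibility interaction scan",
            "=" * 46,
            f"mode:              {man['mode']}",
            f"trios fit:         {man['family_size']}",
            f"skipped degenerate:{man['n_skipped_degenerate']:>7}",
            f"flagged collinear: {man['n_flagged_collinear']:>7}",
            f"alpha (adjusted):  {man['alpha']:g}",
            f"significant models:{int(self.table['significant'].sum()):>7}",
            "",
            "model class      models   genes  variants  peaks",
        ]
        for _, r in self.unique_feature_counts().iterrows():
            lines.append(
                f"{r['model_class']:<15}{r['n_models']:>8}{r['n_genes']:>8}"
                f"{r['n_variants']:>9}{r['n_peaks']:>7}"
            )
        sig = self.significant
        if len(sig):
            lines += [
                "",
                f"significant: {sig['gene_id'].nunique()} genes, "
                f"{sig['variant_id'].nunique()} variants, {sig['peak_id'].nunique()} peaks",
            ]
        return "\n".join(lines)

    def write(self, table_path: str, manifest_path: str | None = None) -> None:
        out = self.table.copy()
        out.to_csv(table_path, sep="\t", index=False)
        if manifest_path:
            with open(manifest_path, "w") as fh:
                json.dump(self.manifest, fh, indent=2, default=str)


def _sample_distinct(rng, total: int, k: int) -> np.ndarray:
    if k >= total:
        return np.arange(total)
    if total <= 2_000_000:
        return rng.choice(total, size=k, replace=False)
    seen: set[int] = set()
    while len(seen) < k:
        draw = rng.integers(0, total, size=int((k - len(seen)) * 1.2) + 16)
        seen.update(int(v) for v in draw)
        if len(seen) > k:
            seen = set(list(seen)[:k])
    return np.fromiter(seen, dtype=np.int64, count=k)


def enumerate_trios(dataset: SyntheticDataset, plan: ScanPlan) -> np.ndarray:
    """Return an (m, 3) array of (gene_idx, marker_idx, peak_idx) to fit."""
    genes, markers, peaks = dataset.genes, dataset.markers, dataset.peaks
    if plan.mode == "random_intrachromosomal":
        rng = np.random.default_rng(plan.seed)
        per_chrom = []
        for chrom, _ in dataset.layout.chromosomes:
            gi = np.flatnonzero(genes["chrom"] == chrom)
            mi = np.flatnonzero(markers["chrom"] == chrom)
            pi = np.flatnonzero(peaks["chrom"] == chrom)
            per_chrom.append((gi, mi, pi, len(gi) * len(mi) * len(pi)))
        totals = np.array([t for *_, t in per_chrom], dtype=np.int64)
        T = int(totals.sum())
        k = T if plan.n_models is None else min(plan.n_models, T)
        flat = np.sort(_sample_distinct(rng, T, k))
        bounds = np.concatenate([[0], np.cumsum(totals)])
        out = np.empty((k, 3), dtype=np.int64)
        for ci, (gi, mi, pi, t) in enumerate(per_chrom):
            sel = flat[(flat >= bounds[ci]) & (flat < bounds[ci + 1])] - bounds[ci]
            nm, npk = len(mi), len(pi)
            lo, hi = np.searchsorted(flat, [bounds[ci], bounds[ci + 1]])
            out[lo:hi, 0] = gi[sel // (nm * npk)]
            out[lo:hi, 1] = mi[(sel // npk) % nm]
            out[lo:hi, 2] = pi[sel % npk]
        return out

    # tad_constrained
    chrom_len = dict(dataset.layout.chromosomes)
    peak_mid = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    trios = []
    for chrom, clen in dataset.layout.chromosomes:
        regions = _enumerate_regions(dataset.tads, chrom, clen)
        if regions.empty:
            continue
        starts = regions["start"].to_numpy()
        g_idx = np.flatnonzero(genes["chrom"] == chrom)
        m_idx = np.flatnonzero(markers["chrom"] == chrom)
        p_idx = np.flatnonzero(peaks["chrom"] == chrom)
        m_pos = markers["start"].to_numpy()[m_idx]
        p_pos = peak_mid[p_idx]
        for gi in g_idx:
            tss = int(genes["tss"].iloc[gi])
            r = int(np.searchsorted(starts, tss, side="right") - 1)
            lo = int(regions["start"].iloc[max(r - 1, 0)])
            hi = int(regions["end"].iloc[min(r + 1, len(regions) - 1)])
            mm = m_idx[(m_pos >= lo) & (m_pos < hi)]
            pp = p_idx[(p_pos >= lo) & (p_pos < hi)]
            if len(mm) == 0 or len(pp) == 0:
                continue
            grid = np.array(np.meshgrid(mm, pp, indexing="ij")).reshape(2, -1).T
            block = np.empty((len(grid), 3), dtype=np.int64)
            block[:, 0] = gi
            block[:, 1:] = grid
            trios.append(block)
    if not trios:
        return np.empty((0, 3), dtype=np.int64)
    return np.concatenate(trios, axis=0)


def run_scan(
    dataset: SyntheticDataset,
    plan: ScanPlan,
    chunk_size: int = 8192,
) -> ScanResults:
    """Enumerate trios per ``plan``, fit, select, classify and adjust.

    Degenerate trios (monomorphic marker or zero-variance peak in the sample
    subset) are skipped and counted; collinear designs are flagged and
    excluded from the Bonferroni family (the family is the number of
    successful fits, recorded in the manifest).
    """
    if dataset.expression is None:
        raise ValueError("dataset has no expression matrix; run plant_models first")
    trios = enumerate_trios(dataset, plan)
    n = len(dataset.samples)

    g_var = np.ptp(dataset.dosage, axis=1) > 0
    a_var = np.ptp(dataset.atac, axis=1) > 0
    ok = g_var[trios[:, 1]] & a_var[trios[:, 2]]
    n_degenerate = int((~ok).sum())
    trios = trios[ok]

    parts = []
    n_flagged = 0
    for lo in range(0, len(trios), chunk_size):
        chunk = trios[lo : lo + chunk_size]
        Y = dataset.expression[chunk[:, 0]]
        G = dataset.dosage[chunk[:, 1]]
        A = dataset.atac[chunk[:, 2]]
        rss, betas, yty, singular = _batch_rss(Y, G, A)
        code, _ = _batch_select(rss, yty, n)

        tolv = _RSS_FLOOR * (yty + 1.0)
        rss_full, rss_null = rss[:, 4], rss[:, 3]
        num = np.maximum(rss_null - rss_full, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = num / (rss_full / (n - 4))
        exact = rss_full <= tolv
        f = np.where(exact & (num <= tolv), 0.0, f)
        f = np.where(exact & (num > tolv), np.inf, f)
        p = stats.f.sf(f, 1, n - 4)
        p = np.where(exact & (num <= tolv), 1.0, p)

        keep = ~singular
        n_flagged += int(singular.sum())
        chunk, code = chunk[keep], code[keep]
        parts.append(pd.DataFrame({
            "gene_id": dataset.genes["name"].to_numpy()[chunk[:, 0]],
            "variant_id": dataset.markers["name"].to_numpy()[chunk[:, 1]],
            "peak_id": dataset.peaks["name"].to_numpy()[chunk[:, 2]],
            "chrom": dataset.genes["chrom"].to_numpy()[chunk[:, 0]],
            "beta0": betas[keep, 0], "beta1": betas[keep, 1],
            "beta2": betas[keep, 2], "beta3": betas[keep, 3],
            "retained": [",".join(sorted(_CODE_TO_RETAINED[c])) for c in code],
            "model_class": [_CODE_TO_CLASS[c] for c in code],
            "rss_full": rss_full[keep], "rss_null": rss_null[keep],
            "f_stat": f[keep], "p_raw": p[keep],
        }))

    if parts:
        table = pd.concat(parts, ignore_index=True)
    else:
        table = pd.DataFrame(columns=[
            "gene_id", "variant_id", "peak_id", "chrom", "beta0", "beta1",
            "beta2", "beta3", "retained", "model_class", "rss_full",
            "rss_null", "f_stat", "p_raw",
        ])
    family = len(table)
    table["p_adj"] = bonferroni_adjust(table["p_raw"].to_numpy(), family) if family else []
    table["significant"] = table["p_adj"] < plan.alpha if family else []
    table["n"] = n

    manifest = {
        "mode": plan.mode,
        "seed": plan.seed,
        "alpha": plan.alpha,
        "n_models_requested": plan.n_models,
        "family_size": family,
        "n_skipped_degenerate": n_degenerate,
        "n_flagged_collinear": n_flagged,
        "n_samples": n,
    }
    return ScanResults(table, manifest)
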