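"""Strain CTCF ChIP consensus, binding variance and genotype association.

Replicate ChIP samples from inbred strains give per-peak fold-enrichment
values. A peak is a *consensus* peak when it is detected (fold enrichment
above a detection floor) in at least ``min_samples`` replicates of at least
one strain. Genotype-dependent binding is assayed by grouping samples by the
allele their strain carries at a biallelic SNP and comparing fold enrichment
between the two groups; Welch's unequal-variance t-test is the default (the
replicate groups are not naturally paired), with a pooled-variance Student
option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class ChipPeakMatrix:
    """ChIP peak intervals x replicate samples fold-enrichment matrix."""

    peaks: pd.DataFrame                 # chrom, start, end, name
    fold_enrichment: np.ndarray         # peaks x samples, >= 0
    samples: list[str]
    sample_to_strain: dict[str, str]
    detection_floor: float = 1.0
    consensus: np.ndarray | None = None

    def __post_init__(self):
        self.fold_enrichment = np.asarray(self.fold_enrichment, dtype=float)
        if (self.fold_enrichment < 0).any():
            raise ValueError("fold enrichment must be non-negative")
        if self.fold_enrichment.shape != (len(self.peaks), len(self.samples)):
            raise ValueError("fold_enrichment shape must be (n_peaks, n_samples)")
        missing = [s for s in self.samples if s not in self.sample_to_strain]
        if missing:
            raise ValueError(f"samples without a strain: {missing}")

    @property
    def strains(self) -> list[str]:
        return sorted(set(self.sample_to_strain[s] for s in self.samples))

    def strain_columns(self) -> dict[str, np.ndarray]:
        return {
            st: np.array([j for j, s in enumerate(self.samples)
                          if self.sample_to_strain[s] == st])
            for st in self.strains
        }

    @classmethod
    def from_sample_tables(cls, tables: dict[str, pd.DataFrame],
                           sample_to_strain: dict[str, str],
                           detection_floor: float = 1.0) -> "ChipPeakMatrix":
        """Merge per-sample narrowPeak-like tables (chrom, start, end,
        fold_enrichment) on exact intervals; absent peaks get enrichment 0."""
        samples = list(tables)
        keys: dict[tuple, int] = {}
        for t in tables.values():
            for tup in zip(t["chrom"], t["start"], t["end"]):
                keys.setdefault(tup, len(keys))
        peaks = pd.DataFrame(
            [{"chrom": c, "start": s, "end": e} for (c, s, e) in keys], columns=["chrom", "start", "end"]
        )
        peaks["name"] = [f"chip{i:05d}" for i in range(len(peaks))]
        fe = np.zeros((len(keys), len(samples)))
        for j, s in enumerate(samples):
            t = tables[s]
            for c, st, en, v in zip(t["chrom"], t["start"], t["end"], t["fold_enrichment"]):
                fe[keys[(c, st, en)], j] = v
        return cls(peaks, fe, samples, sample_to_strain, detection_floor)

    def write(self, path: str) -> None:
        out = self.peaks.copy()
        for j, s in enumerate(self.samples):
            out[s] = self.fold_enrichment[:, j]
        if self.consensus is not None:
            out["consensus"] = self.consensus
        out.to_csv(path, sep="\t", index=False)


@dataclass
class AssociationResult:
    """Genotype-vs-binding-intensity test at one peak/SNP."""

    peak_id: str
    snp_id: str
    group_sizes: tuple[int, int]
    t_stat: float
    p_value: float
    testable: bool = True

    def __post_init__(self):
        if self.testable and not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def consensus_peaks(chip: ChipPeakMatrix, min_samples: int = 2) -> tuple[ChipPeakMatrix, pd.Series]:
    """Flag consensus peaks and report the strain-sharing distribution.

    Consensus: detected (enrichment > detection floor) in >= ``min_samples``
    samples of >= 1 strain. The sharing distribution counts, for consensus
    peaks, how many strains each peak is detected in (>= 1 sample per
    strain). Strains with fewer than ``min_samples`` replicates cannot by
    themselves confer consensus and are logged.
    """
    cols = chip.strain_columns()
    small = [st for st, idx in cols.items() if len(idx) < min_samples]
    if small:
        logger.warning("strains with < %d samples cannot confer consensus: %s",
                       min_samples, small)
    if all(len(idx) < min_samples for idx in cols.values()):
        raise ValueError(f"no strain has >= {min_samples} samples")

    detected = chip.fold_enrichment > chip.detection_floor
    consensus = np.zeros(len(chip.peaks), dtype=bool)
    strain_presence = np.zeros((len(chip.peaks), len(cols)), dtype=bool)
    for k, (st, idx) in enumerate(cols.items()):
        per_strain = detected[:, idx].sum(axis=1)
        consensus |= per_strain >= min_samples
        strain_presence[:, k] = per_strain >= 1

    chip.consensus = consensus
    n_strains = strain_presence[consensus].sum(axis=1)
    sharing = pd.Series(n_strains).value_counts().sort_index(ascending=False)
    sharing.index.name = "n_strains"
    return chip, sharing


def fold_variance(chip: ChipPeakMatrix, threshold: float = 10.0) -> pd.DataFrame:
    """Per-peak sample variance (ddof=1) of fold enrichment, its log10, and
    the exceedance flag against ``threshold``. Requires >= 3 samples."""
    if len(chip.samples) < 3:
        raise ValueError("need >= 3 samples for a variance profile")
    var = chip.fold_enrichment.var(axis=1, ddof=1)
    with np.errstate(divide="ignore"):
        log10_var = np.log10(var)
    return pd.DataFrame({
        "peak_id": chip.peaks["name"],
        "variance": var,
        "log10_variance": log10_var,
        "exceeds_threshold": var > threshold,
    })


def genotype_binding_association(
    intensities: np.ndarray,
    alleles: np.ndarray,
    peak_id: str = "",
    snp_id: str = "",
    equal_var: bool = False,
) -> AssociationResult:
    """Two-sample t-test of per-sample fold enrichment grouped by allele.

    ``alleles`` holds 0/1 per sample (biallelic SNP). Welch's test by
    default; ``equal_var=True`` switches to pooled-variance Student. A group
    with fewer than 2 samples makes the result untestable (flagged).
    """
    x = np.asarray(intensities, dtype=float)
    al = np.asarray(alleles)
    levels = np.unique(al)
    if len(levels) != 2:
        return AssociationResult(peak_id, snp_id, (int((al == levels[0]).sum()) if len(levels) else 0, 0),
                                 float("nan"), float("nan"), testable=False)
    g0, g1 = x[al == levels[0]], x[al == levels[1]]
    if len(g0) < 2 or len(g1) < 2:
        return AssociationResult(peak_id, snp_id, (len(g0), len(g1)),
                                 float("nan"), float("nan"), testable=False)
    t, p = stats.ttest_ind(g0, g1, equal_var=equal_var)
    if np.isnan(t) and np.allclose(g0, g0[0]) and np.allclose(g1, g1[0]) and np.isclose(g0[0], g1[0]):
        t, p = 0.0, 1.0  # identical constant groups: no evidence of difference
    return AssociationResult(peak_id, snp_id, (len(g0), len(g1)), float(t), float(p))


def associate_sites(
    chip: ChipPeakMatrix, site_table: pd.DataFrame, equal_var: bool = False
) -> pd.DataFrame:
    """Run the genotype association at every SNP-carrying site.

    ``site_table`` rows align with ``chip.peaks`` (as produced by the CTCF
    world generator) and carry per-strain alleles in ``allele_<strain>``
    columns. Returns a tidy frame of AssociationResult fields.
    """
    strain_of = [chip.sample_to_strain[s] for s in chip.samples]
    rows = []
    for i, site in site_table.iterrows():
        if not site.get("has_snp", True):
            continue
        alleles = np.array([site[f"allele_{st}"] for st in strain_of])
        res = genotype_binding_association(
            chip.fold_enrichment[i], alleles,
            peak_id=str(chip.peaks["name"].iloc[i]),
            snp_id=str(site.get("site_id", i)),
            equal_var=equal_var,
        )
        rows.append({
            "peak_id": res.peak_id, "snp_id": res.snp_id,
            "n_group0": res.group_sizes[0], "n_group1": res.group_sizes[1],
            "t_stat": res.t_stat, "p_value": res.p_value, "testable": res.testable,
        })
    return pd.DataFrame(rows, columns=[
        "peak_id", "snp_id", "n_group0", "n_group1", "t_stat", "p_value", "testable",
    ])


def subset_significance_rates(
    associations: pd.DataFrame,
    subsets: dict[str, set[str] | list[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Proportion of tested peaks with association p < alpha, per named subset.

    Empty subsets are reported with n=0 and an undefined (NaN) proportion.
    """
    tested = associations[associations["testable"]]
    rows = []
    for name, ids in subsets.items():
        ids = set(ids)
        sub = tested[tested["peak_id"].isin(ids)]
        n = len(sub)
        rows.append({
            "subset": name,
            "n": n,
            "n_significant": int((sub["p_value"] < alpha).sum()),
            "proportion": float((sub["p_value"] < alpha).mean()) if n else float("nan"),
        })
    return pd.DataFrame(rows, columns=["subset", "n", "n_significant", "proportion"])


def standard_subsets(
    chip: ChipPeakMatrix,
    model_table: pd.DataFrame | None = None,
    atac_peaks: pd.DataFrame | None = None,
    tads: pd.DataFrame | None = None,
    negative_effectors: list[str] | None = None,
    positive_effectors: list[str] | None = None,
) -> dict[str, set[str]]:
    """Wire up the standard comparison subsets of ChIP peaks.

    all peaks; peaks under ATAC peaks; peaks whose overlapping ATAC peak
    participates in additive / interacting significant models; negative and
    positive effector overlaps; dense-model regions (ChIP peaks in TADs with
    an above-mean count of significant models).
    """
    all_ids = set(chip.peaks["name"])
    subsets: dict[str, set[str]] = {"all": all_ids}

    chip_mid = ((chip.peaks["start"] + chip.peaks["end"]) // 2).to_numpy()
    peak_of_chip: dict[str, str] = {}
    if atac_peaks is not None:
        for ci, (chrom, mid) in enumerate(zip(chip.peaks["chrom"], chip_mid)):
            sub = atac_peaks[(atac_peaks["chrom"] == chrom)
                             & (atac_peaks["start"] <= mid) & (mid < atac_peaks["end"])]
            if not sub.empty:
                peak_of_chip[chip.peaks["name"].iloc[ci]] = sub["name"].iloc[0]
        subsets["under_atac"] = set(peak_of_chip)

    if model_table is not None and peak_of_chip:
        sig = model_table[model_table["significant"]]
        for cls in ("additive", "interacting"):
            cls_peaks = set(sig.loc[sig["model_class"] == cls, "peak_id"])
            subsets[cls] = {c for c, p in peak_of_chip.items() if p in cls_peaks}

    if negative_effectors is not None:
        ne = set(negative_effectors)
        subsets["negative_effectors"] = {c for c, p in peak_of_chip.items() if p in ne}
    if positive_effectors is not None:
        pe = set(positive_effectors)
        subsets["positive_effectors"] = {c for c, p in peak_of_chip.items() if p in pe}

    if model_table is not None and tads is not None:
        from .tads import assign_to_tads

        sig = model_table[model_table["significant"]]
        if atac_peaks is not None and len(sig):
            apos = atac_peaks.set_index("name")
            amid = ((apos["start"] + apos["end"]) // 2).to_dict()
            achrom = apos["chrom"].to_dict()
            feats = pd.DataFrame({
                "chrom": [achrom[p] for p in sig["peak_id"]],
                "pos": [amid[p] for p in sig["peak_id"]],
            })
            regions = assign_to_tads(feats, tads).to_numpy()
            counts = pd.Series(regions).value_counts()
            dense = set(counts[counts > counts.mean()].index)
            cfeats = pd.DataFrame({"chrom": chip.peaks["chrom"], "pos": chip_mid})
            cregions = assign_to_tads(cfeats, tads).to_numpy()
            subsets["dense_regions"] = {
                n for n, r in zip(chip.peaks["name"], cregions) if r in dense
            }
    return subsets
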