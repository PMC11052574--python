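"""Synthetic genotype / chromatin-accessibility / expression worlds.

Everything the interaction scan consumes can be generated here with planted
ground truth: a multi-chromosome genome tiled by variable-length TADs
(~1.1 Mb on average, the scale reported for mammalian domains), point markers
carrying dosage genotypes (0/1/2 copies of the non-reference allele), open
chromatin peaks with continuous TMM-like intensities, and gene expression
simulated from the interaction model

    y = b0 + b1*g + b2*a + b3*g*a + eps,   eps ~ Normal(0, sigma)

with per-gene model classes (null / genotype-only / ATAC-only / additive /
interacting) and a ledger recording which trio and coefficients were planted.
A separate generator builds a CTCF-binding world: motif instances embedded in
random sequence, strain SNPs inside a fraction of the motifs, and replicate
ChIP fold-enrichment intensities whose means depend on the strain allele.

Coordinates are 0-based half-open throughout. All randomness flows through a
single integer seed; identical (config, seed) give byte-identical datasets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as tio

MODEL_CLASSES = ("null", "genotype_only", "atac_only", "additive", "interacting")

BASES = np.array(["A", "C", "G", "T"])


class SizingError(ValueError):
    """Configured feature counts cannot fit in the configured genome."""


class PlacementError(ValueError):
    """Forced intra-TAD placement impossible for a gene."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (bp)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


@dataclass
class SimulationConfig:
    """Knobs for :func:`generate_genome`.

    Defaults mirror the study design being emulated: 176 samples, TADs
    averaging ~1.1 Mb, balanced allele frequencies from an outbred population.
    Feature counts are scaled to a small multi-megabase toy genome.
    """

    chromosome_lengths: tuple[int, ...] = (25_000_000, 25_000_000)
    n_samples: int = 176
    n_genes: int = 200
    n_markers: int = 600
    n_peaks: int = 1000
    tad_mean_bp: float = 1_100_000.0
    tad_sd_bp: float = 400_000.0
    tad_min_bp: int = 200_000
    gap_prob: float = 0.25
    gap_mean_bp: float = 60_000.0
    tile_to_end: bool = False  # stretch the last TAD to the chromosome end
    allele_freq_range: tuple[float, float] = (0.2, 0.8)
    gene_len_range: tuple[int, int] = (5_000, 50_000)
    peak_width_mean_bp: float = 500.0
    atac_log_mean: float = 1.0
    atac_log_sd: float = 0.5
    noise_sd: float = 0.5

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthRecord:
    """Planted generative truth for one gene."""

    gene_id: str
    variant_id: str
    peak_id: str
    true_class: str
    true_betas: tuple[float, float, float, float]
    causal_intra_tad: bool

    def __post_init__(self):
        if self.true_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model class {self.true_class!r}")
        b0, b1, b2, b3 = self.true_betas
        nonzero = {"x1": b1 != 0, "x2": b2 != 0, "x1x2": b3 != 0}
        expected = {
            "null": (False, False, False),
            "genotype_only": (True, False, False),
            "atac_only": (False, True, False),
            "additive": (True, True, False),
            "interacting": (True, True, True),
        }[self.true_class]
        if (nonzero["x1"], nonzero["x2"], nonzero["x1x2"]) != expected:
            raise ValueError(
                f"true_betas zero-pattern inconsistent with class {self.true_class}"
            )


@dataclass
class TruthSpec:
    """Class mixture and effect-size ranges for :func:`plant_models`."""

    class_proportions: dict = field(
        default_factory=lambda: {
            "null": 0.20,
            "genotype_only": 0.25,
            "atac_only": 0.10,
            "additive": 0.25,
            "interacting": 0.20,
        }
    )
    beta0_range: tuple[float, float] = (2.0, 8.0)
    beta1_range: tuple[float, float] = (0.3, 1.5)  # magnitudes; sign drawn separately
    beta2_range: tuple[float, float] = (0.2, 1.0)
    beta3_range: tuple[float, float] = (0.3, 1.0)
    negative_sign_prob: float = 0.4
    intra_tad_prob: float = 0.8
    sigma: float = 0.5


@dataclass
class SyntheticDataset:
    """A fully materialised synthetic world plus (optionally) planted truth."""

    layout: GenomeLayout
    tads: pd.DataFrame        # chrom, start, end, name
    genes: pd.DataFrame       # chrom, start, end, name, strand, tss
    markers: pd.DataFrame     # chrom, start, end (start+1), name
    peaks: pd.DataFrame       # chrom, start, end, name
    samples: list[str]
    dosage: np.ndarray        # markers x samples, values {0,1,2}
    atac: np.ndarray          # peaks x samples, >= 0
    expression: np.ndarray | None = None  # genes x samples (log2 TPM scale)
    monomorphic: np.ndarray | None = None
    allele_freq: np.ndarray | None = None  # per-marker f used for binomial(2, f)
    truth: pd.DataFrame | None = None
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for df in (self.tads, self.genes, self.markers, self.peaks):
            h.update(df.to_csv(index=False).encode())
        h.update(np.ascontiguousarray(self.dosage).tobytes())
        h.update(np.ascontiguousarray(self.atac).tobytes())
        if self.expression is not None:
            h.update(np.ascontiguousarray(self.expression).tobytes())
        if self.truth is not None:
            h.update(self.truth.to_csv(index=False).encode())
        return h.hexdigest()

    # -- index helpers -----------------------------------------------------
    def gene_index(self, gene_id: str) -> int:
        return self.genes.index[self.genes["name"] == gene_id][0]

    def marker_index(self, variant_id: str) -> int:
        return self.markers.index[self.markers["name"] == variant_id][0]

    def peak_index(self, peak_id: str) -> int:
        return self.peaks.index[self.peaks["name"] == peak_id][0]

    def write(self, outdir: str) -> None:
        """Write the dataset as BED / TSV / YAML under ``outdir``."""
        tio.ensure_dir(outdir)
        tio.write_bed(self.tads, f"{outdir}/tads.bed")
        tio.write_bed(self.genes, f"{outdir}/genes.bed", extra_cols=["strand", "tss"])
        tio.write_bed(self.markers, f"{outdir}/markers.bed")
        tio.write_bed(self.peaks, f"{outdir}/peaks.bed")
        tio.write_matrix(self.dosage, self.markers["name"], self.samples, f"{outdir}/dosage.tsv")
        tio.write_matrix(self.atac, self.peaks["name"], self.samples, f"{outdir}/atac.tsv")
        if self.expression is not None:
            tio.write_matrix(
                self.expression, self.genes["name"], self.samples, f"{outdir}/expression.tsv"
            )
        if self.truth is not None:
            self.truth.to_csv(f"{outdir}/truth.tsv", sep="\t", index=False)
        cfg = dict(self.config)
        cfg["seed"] = self.seed
        tio.write_config(cfg, f"{outdir}/config.yaml")


def _tile_tads(rng: np.random.Generator, layout: GenomeLayout, cfg: SimulationConfig) -> pd.DataFrame:
    # lognormal parameterised by mean/sd of the length itself
    m, s = cfg.tad_mean_bp, cfg.tad_sd_bp
    mu = np.log(m**2 / np.sqrt(s**2 + m**2))
    sigma = np.sqrt(np.log(1.0 + (s / m) ** 2))
    rows = []
    for chrom, length in layout.chromosomes:
        pos = 0
        first_on_chrom = len(rows)
        while True:
            tad_len = int(max(cfg.tad_min_bp, rng.lognormal(mu, sigma)))
            if pos + tad_len > length:
                break
            rows.append((chrom, pos, pos + tad_len))
            pos += tad_len
            if rng.random() < cfg.gap_prob:
                pos += int(rng.exponential(cfg.gap_mean_bp)) + 1
        if cfg.tile_to_end and len(rows) > first_on_chrom:
            chrom_, s_, _ = rows[-1]
            rows[-1] = (chrom_, s_, length)
    if not rows:
        raise SizingError("no TAD of the configured length fits in the genome")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["name"] = [f"tad{i:04d}" for i in range(len(df))]
    return df


def _place_points(rng, layout, n, prefix) -> pd.DataFrame:
    lengths = np.array([L for _, L in layout.chromosomes], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(lengths), size=n, p=probs)
    pos = (rng.random(n) * lengths[chrom_idx]).astype(int)
    df = pd.DataFrame({
        "chrom": [layout.chromosomes[i][0] for i in chrom_idx],
        "start": pos,
    })
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    df["end"] = df["start"] + 1
    df["name"] = [f"{prefix}{i:05d}" for i in range(n)]
    return df[["chrom", "start", "end", "name"]]


def generate_genome(config: SimulationConfig | None = None, seed: int = 0) -> SyntheticDataset:
    """Build genome layout, TAD tiling, features, genotypes and ATAC matrix.

    Expression is left unset; :func:`plant_models` fills it from a
    :class:`TruthSpec`. Raises :class:`SizingError` when the configured
    feature counts cannot fit into the configured chromosomes.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    layout = GenomeLayout(tuple((f"chr{i+1}", L) for i, L in enumerate(cfg.chromosome_lengths)))

    total = layout.total_length
    min_gene = cfg.gene_len_range[0]
    if (
        cfg.n_markers > total
        or cfg.n_peaks * max(1, int(cfg.peak_width_mean_bp / 4)) > total
        or cfg.n_genes * min_gene > 2 * total
    ):
        raise SizingError(
            f"cannot place {cfg.n_genes} genes / {cfg.n_markers} markers / "
            f"{cfg.n_peaks} peaks in a {total} bp genome"
        )

    tads = _tile_tads(rng, layout, cfg)

    # genes: interval + strand + strand-aware TSS
    genes = _place_points(rng, layout, cfg.n_genes, "gene")
    glen = rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1], size=len(genes))
    chrom_len = dict(layout.chromosomes)
    genes["end"] = [
        min(s + L, chrom_len[c]) for s, L, c in zip(genes["start"], glen, genes["chrom"])
    ]
    genes["strand"] = np.where(rng.random(len(genes)) < 0.5, "+", "-")
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)

    markers = _place_points(rng, layout, cfg.n_markers, "var")

    peaks = _place_points(rng, layout, cfg.n_peaks, "peak")
    widths = np.maximum(50, rng.lognormal(np.log(cfg.peak_width_mean_bp), 0.5, len(peaks))).astype(int)
    peaks["end"] = [
        min(s + w, chrom_len[c]) for s, w, c in zip(peaks["start"], widths, peaks["chrom"])
    ]

    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]

    f = rng.uniform(*cfg.allele_freq_range, size=cfg.n_markers)
    dosage = rng.binomial(2, f[:, None], size=(cfg.n_markers, cfg.n_samples)).astype(float)
    monomorphic = (dosage == dosage[:, :1]).all(axis=1)

    atac = np.maximum(
        rng.lognormal(cfg.atac_log_mean, cfg.atac_log_sd, size=(cfg.n_peaks, cfg.n_samples)), 0.0
    )

    return SyntheticDataset(
        layout=layout,
        tads=tads,
        genes=genes,
        markers=markers,
        peaks=peaks,
        samples=samples,
        dosage=dosage,
        atac=atac,
        monomorphic=monomorphic,
        allele_freq=f,
        config=cfg.to_dict(),
        seed=seed,
    )


def _tad_of(tads: pd.DataFrame, chrom: str, pos: int) -> str | None:
    sub = tads[tads["chrom"] == chrom]
    hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
    return None if hit.empty else hit["name"].iloc[0]


def plant_models(
    dataset: SyntheticDataset,
    truth_spec: TruthSpec | None = None,
    seed: int = 0,
) -> tuple[SyntheticDataset, list[TruthRecord]]:
    """Fill ``dataset.expression`` from planted per-gene generative models.

    Each gene is assigned a model class by the configured mixture, a causal
    marker and peak (intra-TAD with probability ``intra_tad_prob``), and
    coefficients drawn from the configured magnitude ranges with random signs
    (negative with probability ``negative_sign_prob``). Expression is the
    interaction model evaluated at the sampled genotype/intensity values plus
    Normal(0, sigma) noise.
    """
    spec = truth_spec or TruthSpec()
    rng = np.random.default_rng(seed)
    classes = list(spec.class_proportions)
    probs = np.array([spec.class_proportions[c] for c in classes], dtype=float)
    if not np.isclose(probs.sum(), 1.0):
        raise ValueError("class proportions must sum to 1")

    n_genes, n_samples = len(dataset.genes), len(dataset.samples)
    expression = np.empty((n_genes, n_samples))
    records: list[TruthRecord] = []

    peak_mid = ((dataset.peaks["start"] + dataset.peaks["end"]) // 2).to_numpy()

    for gi, gene in dataset.genes.iterrows():
        true_class = classes[rng.choice(len(classes), p=probs)]
        gene_tad = _tad_of(dataset.tads, gene["chrom"], int(gene["tss"]))
        want_intra = bool(rng.random() < spec.intra_tad_prob)

        intra_markers = intra_peaks = np.array([], dtype=int)
        if gene_tad is not None:
            trow = dataset.tads[dataset.tads["name"] == gene_tad].iloc[0]
            mm = dataset.markers
            intra_markers = np.flatnonzero(
                (mm["chrom"] == trow["chrom"])
                & (mm["start"] >= trow["start"])
                & (mm["start"] < trow["end"])
            )
            pp = dataset.peaks
            intra_peaks = np.flatnonzero(
                (pp["chrom"] == trow["chrom"])
                & (peak_mid >= trow["start"])
                & (peak_mid < trow["end"])
            )
        have_intra = len(intra_markers) > 0 and len(intra_peaks) > 0

        if want_intra and not have_intra:
            if spec.intra_tad_prob >= 1.0 and true_class != "null":
                raise PlacementError(
                    f"{gene['name']}: intra-TAD placement forced but no intra-TAD "
                    f"marker/peak available (class {true_class})"
                )
            want_intra = False

        if want_intra:
            mi = int(rng.choice(intra_markers))
            pi = int(rng.choice(intra_peaks))
        else:
            same_chrom_m = np.flatnonzero(dataset.markers["chrom"] == gene["chrom"])
            same_chrom_p = np.flatnonzero(dataset.peaks["chrom"] == gene["chrom"])
            if len(same_chrom_m) == 0 or len(same_chrom_p) == 0:
                raise SizingError(f"no markers/peaks on {gene['chrom']}")
            mi = int(rng.choice(same_chrom_m))
            pi = int(rng.choice(same_chrom_p))

        def draw(magrange):
            sign = -1.0 if rng.random() < spec.negative_sign_prob else 1.0
            return sign * rng.uniform(*magrange)

        b0 = rng.uniform(*spec.beta0_range)
        b1 = draw(spec.beta1_range) if true_class in ("genotype_only", "additive", "interacting") else 0.0
        b2 = draw(spec.beta2_range) if true_class in ("atac_only", "additive", "interacting") else 0.0
        b3 = draw(spec.beta3_range) if true_class == "interacting" else 0.0

        g = dataset.dosage[mi]
        a = dataset.atac[pi]
        eps = rng.normal(0.0, spec.sigma, n_samples) if spec.sigma > 0 else 0.0
        expression[gi] = b0 + b1 * g + b2 * a + b3 * g * a + eps

        records.append(
            TruthRecord(
                gene_id=gene["name"],
                variant_id=dataset.markers["name"].iloc[mi],
                peak_id=dataset.peaks["name"].iloc[pi],
                true_class=true_class,
                true_betas=(b0, b1, b2, b3),
                causal_intra_tad=bool(want_intra),
            )
        )

    dataset.expression = expression
    dataset.truth = pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "variant_id": r.variant_id,
                "peak_id": r.peak_id,
                "true_class": r.true_class,
                "beta0": r.true_betas[0],
                "beta1": r.true_betas[1],
                "beta2": r.true_betas[2],
                "beta3": r.true_betas[3],
                "causal_intra_tad": r.causal_intra_tad,
            }
            for r in records
        ]
    )
    return dataset, records


# ---------------------------------------------------------------------------
# CTCF world
# ---------------------------------------------------------------------------

def plant_ctcf_world(
    dataset: SyntheticDataset,
    motif,
    n_sites: int = 200,
    snp_rate: float = 0.5,
    strains: Sequence[str] = ("B6", "CAST", "PWK", "WSB"),
    reps_per_strain: int = 3,
    seed: int = 0,
    seq_len_per_chrom: int = 100_000,
    effect_rate: float = 1.0,
    allele_multiplier: float = 0.2,
    noise_sd: float = 0.5,
    detection_floor: float = 1.0,
    dropped_samples: Sequence[str] = (),
):
    """Build a strain ChIP world: sequences with embedded motif instances,
    SNPs inside a fraction of motifs, and replicate fold-enrichment values.

    Returns ``(sequences, site_table, ChipPeakMatrix)``. A site is recorded
    genotype-dependent when it carries a SNP whose alternate allele scales the
    binding intensity by ``allele_multiplier`` (``effect_rate`` controls the
    fraction of SNP sites with a real effect; set 0 for a null world).
    """
    from .chip import ChipPeakMatrix

    if not (0.0 <= snp_rate <= 1.0):
        raise ValueError(f"snp_rate must be in [0, 1], got {snp_rate}")
    if len(strains) < 2:
        raise ValueError("need at least 2 strains")
    L = motif.length
    if L < 6:
        raise ValueError("motif length must be >= 6")

    rng = np.random.default_rng(seed)
    consensus = "".join(BASES[i] for i in np.argmax(motif.matrix, axis=1))

    chrom_names = [c for c, _ in dataset.layout.chromosomes]
    seqs = {
        c: rng.integers(0, 4, size=seq_len_per_chrom) for c in chrom_names
    }

    # non-overlapping site placement
    sites = []
    occupied = {c: [] for c in chrom_names}
    attempts = 0
    while len(sites) < n_sites and attempts < n_sites * 50:
        attempts += 1
        c = chrom_names[rng.integers(len(chrom_names))]
        start = int(rng.integers(0, seq_len_per_chrom - L))
        if any(abs(start - s) < L + 10 for s in occupied[c]):
            continue
        occupied[c].append(start)
        sites.append((c, start))
    if len(sites) < n_sites:
        raise SizingError("could not place the requested number of motif sites")
    sites.sort()

    strain_list = list(strains)
    samples = [f"{s}_r{r+1}" for s in strain_list for r in range(reps_per_strain)]
    samples = [s for s in samples if s not in set(dropped_samples)]
    sample_strain = {s: s.rsplit("_r", 1)[0] for s in samples}

    rows = []
    fe = np.empty((len(sites), len(samples)))
    for si, (c, start) in enumerate(sites):
        for k, base in enumerate(consensus):
            seqs[c][start + k] = int(np.flatnonzero(BASES == base)[0])
        has_snp = bool(rng.random() < snp_rate)
        snp_offset, ref, alt = -1, "", ""
        alleles = {s: 0 for s in strain_list}
        effect = False
        if has_snp:
            snp_offset = int(rng.integers(0, L))
            ref = consensus[snp_offset]
            alt = str(rng.choice([b for b in BASES if b != ref]))
            while True:  # require both alleles present among strains
                draws = rng.random(len(strain_list)) < 0.5
                if draws.any() and not draws.all():
                    break
            alleles = {s: int(d) for s, d in zip(strain_list, draws)}
            effect = bool(rng.random() < effect_rate)
        base_intensity = rng.lognormal(2.0, 0.6)
        for j, samp in enumerate(samples):
            mult = allele_multiplier if (effect and alleles[sample_strain[samp]] == 1) else 1.0
            fe[si, j] = max(0.0, base_intensity * mult + rng.normal(0.0, noise_sd))
        rows.append(
            {
                "site_id": f"site{si:04d}",
                "chrom": c,
                "start": start,
                "end": start + L,
                "strand": "+",
                "has_snp": has_snp,
                "snp_offset": snp_offset,
                "snp_pos": start + snp_offset if has_snp else -1,
                "ref": ref,
                "alt": alt,
                "genotype_dependent": effect,
                **{f"allele_{s}": alleles[s] for s in strain_list},
            }
        )
    site_table = pd.DataFrame(rows)

    sequences = {c: "".join(BASES[v] for v in seqs[c]) for c in chrom_names}
    peak_df = site_table[["chrom", "start", "end"]].copy()
    peak_df["start"] = np.maximum(0, peak_df["start"] - 100)
    peak_df["end"] = peak_df["end"] + 100
    peak_df["name"] = site_table["site_id"]

    chip = ChipPeakMatrix(
        peaks=peak_df,
        fold_enrichment=fe,
        samples=samples,
        sample_to_strain=sample_strain,
        detection_floor=detection_floor,
    )
    return sequences, site_table, chip
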