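"""TAD membership, enrichment, loop geometry and search profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import tadscan as ts
from tadscan.tads import TadInterval


TADS = pd.DataFrame({
    "chrom": ["chr1", "chr1"],
    "start": [0, 1200],
    "end": [1000, 2000],
    "name": ["tadA", "tadB"],
})


def test_assign_simple_membership():
    feats = pd.DataFrame({"chrom": ["chr1", "chr1", "chr1"], "pos": [500, 1000, 1500]})
    out = ts.assign_to_tads(feats, TADS, {"chr1": 2000})
    assert out.iloc[0] == "tad:tadA"
    assert out.iloc[1].startswith("inter:")  # half-open: end coordinate is outside
    assert out.iloc[2] == "tad:tadB"


def test_assign_unknown_chromosome_errors():
    feats = pd.DataFrame({"chrom": ["chrX"], "pos": [5]})
    with pytest.raises(ValueError, match="chrX"):
        ts.assign_to_tads(feats, TADS)


def test_assign_matches_linear_scan_oracle(rng):
    """10^4 random features vs 50 TADs agree with brute-force membership."""
    starts = np.sort(rng.choice(np.arange(0, 10_000_000, 1000), 50, replace=False))
    tads = pd.DataFrame({
        "chrom": "chr1",
        "start": starts,
        "end": starts + rng.integers(200, 900, 50),
        "name": [f"t{i}" for i in range(50)],
    })
    pos = rng.integers(0, 10_000_000, 10_000)
    feats = pd.DataFrame({"chrom": "chr1", "pos": pos})
    got = ts.assign_to_tads(feats, tads, {"chr1": 10_000_000})
    for p, g in zip(pos, got):
        hit = tads[(tads["start"] <= p) & (p < tads["end"])]
        if len(hit):
            assert g == f"tad:{hit['name'].iloc[0]}"
        else:
            assert g.startswith("inter:")


def test_loop_distance_cases():
    tad = TadInterval("chr1", 0, 1000)
    assert ts.loop_distance(100, 900, tad) == 200   # wraps the joined boundary
    assert ts.loop_distance(100, 600, tad) == 500   # halfway around: maximum L/2
    with pytest.raises(ValueError):
        ts.loop_distance(100, 1500, tad)


def test_loop_distance_two_arc_oracle(rng):
    tad = TadInterval("chr1", 5000, 95_000)
    L = tad.length
    pos = rng.integers(5000, 95_000, size=(2000, 2))
    for a, b in pos:
        d = ts.loop_distance(int(a), int(b), tad)
        arc1 = abs(int(a) - int(b))
        arc2 = L - arc1
        assert d == min(arc1, arc2)
        assert d <= L // 2 + 1


@given(st.integers(0, 999), st.integers(0, 999), st.integers(0, 999))
def test_loop_distance_is_a_metric(a, b, c):
    tad = TadInterval("chr1", 0, 1000)
    dab = ts.loop_distance(a, b, tad)
    assert dab == ts.loop_distance(b, a, tad)          # symmetry
    assert dab <= ts.loop_distance(a, c, tad) + ts.loop_distance(c, b, tad)
    assert (dab == 0) == (a == b)


def _toy_world():
    """One chromosome, two TADs, genes/peaks placed by hand."""
    tads = pd.DataFrame({
        "chrom": "chr1", "start": [0, 1_000_000], "end": [1_000_000, 2_000_000],
        "name": ["tadA", "tadB"],
    })
    genes = pd.DataFrame({
        "chrom": "chr1", "start": [100_000], "end": [120_000],
        "name": ["geneA"], "strand": ["+"], "tss": [100_000],
    })
    peaks = pd.DataFrame({
        "chrom": "chr1",
        "start": [400_000, 1_500_000],
        "end": [400_200, 1_500_200],
        "name": ["peakIn", "peakOut"],
    })
    markers = pd.DataFrame({
        "chrom": "chr1", "start": [500_000], "end": [500_001], "name": ["var0"],
    })
    return tads, genes, peaks, markers


def _model_row(gene, var, peak, cls="interacting", sig=True, betas=(1, 1, 1, 1)):
    return {
        "gene_id": gene, "variant_id": var, "peak_id": peak, "chrom": "chr1",
        "beta0": betas[0], "beta1": betas[1], "beta2": betas[2], "beta3": betas[3],
        "retained": "x1,x1x2,x2" if cls == "interacting" else "x1,x2",
        "model_class": cls, "rss_full": 1.0, "rss_null": 2.0,
        "f_stat": 10.0, "p_raw": 1e-12, "p_adj": 1e-9, "significant": sig, "n": 176,
    }


def test_enrichment_fisher_oracle():
    """OR and p for the table (30,10,10,30) match hypergeometric enumeration."""
    table = np.array([[30, 10], [10, 30]])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    assert odds == 9.0
    # independent enumeration of the hypergeometric tail
    from scipy.stats import hypergeom

    M, n, N = 80, 40, 40
    probs = np.array([hypergeom.pmf(k, M, n, N) for k in range(41)])
    p_enum = probs[probs <= probs[30] * (1 + 1e-9)].sum()
    np.testing.assert_allclose(p, p_enum, rtol=1e-8)


def test_boundary_window_enrichment_planted():
    tads, genes, peaks, markers = _toy_world()
    rows = [
        _model_row("geneA", "var0", "peakIn"),
        _model_row("geneA", "var0", "peakOut", cls="additive", sig=False),
    ]
    table = pd.DataFrame(rows)
    res = ts.boundary_window_enrichment(
        table, peaks, tads, genes, window_bp=50_000,
        chrom_lengths={"chr1": 2_000_000},
    )
    (a, b), (c, d) = res.contingency
    assert (a, b, c, d) == (1, 0, 0, 1)
    assert res.haldane_corrected  # zero cells present in this tiny table


def test_enrichment_planted_intra_world(mixed_scan, mixed_world):
    """Intra-TAD enrichment on planted-intra worlds is strong."""
    ds, _ = mixed_world
    res = ts.boundary_window_enrichment(
        mixed_scan.table, ds.peaks, ds.tads, ds.genes,
        chrom_lengths=dict(ds.layout.chromosomes),
    )
    assert res.odds_ratio > 1.0
    assert res.p_value < 0.01


def test_standardize_tad_coords_bounds_and_sign():
    tads, genes, peaks, markers = _toy_world()
    table = pd.DataFrame([_model_row("geneA", "var0", "peakIn")])
    coords, excluded = ts.standardize_tad_coords(
        table, tads, genes, peaks, {"chr1": 2_000_000}
    )
    assert excluded == 0
    off = coords["loop_offset"].iloc[0]
    # peak at 400100, TSS at 100000, L=1Mb: downstream, 300100/1e6
    np.testing.assert_allclose(off, 300_100 / 1_000_000)
    assert -0.5 <= off <= 0.5
    # a peak in the other TAD is excluded and counted
    table2 = pd.DataFrame([_model_row("geneA", "var0", "peakOut")])
    coords2, excluded2 = ts.standardize_tad_coords(
        table2, tads, genes, peaks, {"chr1": 2_000_000}
    )
    assert excluded2 == 1 and coords2.empty


def test_standardized_offsets_cover_loop(interacting_world, interacting_scan):
    ds, _ = interacting_world
    sig = interacting_scan.table
    coords, _ = ts.standardize_tad_coords(
        sig[sig["significant"] & (sig["model_class"] == "interacting")],
        ds.tads, ds.genes, ds.peaks, dict(ds.layout.chromosomes),
    )
    assert len(coords) > 100
    assert coords["loop_offset"].between(-0.5, 0.5).all()


def test_capture_window_trivial_and_oracle():
    tads, genes, peaks, markers = _toy_world()
    rows = []
    offs = [-10_000, 10_000] * 15
    for k, off in enumerate(offs):
        peaks = pd.concat([
            peaks,
            pd.DataFrame({"chrom": ["chr1"], "start": [100_000 + off],
                          "end": [100_000 + off], "name": [f"pk{k}"]}),
        ], ignore_index=True)
        peaks.loc[peaks["name"] == f"pk{k}", "end"] += 1
        rows.append(_model_row("geneA", "var0", f"pk{k}"))
    # variant placed at the TSS so the peak is always the extreme element
    markers.loc[0, "start"] = 100_000
    table = pd.DataFrame(rows)
    up, down = ts.capture_window(table, genes, markers, peaks, q=1.0)
    assert (up, down) == (10_000, 10_000)
    up95, down95 = ts.capture_window(table, genes, markers, peaks, q=0.95)
    # order-statistic quantile on {0, 10000} distributions
    ups = sorted(max(0, -o) for o in offs)
    downs = sorted(max(0, o) for o in offs)
    assert up95 == float(np.quantile(ups, 0.95, method="higher"))
    assert down95 == float(np.quantile(downs, 0.95, method="higher"))


def test_capture_window_refuses_small_input():
    tads, genes, peaks, markers = _toy_world()
    table = pd.DataFrame([_model_row("geneA", "var0", "peakIn")])
    with pytest.raises(ValueError, match="unstable"):
        ts.capture_window(table, genes, markers, peaks)


def test_search_profiles_tad_beats_linear(interacting_world, interacting_scan):
    """With interactions planted intra-TAD only, the TAD-limited search has
    an interacting percentage >= the linear search in every populated bin."""
    ds, _ = interacting_world
    prof = ts.search_efficiency_profiles(ds, interacting_scan.table, bin_bp=250_000)
    wide = prof.pivot_table(index="bin_start", columns="mode",
                            values=["pct_interacting", "n_pairs"])
    populated = wide[("n_pairs", "tad")] > 0
    assert populated.sum() > 3
    diff = wide.loc[populated, ("pct_interacting", "tad")] - wide.loc[
        populated, ("pct_interacting", "linear")]
    assert (diff >= -1e-9).all()


def test_search_profiles_no_models_all_zero(null_world, null_scan):
    prof = ts.search_efficiency_profiles(null_world, null_scan.table, bin_bp=500_000)
    assert (prof["pct_interacting"] == 0).all()


def test_search_profiles_validation(null_world, null_scan):
    with pytest.raises(ValueError):
        ts.search_efficiency_profiles(null_world, null_scan.table, bin_bp=0)


def test_gene_boundary_proximity():
    tads, genes, peaks, markers = _toy_world()
    # TSS at 100 kb inside tadA start (boundary at 0), + strand
    frac, flags = ts.gene_boundary_proximity(genes, tads, near_bp=150_000)
    assert flags.iloc[0]
    frac0, _ = ts.gene_boundary_proximity(genes, tads, near_bp=0)
    assert frac0 == 0.0
    frac_small, flags_small = ts.gene_boundary_proximity(genes, tads, near_bp=50_000)
    assert not flags_small.iloc[0]


def test_gene_boundary_proximity_geometric_rate(rng):
    """Uniform gene placement: fraction ~ near_bp / mean region length."""
    L, n_tads = 1_000_000, 40
    tads = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n_tads) * L,
        "end": (np.arange(n_tads) + 1) * L,
        "name": [f"t{i}" for i in range(n_tads)],
    })
    m = 4000
    genes = pd.DataFrame({
        "chrom": "chr1",
        "start": rng.integers(0, n_tads * L, m),
        "end": 0, "name": [f"g{i}" for i in range(m)], "strand": "+",
    })
    genes["end"] = genes["start"] + 1
    genes["tss"] = genes["start"]
    near = 100_000
    frac, _ = ts.gene_boundary_proximity(genes, tads, near_bp=near)
    expect = near / L
    assert abs(frac - expect) < 3 * np.sqrt(expect * (1 - expect) / m) + 0.01
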