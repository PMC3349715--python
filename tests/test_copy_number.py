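"""CIN, probe binning, regional CN and the GACN two-stage procedure."""

import numpy as np
import pandas as pd
import pytest

from ladomics.containers import GenomicRegion, SUBTYPES
from ladomics.copy_number import (
    bin_probes,
    cin,
    cn_expression_coordination,
    compare_cin,
    gacn_discovery,
    gacn_validation,
    region_cn,
)


def _probe_frame(rows, samples):
    """rows: list of (chrom, position, values...)."""
    recs = []
    for i, (chrom, pos, *vals) in enumerate(rows):
        recs.append([chrom, pos] + list(vals))
    df = pd.DataFrame(recs, columns=["chromosome", "position"] + samples)
    df.index = pd.Index([f"p{i}" for i in range(len(rows))], name="probe_id")
    return df


def _arms(*specs):
    return pd.DataFrame(
        list(specs), columns=["arm_id", "chromosome", "start", "end"]
    )


# ---------------------------------------------------------------------------
# binning

def test_bin_probes_constant_signal():
    rows = [("chr1", int(p), 0.7) for p in np.arange(0, 10_000_000, 500_000)]
    probes = _probe_frame(rows, ["s1"])
    out = bin_probes(probes, 2_000_000)
    assert (out["s1"] == 0.7).all()
    assert len(out) == 5


def test_bin_probes_single_probe_identity_and_median():
    probes = _probe_frame(
        [("chr1", 10, 0.1), ("chr1", 20, 0.2), ("chr1", 30, 0.9),
         ("chr2", 10, 0.5)],
        ["s1"],
    )
    out = bin_probes(probes, 1_000_000)
    assert out.loc[out["chromosome"] == "chr1", "s1"].iloc[0] == pytest.approx(0.2)
    assert out.loc[out["chromosome"] == "chr2", "s1"].iloc[0] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# CIN

def test_cin_all_zero_genome():
    rows = [("chr1", int(p), 0.0) for p in range(0, 100, 10)]
    probes = _probe_frame(rows, ["s1"])
    arms = _arms(("1p", "chr1", 0, 200))
    assert cin(probes, arms)["s1"] == 0.0


def test_cin_three_arm_hand_example():
    rows = []
    for arm_i, value in enumerate([0.2, -0.4, 0.1]):
        for j in range(5):
            rows.append((f"chr{arm_i + 1}", j * 10, value))
    probes = _probe_frame(rows, ["s1"])
    arms = _arms(*[(f"{i + 1}p", f"chr{i + 1}", 0, 100) for i in range(3)])
    assert cin(probes, arms)["s1"] == pytest.approx(0.2)


def cin_oracle(probes, arms, min_probes=5):
    """Independent brute-force two-stage median."""
    samples = [c for c in probes.columns if c not in ("chromosome", "position")]
    out = {}
    for s in samples:
        arm_values = []
        for _, arm in arms.iterrows():
            vals = [
                row[s]
                for _, row in probes.iterrows()
                if row["chromosome"] == arm["chromosome"]
                and arm["start"] <= row["position"] < arm["end"]
            ]
            if len(vals) >= min_probes:
                arm_values.append(abs(float(np.median(vals))))
        out[s] = float(np.median(arm_values))
    return pd.Series(out)


def test_cin_matches_bruteforce_oracle(rng):
    for _ in range(10):
        n_arms = rng.integers(2, 5)
        rows = []
        for a in range(n_arms):
            for j in range(rng.integers(5, 12)):
                rows.append(
                    (f"chr{a + 1}", int(j * 7), *rng.normal(size=3))
                )
        probes = _probe_frame(rows, ["s1", "s2", "s3"])
        arms = _arms(*[(f"{a + 1}p", f"chr{a + 1}", 0, 1000) for a in range(n_arms)])
        got = cin(probes, arms)
        expected = cin_oracle(probes, arms)
        assert np.allclose(got[expected.index], expected)


def test_cin_invariant_to_probe_order(rng):
    rows = [("chr1", int(i * 10), *rng.normal(size=2)) for i in range(20)]
    probes = _probe_frame(rows, ["s1", "s2"])
    arms = _arms(("1p", "chr1", 0, 500))
    shuffled = probes.sample(frac=1.0, random_state=1)
    pd.testing.assert_series_equal(cin(probes, arms), cin(shuffled, arms))


def test_cin_requires_enough_probes():
    probes = _probe_frame([("chr1", 5, 0.1)], ["s1"])
    arms = _arms(("1p", "chr1", 0, 100))
    with pytest.raises(ValueError):
        cin(probes, arms)


def test_compare_cin_magnoid_strictly_greater_minimal_p():
    values = pd.Series(
        [0.1, 0.2, 0.9, 1.0, 0.15, 0.25],
        index=["b1", "b2", "m1", "m2", "s1", "s2"],
    )
    labels = pd.Series(
        ["Bronchioid", "Bronchioid", "Magnoid", "Magnoid", "Squamoid", "Squamoid"],
        index=values.index,
    )
    res = compare_cin(values, labels, "validation")
    # minimal attainable exact one-sided p for groups of 2 vs 4: 1/C(6,2)
    assert res.p_value == pytest.approx(1 / 15)


# ---------------------------------------------------------------------------
# region CN

def test_region_cn_median_and_half_open_bound():
    probes = _probe_frame(
        [("chr1", 100, 0.3), ("chr1", 150, 0.5), ("chr1", 200, 9.9)],
        ["s1"],
    )
    regions = [GenomicRegion("chr1", 100, 200, "r1")]
    out = region_cn(probes, regions)
    # probe at the end coordinate (200) excluded by the half-open convention
    assert out.loc["r1", "s1"] == pytest.approx(0.4)


def test_region_cn_matches_interval_scan_oracle(rng):
    rows = [("chr1", int(rng.integers(0, 1000)), *rng.normal(size=2)) for _ in range(60)]
    probes = _probe_frame(rows, ["s1", "s2"])
    regions = [
        GenomicRegion("chr1", int(a), int(a) + 200, f"r{a}")
        for a in (0, 300, 700)
    ]
    out = region_cn(probes, regions)
    for region in regions:
        vals = {
            s: [
                row[s]
                for _, row in probes.iterrows()
                if region.contains(row["chromosome"], row["position"])
            ]
            for s in ("s1", "s2")
        }
        for s in ("s1", "s2"):
            if vals[s]:
                assert out.loc[region.name, s] == pytest.approx(np.median(vals[s]))


def test_region_without_probes_excluded():
    probes = _probe_frame([("chr1", 100, 0.3)], ["s1"])
    regions = [GenomicRegion("chr2", 0, 100, "empty")]
    out = region_cn(probes, regions)
    assert len(out) == 0


# ---------------------------------------------------------------------------
# GACN

def _region_values(values_by_sample):
    return pd.DataFrame({"r1": values_by_sample}).T


def test_gacn_forced_amplification_example():
    samples = ["b1", "b2", "m1", "m2", "s1", "s2"]
    labels = pd.Series(
        ["Bronchioid", "Bronchioid", "Magnoid", "Magnoid", "Squamoid", "Squamoid"],
        index=samples,
    )
    vals = pd.DataFrame(
        [[0.0, 0.1, 0.9, 1.1, 0.1, 0.2]], index=["r1"], columns=samples
    )
    out = gacn_discovery(vals, labels, alpha=1.0)
    assert out.loc["r1", "gacn_subtype"] == "Magnoid"


def test_gacn_deletion_farthest_from_zero():
    samples = ["b1", "b2", "m1", "m2", "s1", "s2"]
    labels = pd.Series(
        ["Bronchioid", "Bronchioid", "Magnoid", "Magnoid", "Squamoid", "Squamoid"],
        index=samples,
    )
    vals = pd.DataFrame(
        [[0.0, 0.05, -0.9, -1.1, 0.0, -0.05]], index=["r1"], columns=samples
    )
    out = gacn_discovery(vals, labels, alpha=1.0)
    assert out.loc["r1", "gacn_subtype"] == "Magnoid"


def test_gacn_validation_separated_minimal_p_and_zero_case():
    samples = ["b1", "b2", "m1", "m2", "s1", "s2"]
    labels = pd.Series(
        ["Bronchioid", "Bronchioid", "Magnoid", "Magnoid", "Squamoid", "Squamoid"],
        index=samples,
    )
    disc = pd.DataFrame(
        {"gacn_subtype": ["Magnoid"], "gacn_flag": [""]},
        index=pd.Index(["r1"], name="region"),
    )
    strong = pd.DataFrame(
        [[0.1, 0.05, 2.0, 1.9, -0.11, 0.12]], index=["r1"], columns=samples
    )
    out = gacn_validation(strong, labels, disc)
    assert out.loc["r1", "validation_p"] == pytest.approx(1 / 15)
    assert bool(out.loc["r1", "confirmed_direction"])
    flat = pd.DataFrame([[0.0] * 6], index=["r1"], columns=samples)
    out = gacn_validation(flat, labels, disc)
    assert out.loc["r1", "validation_p"] >= 0.5
    assert not bool(out.loc["r1", "confirmed_direction"])


def test_gacn_recovery_on_synthetic_cohort(small_cohort):
    cohort, truth = small_cohort
    labels = truth.subtype
    values = region_cn(cohort.cn, cohort.regions)[labels.index]
    disc = gacn_discovery(values, labels)
    assigned = disc[disc["gacn_subtype"].notna()]
    correct = sum(
        assigned.loc[r, "gacn_subtype"] == truth.region_gacn[r]
        for r in assigned.index
    )
    assert len(assigned) >= 20
    assert correct / len(assigned) >= 0.95


def test_coordination_perfect_coupling_rho_one():
    samples = [f"x{i}" for i in range(12)]
    labels = pd.Series(
        [SUBTYPES[i % 3] for i in range(12)], index=samples
    )
    rng = np.random.default_rng(8)
    regions = [
        GenomicRegion("chr1", i * 1000, i * 1000 + 500, f"r{i}") for i in range(6)
    ]
    vals = pd.DataFrame(
        rng.normal(size=(6, 12)), index=[r.name for r in regions], columns=samples
    )
    disc = pd.DataFrame(
        {"gacn_subtype": ["Magnoid"] * 6, "gacn_flag": [""] * 6},
        index=pd.Index([r.name for r in regions], name="region"),
    )
    gene_positions = pd.DataFrame(
        {
            "chromosome": ["chr1"] * 6,
            "position": [i * 1000 + 100 for i in range(6)],
        },
        index=pd.Index([f"g{i}" for i in range(6)], name="gene"),
    )
    expression = vals.copy()
    expression.index = gene_positions.index  # expression == region CN per gene
    table, res = cn_expression_coordination(
        vals, disc, expression, labels, gene_positions, regions
    )
    assert res.statistic == pytest.approx(1.0)
    assert (table["cn_diff"] == table["expr_diff"]).all()
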