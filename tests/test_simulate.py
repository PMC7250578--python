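"""Stochastic lineage and karyotype simulators."""

import numpy as np
import pytest

from centroevo import (
    KaryotypeSimConfig,
    PopulationParams,
    SimConfig,
    build_matrix,
    cell_event_prob,
    fractions,
    initial_state,
    integrate,
    make_synthetic_time_course,
    partition_karyotype,
    sample_observations,
    simulate_karyotype_evolution,
    simulate_lineages,
)
from centroevo.simulate import KaryotypeSimConfig as KCfg, daughter_viable


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(seed=0, n0=0)
    with pytest.raises(ValueError):
        SimConfig(seed=0, n0=100, cap=50)
    with pytest.raises(ValueError):
        SimConfig(seed=0, duration=4.0, sampling_days=(0, 8))
    with pytest.raises(ValueError):
        KaryotypeSimConfig(tripolar_prob=1.5)


def test_frozen_population_stays_constant():
    p = PopulationParams(b_C2=0, b_C4=0, q=1, p_bipolar=1, r=1, fs=1,
                         d_C2=0, d_C4=0, d_C6=0)
    cfg = SimConfig(seed=3, n0=100, alpha=0.3, duration=4.0, cap=1000,
                    sampling_days=(0, 2, 4))
    res = simulate_lineages(p, "II", cfg)
    totals = res.counts[["C2", "C4", "SC", "C6"]].sum(axis=1)
    assert (totals == 100).all()


def test_identical_seeds_identical_outputs(dld1):
    cfg = SimConfig(seed=9, n0=200, alpha=0.1, duration=2.0, cap=1000,
                    sampling_days=(0, 1, 2))
    a = simulate_lineages(dld1, "II", cfg, record_events=True)
    b = simulate_lineages(dld1, "II", cfg, record_events=True)
    assert a.counts.equals(b.counts)
    assert a.events == b.events


def test_event_log_daughter_types_follow_fate_table(dld1):
    cfg = SimConfig(seed=13, n0=300, alpha=0.1, duration=2.0, cap=2000,
                    sampling_days=(0, 2))
    res = simulate_lineages(dld1, "II", cfg, record_events=True)
    assert res.events, "expected events at these rates"
    allowed = {
        ("C2", "bipolar-symmetric"): ("C2", "C2"),
        ("C4", "bipolar-symmetric"): ("C4", "C4"),
        ("SC", "bipolar-symmetric"): ("SC", "SC"),
        ("C4", "bipolar-asymmetric"): ("C2", "C6"),
        ("SC", "bipolar-asymmetric"): ("C2", "C6"),
        ("C4", "multipolar-survive"): ("C4",),
        ("C4", "multipolar-fatal"): (),
    }
    for ev in res.events:
        if ev.kind == "death":
            assert ev.daughters == ()
        elif ev.kind == "cytokinesis-failure":
            assert ev.cell_type == "C2"
            assert len(ev.daughters) == 1
            assert ev.daughters[0][1] in ("C4", "SC")
        else:
            types = tuple(t for _, t in ev.daughters)
            assert types == allowed[(ev.cell_type, ev.kind)]


def test_mean_field_agreement_small(dld1):
    """Ensemble-mean fractions track the ODE (modest size; the full-scale
    check runs in the acceptance suite)."""
    matrix = build_matrix(dld1, "II")
    fr = fractions(integrate(matrix, initial_state(0.10, 1.0, dld1, "II"), [2.0]))
    target = fr.fractions[0]
    reps = 30
    obs = []
    for r in range(reps):
        cfg = SimConfig(seed=500 + r, n0=2000, alpha=0.10, duration=2.0,
                        cap=20_000, sampling_days=(2.0,))
        res = simulate_lineages(dld1, "II", cfg)
        row = res.counts.iloc[0][["C2", "C4", "SC", "C6"]].to_numpy(float)
        obs.append(row / row.sum())
    obs = np.array(obs)
    se = obs.std(axis=0, ddof=1) / np.sqrt(reps)
    assert np.all(np.abs(obs.mean(axis=0) - target) < 4 * np.maximum(se, 1e-4))


def test_passaging_does_not_bias_fractions(dld1):
    """Mean day-3 fractions agree with vs without the population cap."""
    def mean_fracs(cap, seed0):
        rows = []
        for r in range(25):
            cfg = SimConfig(seed=seed0 + r, n0=1000, alpha=0.10, duration=3.0,
                            cap=cap, sampling_days=(3.0,))
            res = simulate_lineages(dld1, "II", cfg)
            row = res.counts.iloc[0][["C2", "C4", "SC", "C6"]].to_numpy(float)
            rows.append(row / row.sum())
        return np.array(rows)

    capped = mean_fracs(2000, 7000)
    free = mean_fracs(10_000_000, 8000)
    se = np.sqrt(capped.var(0, ddof=1) / 25 + free.var(0, ddof=1) / 25)
    assert np.all(np.abs(capped.mean(0) - free.mean(0)) < 4 * np.maximum(se, 1e-3))


def test_sample_observations():
    import pandas as pd

    counts = pd.DataFrame({
        "time_days": [0.0, 2.0], "C2": [100, 100], "C4": [0, 100],
        "SC": [0, 0], "C6": [0, 0],
    })
    ds = sample_observations(counts, (0.0, 2.0), 50, seed=1)
    assert ds.extra_fractions[0] == 0.0  # true fraction 0 → observed 0 always
    ds2 = sample_observations(counts, (0.0, 2.0), 50, seed=1)
    assert np.array_equal(ds.extra_fractions, ds2.extra_fractions)
    big = sample_observations(counts, (2.0,), 1_000_000, seed=2)
    assert abs(big.extra_fractions[0] - 0.5) < 0.005
    with pytest.raises(ValueError):
        sample_observations(counts, (5.0,), 50, seed=1)


def test_end_to_end_recovery(dld1):
    """Lineage-simulated, binomially scored data refit by least squares
    recovers the generating (v, r_S) to within sampling accuracy."""
    from centroevo import fit

    cfg = SimConfig(seed=42, n0=5000, alpha=0.10, duration=12.0, cap=20_000,
                    sampling_days=(0, 2, 4, 6, 8, 10, 12), n_sample=300)
    ds = make_synthetic_time_course(dld1, "II", cfg)
    res = fit(ds, ["v", "r_S"], dld1.replace(v=0.4, r_S=0.7), alpha=0.10)
    assert abs(res.fitted["v"] - 0.22) < 0.1
    assert abs(res.fitted["r_S"] - 0.93) < 0.05


def test_viability_rule():
    k = KCfg(nullisomy_lethal=True, monosomy_survival=0.0)
    assert not daughter_viable(np.array([0, 4, 4]), k, 0.5)
    assert not daughter_viable(np.array([1, 4, 4]), k, 0.5)
    assert daughter_viable(np.array([2, 4, 4]), k, 0.99)
    lenient = KCfg(nullisomy_lethal=False, monosomy_survival=1.0)
    assert daughter_viable(np.array([0, 1, 4]), lenient, 0.99)


def test_tripolar_cull_fraction_matches_closed_form():
    """Fraction of tripolar daughters removed by the nullisomy-lethal rule
    ≈ 1 − (80/81)^23 at M = 23, k = 4."""
    from centroevo import PartitionSpec, simulate_partition

    n = 20_000
    out = simulate_partition(PartitionSpec(23, 4, 3), n, seed=17)
    has_null = (out == 0).any(axis=2)  # (n, poles)
    frac = has_null.mean()
    expected = cell_event_prob(1 / 81, 23)
    se = np.sqrt(expected * (1 - expected) / (n * 3))
    assert abs(frac - expected) < 4 * se


def test_karyotype_bipolar_only_preserves_tetraploid_count(dld1):
    """With multipolar divisions off and cytokinesis failure off, every cell
    keeps exactly 4M chromosomes."""
    p = dld1.replace(p_bipolar=1.0, q=1.0)
    cfg = SimConfig(seed=5, n0=100, alpha=0.0, duration=4.0, cap=2000,
                    sampling_days=(0, 2, 4))
    hists = simulate_karyotype_evolution(p, KCfg(), cfg)
    for hist in hists.values():
        nz = np.nonzero(hist)[0]
        assert list(nz) == [92]


def test_karyotype_sim_generates_and_clears_aneuploidy(dld1):
    """Multipolar divisions create intermediate chromosome counts; nullisomy
    lethality keeps every survivor at ≥ 1 copy per chromosome (counts ≥ M)."""
    cfg = SimConfig(seed=6, n0=300, alpha=0.10, duration=6.0, cap=3000,
                    sampling_days=(0, 2, 4, 6))
    hists = simulate_karyotype_evolution(dld1, KCfg(), cfg)
    day0 = hists[0]
    assert set(np.nonzero(day0)[0]) <= {46, 92}
    later = np.nonzero(hists[4.0])[0] if hists[4.0].sum() else []
    assert all(c >= 23 for c in later)
    mid_counts = [c for c in np.nonzero(hists[2.0])[0] if c not in (46, 92)]
    assert mid_counts, "expected aneuploid intermediates by day 2"
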