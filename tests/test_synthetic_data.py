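"""Simulator contracts: determinism, identifiability, rate recovery, Wilson CIs."""

from __future__ import annotations

import math

import numpy as np
import pytest

from msapkit import (
    AFLPSimulationParams,
    SimulationParams,
    build_paper_fixture,
    consensus_call,
    digest_profiles,
    estimate_change_rates,
    simulate_aflp,
    simulate_msap,
    summarize_aflp,
    summarize_pattern_changes,
    write_band_matrix,
)


def pipeline_pattern_summary(reference, derived, ref_group="RCC", derived_group="4nRR", threshold=0.5):
    ref = digest_profiles(consensus_call(reference, ref_group, threshold))
    der = digest_profiles(consensus_call(derived, derived_group, threshold))
    return summarize_pattern_changes(der, ref, derived_group=derived_group, reference_group=ref_group)


def test_fixed_seed_simulation_is_byte_identical(tmp_path):
    params = SimulationParams(n_loci=200, seed=42)
    r1 = simulate_msap(params)
    r2 = simulate_msap(SimulationParams(n_loci=200, seed=42))
    assert r1.reference == r2.reference and r1.derived == r2.derived
    assert r1.truth.table.equals(r2.truth.table)
    for name, matrix in (("a.tsv", r1.reference), ("b.tsv", r2.reference)):
        write_band_matrix(matrix, tmp_path / name)
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
    # a different seed changes the draw
    assert simulate_msap(SimulationParams(n_loci=200, seed=43)).reference != r1.reference


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError, match="sums to"):
        SimulationParams(ref_state_probs=(0.5, 0.5, 0.2, 0.0)).validate()
    with pytest.raises(ValueError, match="rows must sum"):
        SimulationParams(transition=np.full((4, 4), 0.3)).validate()
    with pytest.raises(ValueError, match="exceeds 1"):
        SimulationParams(p_demethylation=0.8, p_hypermethylation=0.5).validate()
    with pytest.raises(ValueError, match="dropout_rate"):
        AFLPSimulationParams(dropout_rate=1.5).validate()


@pytest.mark.parametrize("seed", [0, 7])
def test_zero_noise_identity_transition_gives_all_unchanged(seed):
    params = SimulationParams(
        n_loci=300,
        ref_state_probs=(0.4, 0.15, 0.45, 0.0),
        transition=np.eye(4),
        dropout_rate=0.0,
        spurious_rate=0.0,
        seed=seed,
    )
    reference, derived, truth = simulate_msap(params)
    summary = pipeline_pattern_summary(reference, derived)
    assert summary.a_count == 300 and summary.a_pct == 100.0
    assert truth.class_counts() == {"A": 300}


@pytest.mark.parametrize("seed", [1, 2])
def test_zero_noise_pipeline_counts_equal_truth_counts(seed):
    """End-to-end identifiability: unanimously scored lanes reproduce the truth."""
    params = SimulationParams(
        n_loci=500, dropout_rate=0.0, spurious_rate=0.0, seed=seed
    )
    reference, derived, truth = simulate_msap(params)
    summary = pipeline_pattern_summary(reference, derived)
    got = {
        "A": summary.a_count,
        "B": summary.b_count,
        "C": summary.c_count,
        "unclassified": summary.unclassified_count,
        "excluded": summary.excluded_count,
    }
    want = truth.class_counts()
    assert {k: v for k, v in got.items() if v} == want


def test_msap_demethylation_rate_recovery_zero_noise():
    """Injected NON-ward rate 0.3 on methylated references is recovered within 3 SE."""
    p = 0.3
    n = 10_000
    params = SimulationParams(
        n_loci=n,
        ref_state_probs=(0.6, 0.4, 0.0, 0.0),  # every reference locus methylated
        p_demethylation=p,
        p_hypermethylation=0.0,
        dropout_rate=0.0,
        spurious_rate=0.0,
        seed=123,
    )
    reference, derived, _ = simulate_msap(params)
    summary = pipeline_pattern_summary(reference, derived)
    b_frac = summary.b_count / summary.classified_total
    se = math.sqrt(p * (1 - p) / n)
    assert abs(b_frac - p) <= 3 * se


def test_msap_rate_recovery_under_lane_noise():
    """5% dropout/spurious with 10 individuals and majority consensus barely
    perturbs the recovered class fractions (within 5% relative of the truth)."""
    params = SimulationParams(
        n_loci=10_000,
        ref_state_probs=(0.4, 0.15, 0.45, 0.0),
        p_demethylation=0.3,
        p_hypermethylation=0.2,
        dropout_rate=0.05,
        spurious_rate=0.05,
        seed=321,
    )
    reference, derived, truth = simulate_msap(params)
    summary = pipeline_pattern_summary(reference, derived)
    true_counts = truth.class_counts()
    true_classified = true_counts["A"] + true_counts["B"] + true_counts["C"]
    for cls, got in (("A", summary.a_count), ("B", summary.b_count), ("C", summary.c_count)):
        true_frac = true_counts[cls] / true_classified
        got_frac = got / summary.classified_total
        assert got_frac == pytest.approx(true_frac, rel=0.05)


def test_majority_consensus_recovers_true_bands_under_noise():
    """P(wrong majority call of 10 lanes at 5% error) is far below 1%."""
    params = SimulationParams(
        n_loci=10_000,
        ref_state_probs=(0.4, 0.15, 0.45, 0.0),
        transition=np.eye(4),
        dropout_rate=0.05,
        spurious_rate=0.05,
        seed=99,
    )
    reference, _, truth = simulate_msap(params)
    profiles = digest_profiles(consensus_call(reference, "RCC"))
    bands = {"hemi": (1, 0), "full": (0, 1), "non": (1, 1), "absent": (0, 0)}
    true_pairs = np.array([bands[s] for s in truth.table["reference_state"]])
    got_pairs = profiles.loc[truth.table["locus"], ["hpaii", "mspi"]].to_numpy()
    per_lane_correct = (got_pairs == true_pairs).mean()
    assert per_lane_correct >= 0.99


def test_aflp_zero_rates_give_all_shared():
    params = AFLPSimulationParams(
        n_loci=200, p_loss=0.0, p_gain=0.0, dropout_rate=0.0, spurious_rate=0.0, seed=5
    )
    reference, derived, truth = simulate_aflp(params)
    summary = summarize_aflp(consensus_call(reference, "RCC"), consensus_call(derived, "4nRR"))
    assert summary.c_count == 200 and summary.c_pct == 100.0
    assert truth.class_counts() == {"C": 200}


def test_aflp_loss_rate_recovery_zero_noise():
    p_loss = 0.326
    n = 10_000
    params = AFLPSimulationParams(
        n_loci=n, p_loss=p_loss, p_gain=0.0, dropout_rate=0.0, spurious_rate=0.0, seed=77
    )
    reference, derived, _ = simulate_aflp(params)
    summary = summarize_aflp(consensus_call(reference, "RCC"), consensus_call(derived, "4nRR"))
    b_frac = summary.b_count / summary.total_scored
    se = math.sqrt(p_loss * (1 - p_loss) / n)
    assert abs(b_frac - p_loss) <= 3 * se


def test_fixture_builders_are_unanimous_at_every_threshold():
    """Strict (1.0) and majority (0.5) consensus agree on the exact fixtures."""
    t1 = build_paper_fixture("TABLE1")
    for threshold in (0.5, 1.0):
        s = summarize_aflp(
            consensus_call(t1, "RCC", threshold), consensus_call(t1, "4nRR", threshold)
        )
        assert (s.a_count, s.b_count, s.c_count) == (181, 180, 191)
    t3 = build_paper_fixture("TABLE3")
    for threshold in (0.5, 1.0):
        ref = digest_profiles(consensus_call(t3, "RCC", threshold))
        der = digest_profiles(consensus_call(t3, "4nRR", threshold))
        s = summarize_pattern_changes(der, ref)
        assert (s.a_count, s.b_count, s.c_count) == (154, 94, 140)


def _wilson_oracle(count, total, z=1.959963984540054):
    """Closed-form Wilson score interval, written out independently."""
    p = count / total
    denom = 1 + z**2 / total
    center = (p + z**2 / (2 * total)) / denom
    half = z * math.sqrt(p * (1 - p) / total + z**2 / (4 * total**2)) / denom
    return center - half, center + half


def test_rate_estimates_match_wilson_oracle():
    matrix = build_paper_fixture("TABLE3")
    ref = digest_profiles(consensus_call(matrix, "RCC"))
    der = digest_profiles(consensus_call(matrix, "4nRR"))
    summary = summarize_pattern_changes(der, ref)
    rates = estimate_change_rates(summary)
    altered = rates["altered"]
    assert altered.count == 234 and altered.total == 388
    assert altered.estimate == pytest.approx(234 / 388)
    lo, hi = _wilson_oracle(234, 388)
    assert altered.ci_low == pytest.approx(lo, abs=1e-9)
    assert altered.ci_high == pytest.approx(hi, abs=1e-9)
    assert altered.ci_low < altered.estimate < altered.ci_high


def test_all_one_class_gives_degenerate_boundary_intervals():
    frame_pairs = {f"L{i}": (1, 1) for i in range(30)}
    from conftest import make_digest_frame

    summary = summarize_pattern_changes(
        make_digest_frame(frame_pairs), make_digest_frame(frame_pairs)
    )
    rates = estimate_change_rates(summary)
    assert rates["A"].estimate == 1.0 and rates["A"].ci_high == 1.0
    assert rates["B"].estimate == 0.0 and rates["B"].ci_low == 0.0
    assert rates["altered"].estimate == 0.0 and rates["altered"].ci_low == 0.0


def test_wilson_interval_coverage_over_replicates():
    """95% intervals for the altered rate cover the true rate >= 90% of the time."""
    p_d, p_h = 0.3, 0.2
    # true per-locus altered probability under the shorthand change model
    probs = (0.4, 0.15, 0.45, 0.0)
    q = (probs[0] + probs[1]) * (p_d + p_h) + probs[2] * p_h
    covered = 0
    n_reps = 200
    for rep in range(n_reps):
        params = SimulationParams(
            n_loci=500,
            n_individuals_ref=2,
            n_individuals_derived=2,
            ref_state_probs=probs,
            p_demethylation=p_d,
            p_hypermethylation=p_h,
            dropout_rate=0.0,
            spurious_rate=0.0,
            seed=10_000 + rep,
        )
        reference, derived, _ = simulate_msap(params)
        summary = pipeline_pattern_summary(reference, derived)
        est = estimate_change_rates(summary)["altered"]
        if est.ci_low <= q <= est.ci_high:
            covered += 1
    assert covered / n_reps >= 0.90
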