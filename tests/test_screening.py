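import numpy as np
import pytest

from multiscreen.chem_io import TargetConfig
from multiscreen.consensus import ProbabilityRecord
from multiscreen.screening import (
    MultitargetResult,
    call_target,
    multitarget_count,
    select_multitarget,
)

COMBINED = TargetConfig("COMB")
QSAR_ONLY = TargetConfig("QO", has_docking=False)
DOCK_ONLY = TargetConfig("DO", has_qsar=False)


def combined_record(prob_comb, in_dom=True, prob_dc=None, cid="c"):
    # when only the decision probability is known, carry it as prob_dc too
    return ProbabilityRecord(
        compound_id=cid, target_id="COMB", prob_comb=prob_comb,
        prob_dc=prob_comb if prob_dc is None else prob_dc, in_domain=in_dom)


class TestCallTarget:
    def test_docking_only_active_above_ligand_probability(self):
        rec = ProbabilityRecord("c", "DO", prob_dc=0.47)
        call = call_target(rec, DOCK_ONLY, ligand_prob=0.26)
        assert call.active and call.in_domain is None

    def test_docking_only_comparison_is_strict(self):
        rec = ProbabilityRecord("c", "DO", prob_dc=0.26)
        assert not call_target(rec, DOCK_ONLY, ligand_prob=0.26).active

    def test_qsar_only_boundary_half_is_active(self):
        rec = ProbabilityRecord("c", "QO", p_activity=0.50, in_domain=True)
        assert call_target(rec, QSAR_ONLY).active

    def test_out_of_domain_blocks_high_probability(self):
        rec = combined_record(0.70, in_dom=False)
        assert not call_target(rec, COMBINED, ligand_prob=0.0).active

    def test_combined_requires_docking_gate(self):
        rec = combined_record(0.70, prob_dc=0.30)
        assert not call_target(rec, COMBINED, ligand_prob=0.40).active
        assert call_target(rec, COMBINED, ligand_prob=0.20).active

    def test_missing_ligand_prob_for_docking_target_errors(self):
        rec = combined_record(0.7)
        with pytest.raises(ValueError, match="ligand_prob"):
            call_target(rec, COMBINED)


def _multitarget_row(probs, bold, ligand_prob_nqo1=0.26, cid="row"):
    """Build the eight per-enzyme calls of a study-style summary row.

    ``probs`` follows the table column order: five consensus targets, two
    classifier-only targets, then the docking-only target; ``bold`` marks
    the in-domain (counted) cells.
    """
    combined_ids = ["JNK-3", "PTP1B", "PDE5", "COX-2", "iNOS"]
    calls = []
    for i, tid in enumerate(combined_ids):
        rec = ProbabilityRecord(cid, tid, prob_comb=probs[i], prob_dc=probs[i],
                                in_domain=bold[i])
        calls.append(call_target(rec, TargetConfig(tid), ligand_prob=0.0))
    for i, tid in zip((5, 6), ("NFR2", "NOX1")):
        rec = ProbabilityRecord(cid, tid, p_activity=probs[i], in_domain=bold[i])
        calls.append(call_target(rec, TargetConfig(tid, has_docking=False)))
    rec = ProbabilityRecord(cid, "NQO1", prob_dc=probs[7])
    calls.append(call_target(rec, TargetConfig("NQO1", has_qsar=False),
                             ligand_prob=ligand_prob_nqo1))
    return calls


class TestMultitargetCount:
    def test_summary_row_with_five_hits(self):
        probs = (0.39, 0.68, 0.52, 0.41, 0.62, 0.54, 0.17, 0.47)
        bold = (False, True, True, False, True, True, False, True)
        assert multitarget_count(_multitarget_row(probs, bold)) == 5

    def test_out_of_domain_cells_reduce_the_count(self):
        # high-probability cells excluded when outside the domain
        probs = (0.45, 0.66, 0.56, 0.53, 0.70, 0.59, 0.25, 0.49)
        bold = (False, True, True, False, False, True, False, True)
        assert multitarget_count(_multitarget_row(probs, bold)) == 4

    def test_all_zero_probabilities_count_zero(self):
        probs = (0.0,) * 8
        bold = (True,) * 8
        assert multitarget_count(_multitarget_row(probs, bold)) == 0

    def test_duplicate_target_errors(self):
        calls = _multitarget_row((0.6,) * 8, (True,) * 8)
        with pytest.raises(ValueError, match="duplicate"):
            multitarget_count(calls + [calls[0]])


def _result(cid, n_active, n_targets=6):
    probs = [0.9] * n_active + [0.1] * (n_targets - n_active)
    calls = [
        call_target(
            ProbabilityRecord(cid, f"T{i}", prob_comb=p, prob_dc=p,
                              in_domain=True),
            TargetConfig(f"T{i}"), ligand_prob=0.0)
        for i, p in enumerate(probs)
    ]
    return MultitargetResult(compound_id=cid, calls=calls)


class TestSelectMultitarget:
    def test_threshold_filters_and_sorts(self):
        results = [_result("a", 0), _result("b", 1), _result("c", 2),
                   _result("d", 5)]
        kept = select_multitarget(results, min_targets=2)
        assert [r.compound_id for r in kept] == ["d", "c"]

    def test_min_one_keeps_any_active(self):
        results = [_result("a", 3), _result("b", 3)]
        kept = select_multitarget(results, min_targets=1)
        assert [r.compound_id for r in kept] == ["a", "b"]  # id tie-break

    def test_survivors_non_increasing_in_min_targets(self):
        rng = np.random.default_rng(0)
        results = [_result(f"c{i}", int(rng.integers(0, 7))) for i in range(40)]
        sizes = [len(select_multitarget(results, m)) for m in range(1, 7)]
        assert sizes == sorted(sizes, reverse=True)

    def test_monotone_in_probability_threshold(self):
        """Raising the activity threshold never increases any count."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random()
            rec = ProbabilityRecord("c", "T", prob_comb=p, prob_dc=p,
                                    in_domain=True)
            lo = call_target(rec, TargetConfig("T"), ligand_prob=0.0,
                             threshold=0.3).active
            hi = call_target(rec, TargetConfig("T"), ligand_prob=0.0,
                             threshold=0.7).active
            assert lo or not hi
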