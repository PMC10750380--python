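"""Assignment rule, stretch removal, resolution lifting and the merge."""

import itertools

import numpy as np
import pytest

import diplochrom as dc
from diplochrom.protocol import (
    ASSIGNED,
    DISCARDED,
    REMOVED,
    UNAMBIGUOUS,
    UNASSIGNED,
    assign_contacts,
    decide_assignment,
    merge_runs,
    remove_stretched,
)


# ---------------------------------------------------------------------------
# the two-threshold rule
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "distances,expected",
    [
        ((2.0, 6.0, 7.0, 8.0), 0),      # one close, rest far -> assign
        ((2.0, 4.0, 7.0, 8.0), None),   # second option not beyond 5.0
        ((2.0, 2.5, 9.0, 9.0), None),   # two close options
        ((6.0, 7.0), None),             # nothing close
        ((2.9,), 0),                    # single-option contact below 3.0
        ((3.0,), None),                 # boundary: not strictly below
        ((2.0, 5.0), None),             # boundary: must strictly exceed 5.0
        ((2.0, 5.0 + 1e-9), 0),
    ],
)
def test_decide_assignment_rule_table(distances, expected):
    assert decide_assignment(distances) == expected


def brute_force_rule(distances, lo=3.0, hi=5.0):
    """Independent oracle: enumerate every option explicitly."""
    winners = []
    for k, d in enumerate(distances):
        if np.isfinite(d) and d < lo and all(
            (not np.isfinite(o)) or o > hi
            for j, o in enumerate(distances) if j != k
        ):
            winners.append(k)
    return winners[0] if len(winners) == 1 else None


def test_decide_assignment_matches_brute_force_on_random_tuples(rng):
    """Exhaustive agreement incl. ties and boundary values (criterion-5 core)."""
    values = [0.5, 2.0, 2.999, 3.0, 3.001, 4.0, 5.0, 5.001, 9.0, np.nan]
    for tup in itertools.product(values, repeat=2):
        assert decide_assignment(tup) == brute_force_rule(tup)
    for _ in range(2000):
        n = rng.integers(1, 5)
        d = rng.uniform(0, 8, n)
        d[rng.random(n) < 0.1] = np.nan
        assert decide_assignment(tuple(d)) == brute_force_rule(tuple(d))


# ---------------------------------------------------------------------------
# ledger mechanics on a constructed geometry
# ---------------------------------------------------------------------------


@pytest.fixture()
def toy(sizes):
    """Diploid model with hand-placed chains: mat/pat copies far apart."""
    model = dc.GenomeModel.from_chrom_sizes(sizes, 20_000)
    x = np.zeros((model.n_beads, 3))
    for i, c in enumerate(model.chains):
        # chains along +x, spaced 40 apart in y; beads 1 apart in x
        x[c.start : c.stop, 0] = np.arange(c.n_beads)
        x[c.start : c.stop, 1] = 40.0 * i
    return model, dc.Conformation(model, x)


def test_assign_contacts_uses_geometry(toy, sizes):
    model, conf = toy
    # ambiguous intra-chromosomal contact whose mat option is compact (dist 2)
    # and all cross options are ~40 away
    rec = dc.ContactRecord("chr1", 10_000, "mat", "chr1", 50_000, None)
    led = dc.AssignmentLedger([rec], sizes)
    assert led.status[0] == UNASSIGNED
    led.begin_iteration(0)
    assign_contacts(led, conf)
    assert led.status[0] == ASSIGNED
    ha, hb = led.options[0][led.assigned[0]]
    assert (ha, hb) == ("mat", "mat")


def test_assign_contacts_blocked_by_second_close_option(toy, sizes):
    model, conf = toy
    # both-unknown intra contact: (mat,mat) and (pat,pat) are equally close
    rec = dc.ContactRecord("chr1", 10_000, None, "chr1", 50_000, None)
    led = dc.AssignmentLedger([rec], sizes)
    led.begin_iteration(0)
    assign_contacts(led, conf)
    assert led.status[0] == UNASSIGNED


def test_remove_stretched_and_reinstatement(toy, sizes):
    model, conf = toy
    # unambiguous contact at distance 40 (cross-copy) -> removed
    far = dc.ContactRecord("chr1", 10_000, "mat", "chr1", 10_000, "pat")
    near = dc.ContactRecord("chr1", 10_000, "mat", "chr1", 48_000, "mat")  # dist 2.0
    led = dc.AssignmentLedger([far, near], sizes)
    led.begin_iteration(0)
    remove_stretched(led, conf)
    state = dict(zip(led.keys(), led.status))
    assert state[far.key] == REMOVED
    assert state[near.key] == UNAMBIGUOUS  # below 3.0: retained
    # reinstatement: once the structure brings the pair below 3.0 the removed
    # unambiguous contact is assigned again
    squeezed = conf.copy()
    squeezed.coords[:, 1] = 0.0
    led.begin_iteration(1)
    assign_contacts(led, squeezed)
    assert dict(zip(led.keys(), led.status))[far.key] == UNAMBIGUOUS


def test_assigned_contact_cleared_on_stretch(toy, sizes):
    model, conf = toy
    rec = dc.ContactRecord("chr1", 10_000, "mat", "chr1", 50_000, None)
    led = dc.AssignmentLedger([rec], sizes)
    led.begin_iteration(0)
    assign_contacts(led, conf)
    assert led.status[0] == ASSIGNED
    stretched = conf.copy()
    stretched.coords[model.chains[0].start + 2, :] += 100.0  # move bead of bin 2
    led.begin_iteration(1)
    remove_stretched(led, stretched)
    assert led.status[0] == REMOVED
    assert led.assigned[0] == -1  # assignment not saved


# ---------------------------------------------------------------------------
# resolution lifting
# ---------------------------------------------------------------------------


def test_lift_resolution_reenters_same_bead_contacts(sizes):
    coarse = dc.GenomeModel.from_chrom_sizes(sizes, 1_000_000)
    fine = dc.GenomeModel.from_chrom_sizes(sizes, 200_000)
    rec = dc.ContactRecord("chr1", 100_000, "mat", "chr1", 500_000, "mat")
    # omitted at 1 Mbp (same bead), active at 200 kbp
    assert len(dc.build_bead_contacts([rec], coarse)) == 0
    assert len(dc.build_bead_contacts([rec], fine)) == 1
    led = dc.AssignmentLedger([rec], sizes)
    out = dc.lift_resolution(led, coarse, fine)
    assert out is led


def test_lift_resolution_rejects_mismatched_genomes(sizes):
    coarse = dc.GenomeModel.from_chrom_sizes(sizes, 1_000_000)
    other = dc.GenomeModel.from_chrom_sizes({"chr1": 600_000}, 200_000)
    with pytest.raises(ValueError):
        dc.lift_resolution(dc.AssignmentLedger([], sizes), coarse, other)


def test_interpolate_start_children_near_parents(sizes, rng):
    coarse = dc.GenomeModel.from_chrom_sizes(sizes, 100_000)
    fine = dc.GenomeModel.from_chrom_sizes(sizes, 20_000)
    conf_lo = dc.Conformation(coarse, rng.normal(0, 5, (coarse.n_beads, 3)))
    seeded = dc.interpolate_start(conf_lo, fine, seed=1)
    for b in range(fine.n_beads):
        c = fine.chains[fine.bead_chain[b]]
        parent = coarse.locus_to_bead(c.name, c.homolog, int(fine.bead_mid_bp(b)))
        assert np.linalg.norm(seeded.coords[b] - conf_lo.coords[parent]) < 1.0


# ---------------------------------------------------------------------------
# merging independent series
# ---------------------------------------------------------------------------


def _ledgers_with_assignments(sizes, assignments):
    """Build n ledgers over two ambiguous records, applying given options."""
    recs = [
        dc.ContactRecord("chr1", 10_000, None, "chr2", 10_000, None),
        dc.ContactRecord("chr1", 200_000, None, "chr2", 200_000, None),
    ]
    ledgers = []
    for spec in assignments:
        led = dc.AssignmentLedger(recs, sizes)
        for idx, opt in spec.items():
            led.status[idx] = ASSIGNED
            led.assigned[idx] = opt
        ledgers.append(led)
    return ledgers


def test_merge_consistent_single_supporter_kept(sizes):
    ledgers = _ledgers_with_assignments(
        sizes, [{0: 2}, {}, {0: 2}, {}, {}, {}, {}, {0: 2}, {}, {}]
    )
    merged = merge_runs(ledgers)
    assert merged.status[0] == ASSIGNED and merged.assigned[0] == 2
    assert merged.status[1] == UNASSIGNED


def test_merge_inconsistent_discarded(sizes):
    ledgers = _ledgers_with_assignments(sizes, [{0: 1}, {0: 3}, {}])
    merged = merge_runs(ledgers)
    assert merged.status[0] == DISCARDED


def test_merge_order_independent_and_idempotent(sizes, rng):
    specs = [{0: int(rng.integers(4))} if rng.random() < 0.5 else {} for _ in range(10)]
    ledgers = _ledgers_with_assignments(sizes, specs)
    merged = merge_runs(ledgers)
    perm = [ledgers[i] for i in rng.permutation(10)]
    merged_perm = merge_runs(perm)
    assert merged.status == merged_perm.status
    assert merged.assigned == merged_perm.assigned
    again = merge_runs([merged])
    assert again.status == merged.status


def test_merge_empty_ledgers(sizes):
    ledgers = [dc.AssignmentLedger([], sizes) for _ in range(10)]
    assert len(merge_runs(ledgers)) == 0


def test_merge_rejects_provenance_mismatch(sizes):
    a = dc.AssignmentLedger(
        [dc.ContactRecord("chr1", 1, None, "chr2", 1, None)], sizes
    )
    b = dc.AssignmentLedger(
        [dc.ContactRecord("chr1", 2, None, "chr2", 1, None)], sizes
    )
    with pytest.raises(ValueError, match="provenance"):
        merge_runs([a, b])


# ---------------------------------------------------------------------------
# ladder orchestration
# ---------------------------------------------------------------------------


def test_ladder_plan_validation():
    plan = dc.LadderPlan.default()
    assert plan.resolutions == (
        5_000_000, 2_000_000, 1_000_000, 500_000, 200_000, 100_000, 50_000, 20_000
    )
    assert plan.merge_count == 10
    assert plan.post_merge == (20_000, 10_000, 5_000)
    rod = dc.LadderPlan.rod_cell()
    assert rod.resolutions[0] == 500_000 and rod.resolutions[-1] == 20_000
    assert rod.merge_count == 1
    with pytest.raises(ValueError):
        dc.LadderPlan((100_000, 100_000))
    with pytest.raises(ValueError):
        dc.LadderPlan((100_000,), merge_count=1, post_merge=(50_000,))


def test_single_resolution_ladder_reduces_to_minimize(recovery_fixture):
    """A degenerate one-level plan with unambiguous contacts = plain minimize."""
    fix = recovery_fixture
    plan = dc.LadderPlan((20_000,))
    sched = dc.make_schedule(steps_equil=300, steps_stage=200, steps_final=200)
    cfg = dc.LadderConfig(seed=3, schedule_factory=lambda r, m: sched,
                          haploid=tuple(fix.spec.sizes))
    res = dc.run_ladder(fix.records, fix.spec.sizes, plan, cfg)
    pairs = dc.build_bead_contacts(fix.records, fix.model).pair_array()
    direct = dc.minimize(fix.model, pairs, sched,
                         seed=res.conformation.provenance["seed"])
    np.testing.assert_array_equal(res.conformation.coords, direct.conformation.coords)


def test_ladder_errors_without_usable_contacts(sizes):
    recs = [dc.ContactRecord("chr1", 10_000, None, "chr2", 10_000, None)]
    with pytest.raises(dc.LadderError):
        dc.run_ladder(recs, sizes, dc.LadderPlan((100_000,)), dc.LadderConfig())


def test_merge_ladder_runs_and_reports(sizes, recovery_fixture):
    """merge_count>1 spawns independent series and merges their ledgers."""
    fix = recovery_fixture
    sched = dc.make_schedule(steps_equil=200, steps_stage=100, steps_final=100)
    plan = dc.LadderPlan((40_000, 20_000), merge_count=2, post_merge=(20_000,))
    cfg = dc.LadderConfig(seed=5, schedule_factory=lambda r, m: sched,
                          haploid=tuple(fix.spec.sizes))
    res = dc.run_ladder(fix.records, fix.spec.sizes, plan, cfg)
    assert set(res.report["run"]) == {0, 1, 2}  # two series + post-merge
    assert res.conformation.model.resolution == 20_000
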