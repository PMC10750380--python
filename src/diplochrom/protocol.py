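"""Progressive-resolution protocol: homolog assignment, removal, merge.

In a diploid cell most single-cell Hi-C contacts cannot be attributed to a
specific homolog: a contact between two homologous-pair chromosomes has up
to four candidate assignments (the four permutations of the two copies).
The protocol resolves them structurally. A first minimization at coarse
resolution uses only the unambiguous contacts; each subsequent resolution
re-maps the contact list onto finer beads, minimizes, and then

* removes any *used* contact whose bead distance exceeds 3.0 in the
  minimized structure (even an originally unambiguous one) — the removal
  lasts one iteration, after which the contact may be assigned again;
* assigns an ambiguous contact iff exactly one candidate option sits at a
  distance below 3.0 while every other option exceeds 5.0.

To push past the highest single-series resolution, several independent
series are run and their assigned contact lists merged; contacts assigned
inconsistently across series are discarded as unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ContactRecord, build_bead_contacts
from .minimize import (
    IntegratorConfig,
    MinimizeResult,
    ProtocolStage,
    make_schedule,
    minimize,
    quick_schedule,
)
from .model import Conformation, GenomeModel, HOMOLOG_LABELS, PotentialParams

# record lifecycle states
UNAMBIGUOUS = "unambiguous"
UNASSIGNED = "unassigned"
ASSIGNED = "assigned"
REMOVED = "removed"
DISCARDED = "discarded"

#: states under which a record contributes restraints to the next run
USABLE_STATES = (UNAMBIGUOUS, ASSIGNED)
#: states under which a record is currently eliminated from the structure
ELIMINATED_STATES = (UNASSIGNED, REMOVED, DISCARDED)


@dataclass(frozen=True)
class Thresholds:
    """Distance thresholds of the assignment/removal rules (simulation units)."""

    assign_below: float = 3.0
    reject_above: float = 5.0
    stretch_above: float = 3.0


def decide_assignment(
    distances: Sequence[float],
    assign_below: float = 3.0,
    reject_above: float = 5.0,
) -> int | None:
    """Apply the two-threshold rule to one contact's option distances.

    Returns the index of the single option strictly below ``assign_below``
    when every other (finite) option strictly exceeds ``reject_above``;
    otherwise ``None``. Non-finite distances mark options that could not be
    measured and are skipped.
    """
    d = np.asarray(distances, dtype=float)
    valid = np.isfinite(d)
    if not valid.any():
        return None
    close = valid & (d < assign_below)
    if int(close.sum()) != 1:
        return None
    k = int(np.flatnonzero(close)[0])
    others = valid & ~close
    if np.all(d[others] > reject_above):
        return k
    return None


def _options_for(record: ContactRecord, homologs: Mapping[str, tuple]) -> list[tuple]:
    """All concrete (homolog_a, homolog_b) pairings consistent with the labels."""

    def side(chrom, lab):
        if lab is not None:
            return (lab,)
        return homologs.get(chrom, (None,))

    return [(ha, hb) for ha in side(record.chrom_a, record.homol_a)
            for hb in side(record.chrom_b, record.homol_b)]


class AssignmentLedger:
    """Per-contact assignment state across ladder iterations.

    Holds the canonical record list, each record's candidate homolog
    pairings, its current state, and a history of state changes. At most
    one option is assigned at a time; a removed contact is eligible for
    reassignment at the next iteration.
    """

    def __init__(
        self,
        records: Sequence[ContactRecord],
        sizes: Mapping[str, int],
        haploid: Iterable[str] = (),
    ):
        self.records = list(records)
        self.sizes = dict(sizes)
        self.haploid = frozenset(haploid)
        homologs = {
            name: ((None,) if name in self.haploid else HOMOLOG_LABELS)
            for name in self.sizes
        }
        self.options: list[list[tuple]] = [
            _options_for(r, homologs) for r in self.records
        ]
        self.status: list[str] = [
            UNAMBIGUOUS if len(opts) == 1 else UNASSIGNED for opts in self.options
        ]
        self.assigned: list[int] = [
            0 if len(opts) == 1 else -1 for opts in self.options
        ]
        self.history: list[tuple] = []  # (iteration, idx, event, detail)
        self.iteration: int | None = None

    # -- provenance --------------------------------------------------------

    def keys(self) -> tuple:
        return tuple(r.key for r in self.records)

    def copy(self) -> "AssignmentLedger":
        new = AssignmentLedger.__new__(AssignmentLedger)
        new.records = list(self.records)
        new.sizes = dict(self.sizes)
        new.haploid = self.haploid
        new.options = [list(o) for o in self.options]
        new.status = list(self.status)
        new.assigned = list(self.assigned)
        new.history = list(self.history)
        new.iteration = self.iteration
        return new

    def begin_iteration(self, tag) -> None:
        self.iteration = tag

    # -- views -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records)

    def usable_records(self) -> list[tuple[int, ContactRecord]]:
        """(index, concretely-labelled record) for every currently used contact."""
        out = []
        for i, (r, st) in enumerate(zip(self.records, self.status)):
            if st in USABLE_STATES:
                ha, hb = self.options[i][self.assigned[i]]
                out.append((i, r.with_homologs(ha, hb)))
        return out

    def candidate_indices(self) -> list[int]:
        return [i for i, st in enumerate(self.status) if st in (UNASSIGNED, REMOVED)]

    def counts(self) -> dict[str, int]:
        c: dict[str, int] = {}
        for st in self.status:
            c[st] = c.get(st, 0) + 1
        return c

    def state_of(self, key) -> str:
        try:
            i = self.keys().index(key)
        except ValueError:
            raise KeyError(key) from None
        return self.status[i]

    # -- persistence -------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.records):
            opt = self.assigned[i]
            ha, hb = self.options[i][opt] if opt >= 0 else (None, None)
            rows.append(
                dict(
                    chrom_a=r.chrom_a, pos_a=r.pos_a, homol_a=r.homol_a or ".",
                    chrom_b=r.chrom_b, pos_b=r.pos_b, homol_b=r.homol_b or ".",
                    multiplicity=r.multiplicity, status=self.status[i],
                    assigned_a=ha or ".", assigned_b=hb or ".",
                )
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _option_distances(
    ledger: AssignmentLedger, idx: int, conf: Conformation
) -> np.ndarray:
    """Bead–bead distance of each candidate option in the structure.

    Options touching a chain absent from the model come out NaN (skipped).
    Two loci in the same bead give distance 0.
    """
    model = conf.model
    r = ledger.records[idx]
    d = np.full(len(ledger.options[idx]), np.nan)
    for k, (ha, hb) in enumerate(ledger.options[idx]):
        if not (model.has_chain(r.chrom_a, ha) and model.has_chain(r.chrom_b, hb)):
            continue
        i = model.locus_to_bead(r.chrom_a, ha, r.pos_a)
        j = model.locus_to_bead(r.chrom_b, hb, r.pos_b)
        d[k] = float(np.linalg.norm(conf.coords[i] - conf.coords[j]))
    return d


def assign_contacts(
    ledger: AssignmentLedger,
    conf: Conformation,
    thresholds: Thresholds = Thresholds(),
) -> AssignmentLedger:
    """Assign ambiguous (and reinstate removed) contacts from a minimized
    structure, per the two-threshold rule. Mutates and returns the ledger."""
    for i in ledger.candidate_indices():
        d = _option_distances(ledger, i, conf)
        k = decide_assignment(d, thresholds.assign_below, thresholds.reject_above)
        if k is not None:
            ledger.status[i] = UNAMBIGUOUS if len(ledger.options[i]) == 1 else ASSIGNED
            ledger.assigned[i] = k
            ledger.history.append((ledger.iteration, i, "assigned", float(d[k])))
    return ledger


def remove_stretched(
    ledger: AssignmentLedger,
    conf: Conformation,
    thresholds: Thresholds = Thresholds(),
) -> AssignmentLedger:
    """Drop used contacts stretched beyond 3.0 in the minimized structure.

    The assignment is cleared (not saved) but the contact may be assigned
    again after the next run — removal is per-iteration, not permanent.
    """
    for i, rec in ledger.usable_records():
        d = _option_distances_concrete(rec, conf)
        if d is not None and d > thresholds.stretch_above:
            ledger.status[i] = REMOVED
            if len(ledger.options[i]) > 1:
                ledger.assigned[i] = -1
            ledger.history.append((ledger.iteration, i, "removed", float(d)))
    return ledger


def _option_distances_concrete(rec: ContactRecord, conf: Conformation) -> float | None:
    model = conf.model
    if not (model.has_chain(rec.chrom_a, rec.homol_a) and model.has_chain(rec.chrom_b, rec.homol_b)):
        return None
    i = model.locus_to_bead(rec.chrom_a, rec.homol_a, rec.pos_a)
    j = model.locus_to_bead(rec.chrom_b, rec.homol_b, rec.pos_b)
    return float(np.linalg.norm(conf.coords[i] - conf.coords[j]))


def lift_resolution(
    ledger: AssignmentLedger,
    model_lo: GenomeModel,
    model_hi: GenomeModel,
) -> AssignmentLedger:
    """Carry the ledger to a finer resolution.

    Assignments are homolog pairings, hence resolution-independent — the
    ledger itself needs no change; bead mappings are recomputed lazily from
    bp positions, so contacts omitted at the coarse resolution (same-bead)
    re-enter automatically once their loci fall into distinct, non-bonded
    beads. The models must describe the same genome.
    """
    if model_hi.resolution > model_lo.resolution:
        raise ValueError("lift_resolution expects a finer target model")
    lo = {(c.name, c.homolog): c.length_bp for c in model_lo.chains}
    hi = {(c.name, c.homolog): c.length_bp for c in model_hi.chains}
    if lo != hi:
        raise ValueError("genome tables of the two models disagree")
    return ledger


def interpolate_start(
    conf_lo: Conformation, model_hi: GenomeModel, seed: int = 0, jitter: float = 0.3
) -> Conformation:
    """Seed a finer model's start coordinates from a coarse structure.

    Each child bead is placed at its parent bead's position (the coarse
    bead containing the child bin's midpoint) plus a small jitter to lift
    the degeneracy — every child lands well within one bond length of its
    parent.
    """
    lo_tab = {(c.name, c.homolog): c.length_bp for c in conf_lo.model.chains}
    hi_tab = {(c.name, c.homolog): c.length_bp for c in model_hi.chains}
    if lo_tab != hi_tab:
        raise ValueError("genome tables of the two models disagree")
    rng = np.random.default_rng(seed)
    x = np.empty((model_hi.n_beads, 3))
    lo = conf_lo.model
    for b in range(model_hi.n_beads):
        c = model_hi.chains[model_hi.bead_chain[b]]
        mid = min(int(model_hi.bead_mid_bp(b)), c.length_bp - 1)
        parent = lo.locus_to_bead(c.name, c.homolog, mid)
        x[b] = conf_lo.coords[parent]
    x += rng.normal(0.0, jitter / 3.0, size=x.shape)
    return Conformation(model_hi, x, {"init": "interpolated", "from_resolution": lo.resolution})


def merge_runs(ledgers: Sequence[AssignmentLedger]) -> AssignmentLedger:
    """Merge assignments from independent series into one contact list.

    A contact assigned to the same option in every series that assigned it
    is kept with that option (a single supporting series suffices — only
    *inconsistent* assignments are unreliable); options disagreeing across
    series are discarded; never-assigned contacts stay unassigned. The
    merge is order-independent and idempotent.
    """
    if not ledgers:
        raise ValueError("no ledgers to merge")
    keys0 = ledgers[0].keys()
    for l in ledgers[1:]:
        if l.keys() != keys0 or l.sizes != ledgers[0].sizes:
            raise ValueError("ledger provenance mismatch: different contact lists")
    out = ledgers[0].copy()
    out.history = []
    out.begin_iteration("merge")
    for i in range(len(out)):
        if len(out.options[i]) == 1:
            out.status[i] = UNAMBIGUOUS
            out.assigned[i] = 0
            continue
        chosen = {
            l.assigned[i]
            for l in ledgers
            if l.status[i] == ASSIGNED
        }
        # a run may have discarded earlier; discards propagate
        if any(l.status[i] == DISCARDED for l in ledgers) or len(chosen) > 1:
            out.status[i] = DISCARDED
            out.assigned[i] = -1
            out.history.append(("merge", i, "discarded", len(chosen)))
        elif len(chosen) == 1:
            out.status[i] = ASSIGNED
            out.assigned[i] = chosen.pop()
        else:
            out.status[i] = UNASSIGNED
            out.assigned[i] = -1
    return out


# ---------------------------------------------------------------------------
# Ladder orchestration
# ---------------------------------------------------------------------------


class LadderError(RuntimeError):
    pass


@dataclass(frozen=True)
class LadderPlan:
    """Resolution schedule of a reconstruction."""

    resolutions: tuple[int, ...]
    merge_count: int = 1
    post_merge: tuple[int, ...] = ()

    def __post_init__(self):
        if not self.resolutions:
            raise ValueError("empty resolution ladder")
        if any(b >= a for a, b in zip(self.resolutions, self.resolutions[1:])):
            raise ValueError("resolutions must strictly decrease (refine)")
        if self.merge_count < 1:
            raise ValueError("merge_count must be >= 1")
        if self.merge_count == 1 and self.post_merge:
            raise ValueError("post_merge stages require merge_count > 1")

    @classmethod
    def default(cls) -> "LadderPlan":
        """Full protocol: 5 Mbp → 20 kbp in eight steps, 10-run merge,
        then 20 kbp, 10 kbp and 5 kbp on the merged list."""
        return cls(
            (5_000_000, 2_000_000, 1_000_000, 500_000, 200_000, 100_000, 50_000, 20_000),
            merge_count=10,
            post_merge=(20_000, 10_000, 5_000),
        )

    @classmethod
    def rod_cell(cls) -> "LadderPlan":
        """Sparse-data variant: start at 500 kbp, end at 20 kbp, no merge."""
        return cls((500_000, 200_000, 100_000, 50_000, 20_000))

    @classmethod
    def desk_scale(cls) -> "LadderPlan":
        """Three-resolution ladder for megabase-sized test genomes."""
        return cls((100_000, 50_000, 20_000))


@dataclass
class LadderConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    schedule_factory: Callable[[int, GenomeModel], list[ProtocolStage]] = (
        lambda res, model: make_schedule()
    )
    integ: IntegratorConfig = field(default_factory=IntegratorConfig)
    params: PotentialParams = field(default_factory=PotentialParams)
    seed: int = 0
    haploid: tuple[str, ...] = ()
    interpolate: bool = False
    cube_side: float = 10.0


@dataclass
class LadderResult:
    conformation: Conformation
    ledger: AssignmentLedger
    structures: list[tuple[int, Conformation]]
    report: pd.DataFrame

    @property
    def final_model(self) -> GenomeModel:
        return self.conformation.model


def _sub_seed(base: int, run: int, level: int) -> int:
    return int((base * 9_973 + run * 613 + level * 7 + 1) % (2**31 - 1))


def _one_series(
    ledger: AssignmentLedger,
    sizes: Mapping[str, int],
    resolutions: Sequence[int],
    config: LadderConfig,
    run_id: int,
    rows: list,
) -> tuple[Conformation, list[tuple[int, Conformation]]]:
    prev_conf: Conformation | None = None
    structures: list[tuple[int, Conformation]] = []
    conf = None
    for level, res in enumerate(resolutions):
        model = GenomeModel.from_chrom_sizes(sizes, res, haploid=config.haploid)
        used = [rec for _, rec in ledger.usable_records()]
        cset = build_bead_contacts(used, model)
        if len(cset) == 0:
            raise LadderError(
                f"no usable contacts at resolution {res} "
                f"(run {run_id}; {ledger.counts()})"
            )
        if level == 0:
            per_bead = len(cset) / model.n_beads
            if per_bead < 1.0:
                warnings.warn(
                    f"only {per_bead:.2f} unambiguous contacts per bead at the "
                    f"initial resolution {res}; aim for around one per bead",
                    stacklevel=3,
                )
        start = None
        if config.interpolate and prev_conf is not None:
            start = interpolate_start(
                prev_conf, model, seed=_sub_seed(config.seed, run_id, 100 + level)
            )
        result: MinimizeResult = minimize(
            model,
            cset.pair_array(),
            schedule=config.schedule_factory(res, model),
            integ=config.integ,
            params=config.params,
            seed=_sub_seed(config.seed, run_id, level),
            start=start,
            cube_side=config.cube_side,
        )
        conf = result.conformation
        conf.provenance.update({"run": run_id, "resolution": res})
        ledger.begin_iteration((run_id, res))
        remove_stretched(ledger, conf, config.thresholds)
        assign_contacts(ledger, conf, config.thresholds)
        counts = ledger.counts()
        rows.append(
            dict(
                run=run_id,
                resolution=res,
                n_beads=model.n_beads,
                n_restraints=len(cset),
                restraints_per_bead=len(cset) / model.n_beads,
                n_raw_usable=len(used),
                n_ambiguous_skipped=cset.n_ambiguous_skipped,
                n_same_bead=cset.n_same_bead,
                n_duplicate=cset.n_duplicate,
                n_assigned=counts.get(ASSIGNED, 0),
                n_unassigned=counts.get(UNASSIGNED, 0),
                n_removed=counts.get(REMOVED, 0),
                n_discarded=counts.get(DISCARDED, 0),
                final_energy=result.traces[-1].final_energy,
            )
        )
        prev_conf = conf
        structures.append((res, conf))
    return conf, structures


def run_ladder(
    records: Sequence[ContactRecord],
    sizes: Mapping[str, int],
    plan: LadderPlan,
    config: LadderConfig | None = None,
) -> LadderResult:
    """Run the full progressive protocol on a contact list.

    The initial resolution uses only unambiguous contacts (nothing is
    assigned yet); each level then minimizes, removes stretched contacts,
    and assigns ambiguous ones for the next level. With ``merge_count > 1``
    the whole pre-merge ladder is repeated as independent series whose
    assignments are merged before the post-merge resolutions run.
    """
    config = config or LadderConfig()
    rows: list[dict] = []
    base = AssignmentLedger(records, sizes, haploid=config.haploid)
    if plan.merge_count == 1:
        ledger = base
        conf, structures = _one_series(
            ledger, sizes, plan.resolutions, config, run_id=0, rows=rows
        )
    else:
        ledgers = []
        structures = []
        conf = None
        for run in range(plan.merge_count):
            led = base.copy()
            conf, st = _one_series(
                led, sizes, plan.resolutions, config, run_id=run, rows=rows
            )
            ledgers.append(led)
            if run == 0:
                structures = st
        ledger = merge_runs(ledgers)
        if plan.post_merge:
            conf, st = _one_series(
                ledger, sizes, plan.post_merge, config,
                run_id=plan.merge_count, rows=rows,
            )
            structures = structures + st
    return LadderResult(conf, ledger, structures, pd.DataFrame(rows))
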