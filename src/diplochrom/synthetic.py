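"""Desk-scale diploid test systems with known ground truth.

The generator emulates the statistical structure the reconstruction method
assumes: compact chains with distinct territories (dense intra-chain
contacts, sparse inter-chain ones), homolog ambiguity from unphased reads,
and a controllable admixture of uniformly random spurious contacts. Every
pipeline stage can be exercised against the known conformation without any
external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import (
    ContactRecord,
    canonicalize,
    write_chrom_sizes,
    write_contacts,
    write_structure,
    write_track,
)
from .model import Conformation, GenomeModel

TRUTH_KINDS = ("confined_walk", "globule", "territory")
TRACK_KINDS = ("central", "inverted", "uniform")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic diploid system.

    Defaults describe the standard desk-scale condition: two chromosome
    pairs of a few Mbp each at 20 kbp resolution (4 chains of 180/120
    beads), territory-packed ground truth at liquid-like bead density,
    contacts derived from all pairs within 2 simulation-length units
    (a data-rich regime of several restraints per bead), 25% of contacts
    with homolog labels stripped (as in a haplotype-imputed single-cell
    data set), and no spurious contacts unless injected.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 3_600_000, "chr2": 2_400_000}
    )
    resolution: int = 20_000
    kind: str = "territory"
    density: float = 0.5              # beads per unit volume in a territory
    contact_cutoff: float = 2.0       # derive contacts from pairs closer than this
    subsample: float = 1.0            # fraction of candidate contacts kept
    ambiguity: float = 0.25           # fraction of contacts with labels stripped
    spurious: float = 0.0             # spurious contacts as a fraction of real ones
    track: str = "central"
    ploidy: int = 2
    seed: int = 0

    def __post_init__(self):
        for name, v in (("subsample", self.subsample), ("ambiguity", self.ambiguity)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.spurious < 0:
            raise ValueError("spurious fraction must be non-negative")
        if self.kind not in TRUTH_KINDS:
            raise ValueError(f"kind must be one of {TRUTH_KINDS}")
        if self.track not in TRACK_KINDS:
            raise ValueError(f"track must be one of {TRACK_KINDS}")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chrom_lengths)


def _confined_walk(
    n: int, center: np.ndarray, radius: float, rng, start: np.ndarray | None = None
) -> np.ndarray:
    """Random walk with unit steps confined to a sphere: compact, globule-like."""
    x = np.empty((n, 3))
    x[0] = center + rng.normal(0, 0.1, 3) if start is None else start
    for i in range(1, n):
        for _ in range(64):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            cand = x[i - 1] + step
            if np.linalg.norm(cand - center) <= radius:
                break
        else:
            # pull back toward the center if the walk got stuck at the wall
            d = center - x[i - 1]
            cand = x[i - 1] + d / np.linalg.norm(d)
        x[i] = cand
    return x


def _territory_centers(k: int, edge: float, rng) -> np.ndarray:
    """k territory centers with nearest-neighbor separation ``edge``.

    Vertices of simple polytopes, scaled so adjacent territory spheres
    touch — chromosome territories tile the nucleus rather than floating
    in a void, and the touching interfaces are what gives a contact list
    its (sparse) inter-chromosomal contacts.
    """
    base = np.array(
        [
            [1.0, 1.0, 1.0], [-1.0, -1.0, 1.0], [-1.0, 1.0, -1.0], [1.0, -1.0, -1.0],
            [1.0, 1.0, -1.0], [-1.0, -1.0, -1.0], [-1.0, 1.0, 1.0], [1.0, -1.0, 1.0],
        ]
    ) / np.sqrt(3.0)
    if k > len(base):
        extra = rng.normal(size=(k - len(base), 3))
        extra /= np.linalg.norm(extra, axis=1, keepdims=True)
        base = np.vstack([base, extra])
    pts = base[:k]
    if k == 1:
        return np.zeros((1, 3))
    dmin = min(
        float(np.linalg.norm(pts[i] - pts[j]))
        for i in range(k) for j in range(i + 1, k)
    )
    return pts * (edge / dmin)


def _relax_in_spheres(
    model: GenomeModel,
    x: np.ndarray,
    centers: np.ndarray,
    radii: np.ndarray,
    rng,
    n_steps: int = 3_000,
    k_conf: float = 20.0,
) -> np.ndarray:
    """Equilibrate a starting configuration under the polymer model itself.

    Bonds and excluded volume are the reconstruction model's own potentials,
    plus a harmonic wall holding each chain inside its territory sphere
    (generator-only plumbing). This makes the ground truth a configuration
    the model could have produced: bond lengths near 1 and spatial-neighbor
    spacing set by the soft-core diameter (~1.4), so derived contacts sit
    near the contact potential's minimum instead of far inside it.
    """
    from .minimize import IntegratorConfig
    from . import _kernels
    from .model import PotentialParams

    p = PotentialParams()
    integ = IntegratorConfig()
    bonds = np.ascontiguousarray(model.bonds())
    none = np.empty((0, 2), dtype=np.int64)
    x = np.ascontiguousarray(x, dtype=np.float64).copy()
    v = rng.normal(0.0, 1.0, x.shape)
    a = float(np.exp(-integ.gamma * integ.dt))
    b = float(np.sqrt(integ.kT * (1.0 - a * a)))
    chain_of = model.bead_chain
    half = 0.5 * integ.dt
    f = np.zeros_like(x)
    chunk = 100
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = rng.standard_normal((m, x.shape[0], 3))
        for s in range(m):
            f[:] = 0.0
            _kernels.harmonic_pairs(x, bonds, p.k_b, p.r0_b, f)
            _kernels.ev_auto(x, p.epsilon, p.sigma, p.r_cut, f)
            # harmonic wall outside each territory sphere
            d = x - centers[chain_of]
            r = np.linalg.norm(d, axis=1)
            out = r > radii[chain_of]
            if out.any():
                exc = (r[out] - radii[chain_of][out]) / np.maximum(r[out], 1e-12)
                f[out] -= k_conf * exc[:, None] * d[out]
            v += half * f
            x += half * v
            v *= a
            v += b * noise[s]
            x += half * v
            v += half * f  # half-kick with stale force: adequate for sampling
        done += m
    return x


def make_ground_truth(spec: FixtureSpec) -> tuple[GenomeModel, Conformation]:
    """Generate the model and a ground-truth conformation.

    ``territory``: each chain starts as a confined walk in its own sphere
    (adjacent spheres touching, homologous copies on distinct vertices) and
    is then equilibrated under the model's own bond/excluded-volume
    potentials with a territory-confinement wall — compact, melt-like
    chromosome territories. ``confined_walk``: all chains share one sphere
    (territories mix). ``globule``: like ``territory`` but ~50% denser.
    """
    model = GenomeModel.from_chrom_sizes(spec.sizes, spec.resolution, ploidy=spec.ploidy)
    rng = np.random.default_rng(spec.seed)
    density = spec.density * (1.5 if spec.kind == "globule" else 1.0)

    def sphere_radius(n: int) -> float:
        return (3.0 * n / (4.0 * np.pi * density)) ** (1.0 / 3.0)

    x = np.empty((model.n_beads, 3))
    if spec.kind == "confined_walk":
        r_all = sphere_radius(model.n_beads)
        for c in model.chains:
            s = rng.normal(size=3)
            s *= rng.random() ** (1 / 3) * 0.8 * r_all / np.linalg.norm(s)
            x[c.start : c.stop] = _confined_walk(
                c.n_beads, np.zeros(3), r_all, rng, start=s
            )
        centers = np.zeros((len(model.chains), 3))
        radii = np.full(len(model.chains), r_all)
    else:
        radii = np.array([sphere_radius(c.n_beads) for c in model.chains])
        # adjacent spheres just touch (slight overlap seeds interface contacts)
        edge = 0.95 * 2.0 * float(np.mean(radii))
        vertex = _territory_centers(len(model.chains), edge, rng)
        centers = np.empty_like(vertex)
        # keep homologous copies on distinct vertices
        order = np.argsort([f"{c.name}:{c.homolog}" for c in model.chains], kind="stable")
        for rank, ci in enumerate(order):
            c = model.chains[ci]
            centers[ci] = vertex[rank]
            x[c.start : c.stop] = _confined_walk(
                c.n_beads, vertex[rank], radii[ci], rng
            )
    x = _relax_in_spheres(model, x, centers, radii, rng)
    # Second pass: swap the confinement wall for the structure's own
    # spatial-neighbor contacts and re-equilibrate without walls. The truth
    # is then a thermal state of the reconstruction model under restraints
    # its own geometry implies — i.e., a structure the pipeline can in
    # principle recover exactly (up to a rigid motion and a mirror).
    from .minimize import IntegratorConfig, ProtocolStage, run_stage
    from .model import PotentialParams

    p = PotentialParams()
    conf = Conformation(model, x)
    bonds = model.bonds()
    # two derive→anneal passes converge to a thermal state whose own
    # spatial-neighbor set is (approximately) the restraint set
    for k in range(2):
        tree = cKDTree(conf.coords)
        pairs = tree.query_pairs(r=spec.contact_cutoff, output_type="ndarray")
        pairs = np.sort(pairs, axis=1)
        same = model.bead_chain[pairs[:, 0]] == model.bead_chain[pairs[:, 1]]
        adj = pairs[:, 1] == pairs[:, 0] + 1
        pairs = np.ascontiguousarray(pairs[~(same & adj)], dtype=np.int64)
        stage = ProtocolStage(p.k_c, p.sigma, p.epsilon, 3_000, f"truth-anneal-{k}")
        conf, _, _ = run_stage(conf, bonds, pairs, stage,
                               IntegratorConfig(), p, rng)
    conf.provenance.update({"truth": spec.kind, "seed": spec.seed})
    return model, conf


def derive_contacts(
    truth: Conformation,
    cutoff: float | None = None,
    subsample: float = 1.0,
    ambiguity: float = 0.0,
    seed: int = 0,
) -> list[ContactRecord]:
    """Contacts implied by a ground-truth structure.

    Every non-bonded bead pair within ``cutoff`` becomes a candidate
    contact; each gets bp positions drawn uniformly inside the two bins (so
    bin-rounding paths are exercised), is kept with probability
    ``subsample``, and has both homolog labels stripped with probability
    ``ambiguity``. The truth structure satisfies every derived contact by
    construction (all below the cutoff), so with ambiguity 0 the list pins
    the truth down to a rigid motion and a mirror.
    """
    if cutoff is None:
        cutoff = 2.0
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    model = truth.model
    rng = np.random.default_rng(seed)
    tree = cKDTree(truth.coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    records: list[ContactRecord] = []
    for i, j in np.sort(pairs, axis=1):
        same = model.bead_chain[i] == model.bead_chain[j]
        if i == j or (same and j == i + 1):
            continue
        if subsample < 1.0 and rng.random() >= subsample:
            continue
        ca = model.chains[model.bead_chain[i]]
        cb = model.chains[model.bead_chain[j]]
        pa = model.bead_start_bp(i) + int(
            rng.integers(0, min(model.resolution, ca.length_bp - model.bead_start_bp(i)))
        )
        pb = model.bead_start_bp(j) + int(
            rng.integers(0, min(model.resolution, cb.length_bp - model.bead_start_bp(j)))
        )
        ha, hb = ca.homolog, cb.homolog
        if ambiguity > 0 and rng.random() < ambiguity:
            ha, hb = None, None
        records.append(ContactRecord(ca.name, pa, ha, cb.name, pb, hb))
    return canonicalize(records)


def inject_spurious(
    records: Sequence[ContactRecord],
    sizes: Mapping[str, int],
    fraction: float = 0.05,
    seed: int = 0,
    ambiguity: float | None = None,
) -> tuple[list[ContactRecord], frozenset]:
    """Add uniformly random locus pairs and return their canonical keys.

    ``round(fraction · n_real)`` spurious contacts are placed uniformly
    over the genome (any chromosomes, not distance-matched). By default
    they carry no homolog labels: spurious contacts model random ligation
    noise, and a random read pair carries no reliable haplotype phasing —
    which is precisely why the structural assignment gate can reject them.
    ``ambiguity`` < 1 labels a share of them with random homologs to
    stress the harder, phased-noise case. The tag set is for scoring only
    and is invisible to the pipeline.
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    rng = np.random.default_rng(seed)
    n_add = int(round(fraction * len(records)))
    if ambiguity is None:
        ambiguity = 1.0
    names = list(sizes)
    existing = {r.key for r in records}
    spurious: list[ContactRecord] = []
    spurious_keys: set = set()
    from .model import HOMOLOG_LABELS

    while len(spurious) < n_add:
        ca, cb = rng.choice(names), rng.choice(names)
        pa = int(rng.integers(0, sizes[ca]))
        pb = int(rng.integers(0, sizes[cb]))
        if ca == cb and pa == pb:
            continue
        if rng.random() < ambiguity:
            ha, hb = None, None
        else:
            ha = HOMOLOG_LABELS[int(rng.integers(0, 2))]
            hb = HOMOLOG_LABELS[int(rng.integers(0, 2))]
        rec = ContactRecord(ca, pa, ha, cb, pb, hb).canonical()
        if rec.key in existing or rec.key in spurious_keys:
            continue
        spurious.append(rec)
        spurious_keys.add(rec.key)
    combined = canonicalize(list(records) + spurious)
    return combined, frozenset(spurious_keys)


def score_spurious_removal(ledger, spurious_keys: frozenset) -> float:
    """Fraction of tagged spurious contacts the protocol eliminated
    (left in removed/unassigned/discarded state)."""
    from .protocol import ELIMINATED_STATES

    keys = ledger.keys()
    idx = [i for i, k in enumerate(keys) if k in spurious_keys]
    if not idx:
        raise ValueError("no tagged spurious contacts found in ledger")
    gone = sum(1 for i in idx if ledger.status[i] in ELIMINATED_STATES)
    return gone / len(idx)


def make_track(
    model: GenomeModel,
    kind: str,
    seed: int = 0,
    truth: Conformation | None = None,
    noise: float = 0.05,
) -> np.ndarray:
    """Per-bead scalar track (a CpG-density stand-in).

    ``central`` decreases with the ground-truth radial position (the usual
    nuclear arrangement), ``inverted`` increases outward (the rod
    photoreceptor arrangement), ``uniform`` is constant. The track is
    genomic: homologous copies of a bin share one value (the mean of the
    two copies' radial signals), as a sequence-derived track would.
    """
    if kind not in TRACK_KINDS:
        raise ValueError(f"kind must be one of {TRACK_KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        return np.ones(model.n_beads)
    if truth is None:
        raise ValueError(f"{kind!r} track needs the ground-truth conformation")
    x = truth.coords - truth.coords.mean(axis=0)
    r = np.linalg.norm(x, axis=1)
    rn = r / r.max() if r.max() > 0 else r
    base = (1.0 - rn) if kind == "central" else rn
    vals = 0.1 + base
    # symmetrize across homologs: one value per genomic bin
    groups: dict[tuple, list[int]] = {}
    for b in range(model.n_beads):
        c = model.chains[model.bead_chain[b]]
        groups.setdefault((c.name, int(model.bead_bin[b])), []).append(b)
    for beads in groups.values():
        m = float(np.mean(vals[beads])) + noise * float(rng.standard_normal())
        vals[beads] = m
    return np.clip(vals, 0.01, None)


@dataclass
class Fixture:
    """A fully materialized synthetic system."""

    spec: FixtureSpec
    model: GenomeModel
    truth: Conformation
    records: list[ContactRecord]
    spurious_keys: frozenset
    track: np.ndarray


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Ground truth → contacts (→ spurious) → track, all from one seed."""
    model, truth = make_ground_truth(spec)
    records = derive_contacts(
        truth, spec.contact_cutoff, spec.subsample, spec.ambiguity,
        seed=spec.seed + 1,
    )
    keys: frozenset = frozenset()
    if spec.spurious > 0:
        records, keys = inject_spurious(
            records, spec.sizes, spec.spurious, seed=spec.seed + 2
        )
    track = make_track(model, spec.track, seed=spec.seed + 3, truth=truth)
    return Fixture(spec, model, truth, records, keys, track)


def emit_fixture(fix: Fixture, outdir) -> dict[str, Path]:
    """Write the fixture as the same plain-text files the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "contacts": outdir / "contacts.tsv",
        "sizes": outdir / "chrom.sizes",
        "truth": outdir / "truth.3dg",
        "track": outdir / "track.bedgraph",
        "manifest": outdir / "manifest.json",
    }
    write_contacts(fix.records, paths["contacts"])
    write_chrom_sizes(fix.spec.sizes, paths["sizes"])
    write_structure(fix.truth, paths["truth"])
    write_track(fix.model, fix.track, paths["track"])
    manifest = {
        "chrom_lengths": fix.spec.sizes,
        "resolution": fix.spec.resolution,
        "kind": fix.spec.kind,
        "contact_cutoff": fix.spec.contact_cutoff,
        "subsample": fix.spec.subsample,
        "ambiguity": fix.spec.ambiguity,
        "spurious": fix.spec.spurious,
        "track": fix.spec.track,
        "seed": fix.spec.seed,
        "n_contacts": len(fix.records),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
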