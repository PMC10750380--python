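"""Structure QC and analysis.

Covers the standard checks applied to reconstructed ensembles: pruning of
low-contact edge segments ("arms" produced by contact-poor repetitive
regions), chirality detection and mirror normalization (a contact list
cannot distinguish a structure from its mirror image), RMSD against the
iteratively superposed mean structure, bond/contact length distributions,
recovery of the contact matrix from close bead pairs, and radial profiles
of genomic tracks such as CpG density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import ContactRecord
from .model import Conformation


# ---------------------------------------------------------------------------
# Rigid superposition (Kabsch, rotation only — never scaled, never reflected)
# ---------------------------------------------------------------------------


def kabsch_rotation(target: np.ndarray, mobile: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||target − mobile·Rᵀ|| (both centered)."""
    h = mobile.T @ target
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(target: np.ndarray, mobile: np.ndarray) -> np.ndarray:
    """Rigidly superpose ``mobile`` onto ``target`` (translation+rotation)."""
    tc = target - target.mean(axis=0)
    mc = mobile - mobile.mean(axis=0)
    r = kabsch_rotation(tc, mc)
    return mc @ r.T + target.mean(axis=0)


def pairwise_rmsd(a: np.ndarray, b: np.ndarray, mirror: bool = False) -> float:
    """RMSD between two coordinate sets after optimal rigid superposition.

    With ``mirror=True`` the reflection of ``b`` is also tried and the
    smaller RMSD returned — a contact list cannot determine a structure's
    global chirality, and when the chain-based chirality indicator is
    degenerate (e.g., intermixed chains) the mirror must be resolved by
    the superposition itself.
    """
    bb = superpose(a, b)
    r = float(np.sqrt(np.mean(np.sum((a - bb) ** 2, axis=1))))
    if mirror:
        bm = b - b.mean(axis=0)
        bm = bm * np.array([1.0, 1.0, -1.0])
        r = min(r, pairwise_rmsd(a, bm, mirror=False))
    return r


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


@dataclass
class StructureEnsemble:
    """Conformations of one genome model (e.g., independent minimizations)."""

    members: list[Conformation]

    def __post_init__(self):
        if not self.members:
            raise ValueError("empty ensemble")
        m0 = self.members[0].model
        for c in self.members[1:]:
            if c.model.n_beads != m0.n_beads:
                raise ValueError("ensemble members have differing bead counts")

    def __len__(self):
        return len(self.members)

    def coords(self) -> list[np.ndarray]:
        return [c.coords for c in self.members]


# ---------------------------------------------------------------------------
# Edge pruning
# ---------------------------------------------------------------------------


@dataclass
class PruneResult:
    kept: np.ndarray      # bead indices kept, ascending
    removed: np.ndarray   # bead indices removed, ascending
    counts: np.ndarray    # per-bead nearby-contact-endpoint counts
    conformation: Conformation  # original conformation (index with .kept)

    def kept_coords(self) -> np.ndarray:
        return self.conformation.coords[self.kept]


def prune_low_contact_beads(
    conf: Conformation,
    records: Sequence[ContactRecord],
    fraction: float = 0.06,
    window_bp: int = 500_000,
) -> PruneResult:
    """Remove the beads with the fewest nearby contacts.

    For each bead, count the contact *endpoints* whose genomic position
    falls within ±``window_bp`` of the bead's bin midpoint on the same
    chain; the ``floor(fraction·N)`` beads with the lowest counts are
    removed (ties broken by bead index). These contact-poor edge segments
    ("arms") sit outside the main structure and move between runs, so they
    are excluded from downstream analyses. Endpoints of ambiguous records
    (unknown homolog on a diploid chromosome) do not contribute.
    """
    model = conf.model
    if window_bp < model.resolution:
        raise ValueError(
            f"window ({window_bp} bp) must be at least one bin ({model.resolution} bp)"
        )
    # gather endpoint positions per chain
    per_chain: dict[int, list[int]] = {i: [] for i in range(len(model.chains))}
    for r in records:
        for chrom, hom, pos in (
            (r.chrom_a, r.homol_a, r.pos_a),
            (r.chrom_b, r.homol_b, r.pos_b),
        ):
            if model.has_chain(chrom, hom):
                per_chain[model.chain_index(chrom, hom)].append(pos)
    counts = np.zeros(model.n_beads, dtype=np.int64)
    for ci, positions in per_chain.items():
        if not positions:
            continue
        pos = np.sort(np.asarray(positions))
        c = model.chains[ci]
        for b in range(c.start, c.stop):
            mid = model.bead_mid_bp(b)
            lo = np.searchsorted(pos, mid - window_bp, side="left")
            hi = np.searchsorted(pos, mid + window_bp, side="right")
            counts[b] = hi - lo
    n_remove = int(np.floor(fraction * model.n_beads))
    order = np.argsort(counts, kind="stable")  # ties broken by bead index
    removed = np.sort(order[:n_remove])
    kept = np.sort(order[n_remove:])
    if n_remove and counts.max() == counts.min():
        warnings.warn(
            "all beads have equal nearby-contact counts; pruning falls back "
            "to the bead-index tie-break",
            stacklevel=2,
        )
    return PruneResult(kept, removed, counts, conf)


# ---------------------------------------------------------------------------
# Chirality
# ---------------------------------------------------------------------------


def chirality(conf: Conformation, tol: float = 1e-9) -> int:
    """Handedness of a structure: sign of the determinant of the first
    three chains' centers of mass after centering the whole structure.

    Returns +1 or −1; 0 flags a degenerate (coplanar/collinear) case. The
    choice of the first three chains is arbitrary but consistent across an
    ensemble that shares territory placement, which is all the mirror
    normalization needs. Note that a genome with exactly three chains is
    always degenerate: after centering, the three chain centers are
    linearly dependent, so the determinant vanishes identically — at least
    four chains are needed for a meaningful sign.
    """
    model = conf.model
    if len(model.chains) < 3:
        raise ValueError("chirality needs at least three chains")
    x = conf.coords - conf.coords.mean(axis=0)
    coms = np.stack([x[s].mean(axis=0) for s in model.chain_slices()[:3]])
    det = float(np.linalg.det(coms))
    norms = np.prod(np.linalg.norm(coms, axis=1))
    if norms == 0 or abs(det) < tol * max(norms, 1e-300):
        return 0
    return 1 if det > 0 else -1


def normalize_chirality(ensemble: StructureEnsemble) -> StructureEnsemble:
    """Mirror every member with Chir = −1 so the ensemble is uniformly +1.

    Mirroring reflects through a coordinate plane after centering.
    Degenerate members (Chir = 0) are left untouched with a warning.
    """
    out: list[Conformation] = []
    for c in ensemble.members:
        chir = chirality(c)
        if chir == -1:
            out.append(c.reflected(axis=2))
        else:
            if chir == 0:
                warnings.warn("degenerate chirality; structure left unmirrored",
                              stacklevel=2)
            out.append(c.copy())
    return StructureEnsemble(out)


# ---------------------------------------------------------------------------
# RMSD against the mean structure
# ---------------------------------------------------------------------------


@dataclass
class RmsdResult:
    rmsd: np.ndarray          # per-member RMSD vs the converged mean
    mean_coords: np.ndarray
    aligned: list[np.ndarray]


def ensemble_rmsd(
    ensemble: StructureEnsemble,
    max_iter: int = 64,
    tol: float = 1e-9,
) -> RmsdResult:
    """Per-structure RMSD against the iteratively superposed mean.

    All members are rigidly superposed onto the running mean, the mean is
    recomputed, and the two steps iterate to convergence (no scaling at any
    point). RMSD_j = sqrt(mean_i |r_i^(j) − ⟨r_i⟩|²). Mirror-normalize the
    ensemble first: superposition uses proper rotations only.
    """
    coords = [c - c.mean(axis=0) for c in ensemble.coords()]
    mean = coords[0].copy()
    for _ in range(max_iter):
        aligned = [superpose(mean, c) for c in coords]
        new_mean = np.mean(aligned, axis=0)
        shift = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
        mean = new_mean
        if shift < tol:
            break
    aligned = [superpose(mean, c) for c in coords]
    rmsd = np.array(
        [np.sqrt(np.mean(np.sum((a - mean) ** 2, axis=1))) for a in aligned]
    )
    return RmsdResult(rmsd, mean, aligned)


# ---------------------------------------------------------------------------
# Length distributions
# ---------------------------------------------------------------------------


@dataclass
class LengthDistributions:
    bond_lengths: np.ndarray
    contact_lengths: np.ndarray
    bond_hist: tuple[np.ndarray, np.ndarray]     # (density, edges)
    contact_hist: tuple[np.ndarray, np.ndarray]
    bond_mode: float
    contact_mode: float
    stretched_fraction: float  # contacts beyond the removal threshold


def length_distributions(
    conf: Conformation,
    bonds: np.ndarray,
    contacts: np.ndarray,
    bins: int = 60,
    stretch_threshold: float = 3.0,
) -> LengthDistributions:
    """Normalized bond/contact length histograms with modes.

    Well-minimized structures peak near the potential minima — 1.0 for
    bonds, 1.5 for contacts — with some overstretching from conflicting or
    erroneous contacts.
    """
    x = conf.coords

    def hist(pairs):
        pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
        if pairs.size == 0:
            return np.array([]), (np.array([]), np.array([])), float("nan")
        d = np.linalg.norm(x[pairs[:, 0]] - x[pairs[:, 1]], axis=1)
        dens, edges = np.histogram(d, bins=bins, density=True)
        mode = float(0.5 * (edges[np.argmax(dens)] + edges[np.argmax(dens) + 1]))
        return d, (dens, edges), mode

    bl, bh, bm = hist(bonds)
    cl, ch, cm = hist(contacts)
    frac = float(np.mean(cl > stretch_threshold)) if cl.size else float("nan")
    return LengthDistributions(bl, cl, bh, ch, bm, cm, frac)


# ---------------------------------------------------------------------------
# Contact-matrix recovery
# ---------------------------------------------------------------------------


@dataclass
class RecoveredContacts:
    fraction: float | None          # recorded / close pairs; None if no close pairs
    n_close: int
    n_recorded_close: int
    close_pairs: np.ndarray         # (K, 2) bead pairs at distance < cutoff
    triplets: np.ndarray            # (K, 3) sparse (i, j, 1) matrix entries


def recovered_contact_fraction(
    conf: Conformation,
    contacts: np.ndarray,
    cutoff: float = 3.0,
    keep: np.ndarray | None = None,
) -> RecoveredContacts:
    """Close bead pairs in the structure vs the recorded contact list.

    A close pair is any non-identical, non-bonded bead pair at distance
    strictly below ``cutoff``. The reported fraction is the share of close
    pairs that were recorded Hi-C contacts; the sparse binary matrix of
    close pairs is returned as (i, j, 1) triplets. ``keep`` restricts the
    analysis to a bead subset (e.g., after pruning).
    """
    model = conf.model
    idx = np.arange(model.n_beads) if keep is None else np.asarray(keep, dtype=int)
    x = conf.coords[idx]
    tree = cKDTree(x)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(x[pairs[:, 0]] - x[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]  # strict inequality
    gp = idx[pairs] if pairs.size else pairs.reshape(0, 2)
    gp = np.sort(gp, axis=1)
    # drop bonded neighbors (consecutive beads of one chain)
    if gp.size:
        same_chain = model.bead_chain[gp[:, 0]] == model.bead_chain[gp[:, 1]]
        adjacent = gp[:, 1] == gp[:, 0] + 1
        gp = gp[~(same_chain & adjacent)]
    recorded = {
        (int(min(i, j)), int(max(i, j)))
        for i, j in np.asarray(contacts, dtype=int).reshape(-1, 2)
    }
    n_close = len(gp)
    if n_close == 0:
        return RecoveredContacts(None, 0, 0, gp, np.empty((0, 3), dtype=int))
    n_rec = sum((int(i), int(j)) in recorded for i, j in gp)
    trip = np.column_stack([gp, np.ones(len(gp), dtype=int)])
    return RecoveredContacts(n_rec / n_close, n_close, n_rec, gp, trip)


# ---------------------------------------------------------------------------
# Radial profiles
# ---------------------------------------------------------------------------


@dataclass
class RadialProfile:
    """Track enrichment per radial shell, per structure and averaged.

    Distances are measured from each structure's center of mass and
    normalized by its radius of gyration (a per-structure convention, so
    cells of different overall size are comparable); enrichment is the mean
    track value in a shell divided by the global mean — 1 everywhere for a
    uniform track.
    """

    edges: np.ndarray            # (n_shells+1,) normalized radii
    per_structure: np.ndarray    # (n_structures, n_shells), NaN for empty shells
    mean: np.ndarray             # across-structure mean, NaN-aware

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def radial_profile(
    ensemble: StructureEnsemble,
    track: np.ndarray,
    n_shells: int = 10,
    keep: np.ndarray | None = None,
) -> RadialProfile:
    track = np.asarray(track, dtype=float)
    m0 = ensemble.members[0].model
    if track.shape != (m0.n_beads,):
        raise ValueError(
            f"track length {track.shape} does not match model bead count {m0.n_beads}"
        )
    idx = np.arange(m0.n_beads) if keep is None else np.asarray(keep, dtype=int)
    t = track[idx]
    radii = []
    for c in ensemble.members:
        x = c.coords[idx]
        x = x - x.mean(axis=0)
        r = np.linalg.norm(x, axis=1)
        rg = np.sqrt(np.mean(np.sum(x**2, axis=1)))
        radii.append(r / rg if rg > 0 else r)
    rmax = max(float(r.max()) for r in radii) if len(idx) > 1 else 1.0
    rmax = max(rmax, 1e-12)
    edges = np.linspace(0.0, rmax * (1 + 1e-12), n_shells + 1)
    gmean = t.mean() if t.size else float("nan")
    per = np.full((len(ensemble), n_shells), np.nan)
    for si, r in enumerate(radii):
        which = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_shells - 1)
        for s in range(n_shells):
            mask = which == s
            if mask.any() and gmean != 0:
                per[si, s] = t[mask].mean() / gmean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(per, axis=0)
    return RadialProfile(edges, per, mean)
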