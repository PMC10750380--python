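"""Bead-spring polymer model of interphase chromatin.

Chromosomes are coarse-grained chains of beads connected by harmonic
springs; one bead covers ``resolution`` base pairs (anywhere from 5 kbp to
5 Mbp). Single-cell Hi-C contacts are enforced as a second harmonic spring
between non-adjacent beads, and excluded volume is a *bounded* Gaussian
repulsion. Because the Gaussian is finite at ``r = 0``, chains can cross
each other during the early, soft stages of minimization — this is a
feature: it lets the structure rearrange topologically before the
potentials are ramped to their full stiffness.

All quantities are in simulation units: the preferred bond length is 1,
the preferred contact length is 1.5, and energies are in units of k_BT.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _kernels

#: Canonical homolog labels. ``None`` marks an unknown homolog.
MATERNAL = "mat"
PATERNAL = "pat"
HOMOLOG_LABELS = (MATERNAL, PATERNAL)


def default_rcut(sigma: float) -> float:
    """Excluded-volume cutoff at which the Gaussian has fallen to 1% of ε.

    Solving ``ε·exp(−½(r/σ)²) = 0.01·ε`` gives ``r = σ·√(2 ln 100)``,
    about ``3.035·σ``. Truncating there leaves a ~1% energy step at the
    cutoff; the potential is deliberately *not* shifted (the step is small
    and the truncation keeps the force field cheap and local).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return sigma * math.sqrt(2.0 * math.log(100.0))


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the three interaction potentials.

    Attributes
    ----------
    k_b, k_c:
        Bond / contact spring stiffness (energy/length²). Final-stage
        values are large (2000) so bond and contact lengths vary little.
    r0_b, r0_c:
        Preferred bond (1.0) and contact (1.5) lengths. The two differ on
        purpose: it lifts the degeneracy of the ground state, so repeated
        minimizations converge to very similar structures.
    sigma, epsilon:
        Width and scale of the Gaussian excluded volume. ε bounds the
        repulsion, permitting chain crossings; the default (10 k_BT) keeps
        overlap rare at full strength without forbidding rearrangement.
        The default width (0.65) keeps the cutoff r_cut ≈ 2.0 comparable
        to the bond length. ε must be large enough that excluded volume
        actually maintains liquid-like bead density against the
        restraint network: harmonic contacts only fix *contact* pairs, so
        at k_BT = 1 the assembly is entropically driven toward compact,
        interpenetrating states unless the soft-core pressure resists.
        With ε = 150 a contact pair at its preferred 1.5 pays ≈ 10 k_BT
        and a bonded pair ≈ 46 k_BT — bounded, so chains still cross
        while the potentials are soft — and equilibrated structures hold
        the density scale that the assignment thresholds (3.0/5.0)
        presuppose. At ε ≈ 10 reconstructions visibly collapse.
    r_cut:
        Truncation radius of the Gaussian. Defaults to ``default_rcut(sigma)``
        (the 1%-of-maximum rule).
    """

    k_b: float = 2000.0
    k_c: float = 2000.0
    r0_b: float = 1.0
    r0_c: float = 1.5
    sigma: float = 0.65
    epsilon: float = 150.0
    r_cut: float | None = None

    def __post_init__(self) -> None:
        if self.k_b < 0 or self.k_c < 0:
            raise ValueError("spring stiffnesses must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.r_cut is None:
            object.__setattr__(self, "r_cut", default_rcut(self.sigma))
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")

    def replace(self, **kwargs) -> "PotentialParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PotentialParams":
        return cls(**{k: d[k] for k in d})


def harmonic_energy(r, k: float, r0: float):
    """Harmonic bond/contact energy ``½·k·(r − r0)²``.

    Vectorized over ``r``. Negative distances are a domain error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    e = 0.5 * k * (r - r0) ** 2
    return float(e) if e.ndim == 0 else e


def harmonic_force(r, k: float, r0: float):
    """Magnitude of the restoring force, ``−dV/dr = −k·(r − r0)``."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    f = -k * (r - r0)
    return float(f) if f.ndim == 0 else f


def gaussian_ev_energy(r, params: PotentialParams):
    """Truncated Gaussian excluded-volume energy.

    ``ε·exp(−½(r/σ)²)`` for ``r < r_cut`` and exactly 0 beyond. The value
    is bounded by ε at full overlap, which is what makes chain crossing
    possible during minimization.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    e = np.where(
        r < params.r_cut,
        params.epsilon * np.exp(-0.5 * (r / params.sigma) ** 2),
        0.0,
    )
    return float(e) if e.ndim == 0 else e


# ---------------------------------------------------------------------------
# Genome representation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chain:
    """One polymer chain: a chromosome copy at a fixed resolution."""

    name: str
    homolog: str | None
    length_bp: int
    n_beads: int
    start: int  # global index of the chain's first bead

    @property
    def stop(self) -> int:
        return self.start + self.n_beads


class GenomeModel:
    """Bead-level genome at one resolution.

    Each chromosome copy is a chain of ``ceil(length / resolution)`` beads;
    bead ``k`` of a chain covers the 0-based half-open bin
    ``[k·resolution, (k+1)·resolution)``. Consecutive beads of a chain are
    bonded; there are no bonds across chains.
    """

    def __init__(self, resolution: int, chains: Sequence[Chain]):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.resolution = int(resolution)
        self.chains = tuple(chains)
        self._index = {(c.name, c.homolog): i for i, c in enumerate(self.chains)}
        if len(self._index) != len(self.chains):
            raise ValueError("duplicate (chromosome, homolog) chain")
        self.n_beads = sum(c.n_beads for c in self.chains)
        # per-bead lookup arrays
        self.bead_chain = np.empty(self.n_beads, dtype=np.int64)
        self.bead_bin = np.empty(self.n_beads, dtype=np.int64)
        for i, c in enumerate(self.chains):
            self.bead_chain[c.start : c.stop] = i
            self.bead_bin[c.start : c.stop] = np.arange(c.n_beads)

    @classmethod
    def from_chrom_sizes(
        cls,
        sizes: Mapping[str, int],
        resolution: int,
        ploidy: int = 2,
        haploid: Iterable[str] = (),
    ) -> "GenomeModel":
        """Build a (by default diploid) model from a chromosome-sizes table.

        Chromosomes named in ``haploid`` (e.g., chrX/chrY in males) get a
        single chain with no homolog label; contacts touching them are
        unambiguous on that side by construction.
        """
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        if ploidy not in (1, 2):
            raise ValueError("only haploid or diploid genomes are supported")
        haploid = set(haploid)
        chains: list[Chain] = []
        start = 0
        for name, length in sizes.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            n = -(-length // resolution)  # ceil
            labels: tuple[str | None, ...]
            if ploidy == 1 or name in haploid:
                labels = (None,)
            else:
                labels = HOMOLOG_LABELS
            for lab in labels:
                chains.append(Chain(name, lab, length, n, start))
                start += n
        return cls(resolution, chains)

    # -- lookups ----------------------------------------------------------

    def chain_index(self, name: str, homolog: str | None) -> int:
        try:
            return self._index[(name, homolog)]
        except KeyError:
            raise KeyError(f"no chain ({name!r}, {homolog!r}) in model") from None

    def has_chain(self, name: str, homolog: str | None) -> bool:
        return (name, homolog) in self._index

    def homologs_of(self, name: str) -> tuple[str | None, ...]:
        """Homolog labels present for a chromosome name."""
        labs = tuple(h for (n, h), _ in self._index.items() if n == name)
        if not labs:
            raise KeyError(f"chromosome {name!r} not in model")
        return labs

    def chrom_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.chains:
            seen.setdefault(c.name, None)
        return tuple(seen)

    def locus_to_bead(self, chrom: str, homolog: str | None, pos_bp: int) -> int:
        """Bead whose half-open bin contains ``pos_bp`` (0-based)."""
        ci = self.chain_index(chrom, homolog)
        c = self.chains[ci]
        if not (0 <= pos_bp < c.length_bp):
            raise ValueError(
                f"position {pos_bp} out of range for {chrom}({homolog}) "
                f"of length {c.length_bp}"
            )
        return c.start + int(pos_bp) // self.resolution

    def bead_start_bp(self, bead: int) -> int:
        return int(self.bead_bin[bead]) * self.resolution

    def bead_mid_bp(self, bead: int) -> float:
        c = self.chains[self.bead_chain[bead]]
        lo = self.bead_start_bp(bead)
        hi = min(lo + self.resolution, c.length_bp)
        return 0.5 * (lo + hi)

    def bonds(self) -> np.ndarray:
        """(M, 2) array of bonded bead pairs (consecutive within chains)."""
        parts = []
        for c in self.chains:
            if c.n_beads >= 2:
                idx = np.arange(c.start, c.stop - 1)
                parts.append(np.stack([idx, idx + 1], axis=1))
        if not parts:
            return np.empty((0, 2), dtype=np.int64)
        return np.concatenate(parts).astype(np.int64)

    def chain_slices(self) -> list[slice]:
        return [slice(c.start, c.stop) for c in self.chains]

    def same_model(self, other: "GenomeModel") -> bool:
        return (
            self.resolution == other.resolution
            and self.chains == other.chains
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenomeModel(resolution={self.resolution}, "
            f"chains={len(self.chains)}, beads={self.n_beads})"
        )


@dataclass
class Conformation:
    """3D coordinates for every bead of a :class:`GenomeModel`."""

    model: GenomeModel
    coords: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.model.n_beads, 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match "
                f"model bead count {self.model.n_beads}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def copy(self) -> "Conformation":
        return Conformation(self.model, self.coords.copy(), dict(self.provenance))

    def centered(self) -> "Conformation":
        c = self.copy()
        c.coords -= c.coords.mean(axis=0)
        return c

    def reflected(self, axis: int = 2) -> "Conformation":
        """Mirror image through the coordinate plane normal to ``axis``,
        after centering at the center of mass."""
        c = self.copy()
        com = c.coords.mean(axis=0)
        c.coords -= com
        c.coords[:, axis] *= -1.0
        return c


# ---------------------------------------------------------------------------
# Total energy
# ---------------------------------------------------------------------------


def _check_pairs(pairs: np.ndarray, n: int, what: str) -> np.ndarray:
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs.size and (pairs.min() < 0 or pairs.max() >= n):
        raise IndexError(f"{what} reference bead indices outside [0, {n})")
    return pairs


def total_energy(
    conf: Conformation | np.ndarray,
    bonds: np.ndarray,
    contacts: np.ndarray,
    params: PotentialParams,
    method: str = "cell",
) -> float:
    """Total potential energy: bonds + contacts + truncated-Gaussian EV.

    ``method='cell'`` uses a cell-list neighbor search (cell size ≥ r_cut);
    ``method='brute'`` is the O(N²) reference sum. The two are contractually
    identical (not merely close): the cell list enumerates exactly the pairs
    within the cutoff. The energy depends only on pairwise distances, so it
    is invariant under rigid motions and reflections.
    """
    x = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = x.shape[0]
    bonds = _check_pairs(bonds, n, "bonds")
    contacts = _check_pairs(contacts, n, "contacts")
    e = 0.0
    if bonds.size:
        d = np.linalg.norm(x[bonds[:, 0]] - x[bonds[:, 1]], axis=1)
        e += float(np.sum(harmonic_energy(d, params.k_b, params.r0_b)))
    if contacts.size:
        d = np.linalg.norm(x[contacts[:, 0]] - x[contacts[:, 1]], axis=1)
        e += float(np.sum(harmonic_energy(d, params.k_c, params.r0_c)))
    if params.epsilon > 0 and n > 1:
        f = np.zeros_like(x)
        if method == "brute":
            e += _kernels.ev_brute(x, params.epsilon, params.sigma, params.r_cut, f)
        elif method == "cell":
            e += _kernels.ev_auto(x, params.epsilon, params.sigma, params.r_cut, f)
        else:
            raise ValueError(f"unknown method {method!r}")
    return e


def forces(
    x: np.ndarray,
    bonds: np.ndarray,
    contacts: np.ndarray,
    params: PotentialParams,
) -> tuple[np.ndarray, float]:
    """Forces ``−∇V`` and total potential energy for the integrator."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    n = x.shape[0]
    bonds = _check_pairs(bonds, n, "bonds")
    contacts = _check_pairs(contacts, n, "contacts")
    f = np.zeros_like(x)
    e = _kernels.harmonic_pairs(x, bonds, params.k_b, params.r0_b, f)
    e += _kernels.harmonic_pairs(x, contacts, params.k_c, params.r0_c, f)
    if params.epsilon > 0 and n > 1:
        e += _kernels.ev_auto(x, params.epsilon, params.sigma, params.r_cut, f)
    return f, e
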