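# Methods

## The model

Chromatin is represented as coarse-grained bead-spring polymers: one chain
per chromosome copy, one bead per `resolution` base pairs (5 kbp–5 Mbp).
Three interactions act between beads, all in simulation units (length unit
= preferred bond length, energy unit = k_BT):

* **Bonds** between consecutive beads of a chain: harmonic,
  `V = ½·k_b·(r − r0_b)²` with `r0_b = 1`.
* **Contacts**: the same harmonic form between the two beads containing the
  loci of a recorded single-cell Hi-C contact, with `r0_c = 1.5`. The
  offset between `r0_b` and `r0_c` lifts ground-state degeneracy, so
  repeated minimizations converge to similar structures. Final stiffnesses
  are large, `k_b = k_c = 2000`, so bond and contact lengths vary little.
* **Excluded volume**: a truncated Gaussian,
  `V = ε·exp(−½(r/σ)²)` for `r < r_cut`, exactly 0 beyond. The cutoff
  follows the 1%-of-maximum rule, `r_cut = σ·√(2·ln 100) ≈ 3.035·σ`; the
  ~1% step at the cutoff is intentional (plain truncation, no shift).
  Because the potential is bounded by ε, chains can cross while the
  potentials are soft — the mechanism by which the topology rearranges
  during minimization.

There are no attractive nonbonded terms, no bending stiffness, no
topological constraints and no confinement; minimizations are
unconstrained.

### Choice of σ and ε

σ and ε are free parameters of the model. Defaults: `σ = 0.65`
(`r_cut ≈ 1.97`, comparable to the bond length) and `ε = 150`.

ε deserves explanation. Harmonic contacts constrain only the *recorded*
pairs; nothing in the restraint network keeps non-contact pairs apart. At
k_BT = 1 the ensemble of restraint-satisfying configurations is therefore
entropically dominated by compact, interpenetrating states, and only the
soft-core pressure resists this. With ε near 10 the effect is dramatic: a
600-bead diploid test system collapses to roughly half its true linear
size, at which point the absolute assignment thresholds (3.0/5.0 below)
lose their meaning because almost every candidate distance falls below
them. ε = 150 holds equilibrated structures at liquid-like bead density
(≈0.5 beads per unit volume) while remaining bounded: a contact pair at
1.5 pays ≈ 10 k_BT of overlap energy and a bonded pair ≈ 46 k_BT, and
crossings still occur freely in the soft early stages. Both parameters are
exposed in `PotentialParams`.

## Staged minimization

One run: beads are placed uniformly at random in a cube of side 10, bonds
alone are equilibrated, then contacts and excluded volume are ramped up in
five stages to their final values, with a final hold at full strength. The
default ramp is geometric in the contact stiffness,
`k_c ∈ {0.2, 2, 20, 200, 2000}`, and linear in σ and ε. Only the
endpoints are physically prescribed; the intermediates must merely be
smooth. Two numerical observations fixed the defaults:

* starting the contact ramp *very* soft (0.2, four decades below the final
  value) lets the large-scale topology sort itself out while chains still
  cross; a steeper ramp (starting at 2) degrades the reproducibility of
  independent runs from RMSD ≈ 0.6 to ≈ 1.6 on a 300-bead globule;
* ε must ramp together with σ — full excluded volume applied while the
  fold is still organizing blocks the necessary chain crossings and traps
  chains in wrong folds.

The integrator is a BAOAB-splitting Langevin scheme with the thermostat at
γ = 1, k_BT = 1, dt = 0.001 and unit bead mass. Trajectories are bitwise
reproducible from the seed (noise comes from a seeded numpy generator).
Default stage lengths are 5 000 steps of bond equilibration, 8 000 per ramp
stage and 15 000 of final hold (a "quick" schedule with 3 000/4 000/8 000
exists for small systems); these are solver settings sized for desk-scale
systems of hundreds of beads, chosen so that energy traces and bond-length
statistics stop changing, and are configurable for larger systems.
Independent conformations can be generated by resetting bond and contact
potentials to zero, letting the structure collapse into a coil, and
rerunning the ramp with a new seed.

## Contact mapping

Bins are 0-based and half-open: bead `k` covers `[k·res, (k+1)·res)`, so
every bp position maps to exactly one bead. When mapping a contact list
onto beads: same-bead contacts are omitted (they become informative again
at higher resolution), bonded-neighbor contacts are omitted, and duplicate
bead pairs collapse into one restraint — multiplicities are recorded but
never scale `k_c`, so the contact amplitude is independent of read count.
Two homolog naming dialects are parsed (`chr1(mat)/(pat)` and
`chr1a/chr1b`); chromosomes without a homologous partner (haploid, e.g.,
male chrX) are unambiguous by construction.

## Progressive homolog assignment

A contact between homologous-pair chromosomes has up to four candidate
assignments. The protocol starts at a coarse resolution using only
unambiguous contacts, then at each resolution: map → minimize → remove
stretched → assign.

* **Assignment rule** (hard two-threshold test, no likelihood weights): an
  unassigned contact is assigned to an option iff that option's bead
  distance in the minimized structure is < 3.0 *and* every other option
  exceeds 5.0. Distances are measured on the final minimized structure of
  the iteration, not time-averaged.
* **Removal rule**: any *used* contact whose distance ends up > 3.0 is
  dropped for the next run — even an originally unambiguous one — and its
  assignment is not saved. Removal is per-iteration: the contact may be
  assigned again later by the same rule.
* **Merge**: to go beyond the resolution one series supports, several
  independent series run from different seeds and their assignments are
  merged. A contact assigned to the same option in every series that
  assigned it is kept (a single supporting series suffices; quorum is a
  config option), conflicting assignments are discarded, never-assigned
  contacts stay unassigned.

The default full-genome plan is 5 Mbp → 20 kbp in eight steps, a 10-run
merge, then 20/10/5 kbp; a sparse-data variant starts at 500 kbp, ends at
20 kbp and skips the merge; the desk-scale plan used throughout the tests
is (100 kbp, 50 kbp, 20 kbp) with no merge. Each resolution starts fresh
from the cube by default; interpolation seeding from the previous
structure (children placed at their parent bead, jittered) is available
behind a config flag. A diagnostic warns when the initial resolution has
fewer than about one unambiguous contact per bead.

## Post-processing

* **Edge pruning**: per bead, contact endpoints within ±0.5 Mbp of the
  bead's bin midpoint on the same chain are counted; the `floor(0.06·N)`
  beads with the lowest counts are removed (stable tie-break by bead
  index). The genomic window semantics and the endpoint-counting choice
  are configurable.
* **Chirality**: the sign of the determinant of the first three chains'
  centers of mass after centering the structure. Contact lists cannot
  distinguish mirror images, so ensembles are normalized to chirality +1
  by reflecting members with −1. Caveat: for a genome with *exactly* three
  chains the centered centers are linearly dependent and the indicator is
  identically degenerate; such ensembles fall back to mirror resolution by
  RMSD (`pairwise_rmsd(..., mirror=True)`).
* **RMSD**: members are iteratively superposed onto the running mean
  (proper rotations only, never scaled, never reflected), the mean is
  recomputed, and per-member RMSD is evaluated against the converged mean.
* **Length distributions**: normalized histograms of bond and contact
  lengths with their modes; well-minimized structures peak near 1.0 and
  1.5.
* **Contact recovery**: all non-bonded bead pairs at distance < 3.0 are
  "close"; the recovered fraction is the share of close pairs that were
  recorded contacts; the close-pair set is exported as a sparse binary
  matrix.
* **Radial profiles**: per structure, bead distances from the center of
  mass are normalized by the radius of gyration (a per-structure
  convention); a genomic track's enrichment per radial shell is its shell
  mean divided by the global mean, so a uniform track gives 1 everywhere.

## The synthetic test system

The fixture generator produces a small diploid genome (default: two pairs,
3.6 + 2.4 Mbp, 20 kbp resolution → four chains of 180/120 beads) with a
known conformation, from which everything else derives.

Ground truth: each chain starts as a unit-step random walk confined to its
territory sphere (adjacent spheres touching so territories tile space and
interfaces produce inter-chromosomal contacts; homologous copies on
distinct vertices), is relaxed under the model's own bond and
excluded-volume potentials with a generator-only confinement wall, and is
then annealed twice under the contact set implied by its own geometry with
the wall removed. The two anneal passes make the truth a thermal state of
the reconstruction model under restraints its own geometry implies — a
structure the pipeline can in principle recover exactly (up to rigid
motion and mirror). Without this self-consistency step the truth is not a
realizable state of the restraint system and recovery RMSD is bounded
below by about 2 bead diameters. The territory density default
(0.5 beads/unit³) is the model's own equilibrium density at the default
potentials, so truth and reconstruction share a scale.

Contacts: every non-bonded bead pair within the cutoff (default 2.0)
becomes a candidate contact, with bp positions drawn uniformly inside the
bins (exercising the rounding paths), kept with probability `subsample`
(default 1.0 — the spurious-removal test emulates a data-rich regime of
several restraints per bead) and stripped of both homolog labels with
probability `ambiguity` (default 0.25, so ~75% of contacts are usable
as-is, matching a haplotype-imputed single-cell data set). Spurious
contacts are `round(fraction·n)` uniformly random locus pairs, unphased by
default — they model random ligation noise, which carries no reliable
haplotype information — and internally tagged for scoring only.

Tracks: a per-bin scalar (CpG-density stand-in) decreasing outward
(`central`), increasing outward (`inverted`, the rod-photoreceptor
arrangement) or constant (`uniform`); homologous copies share one value,
as a sequence-derived track would.

## What the tests show, and what they do not

The spurious-elimination experiment (four chains, 5% unphased spurious
contacts, three-resolution ladder, five seeds) eliminates 85–93% of the
injected contacts, essentially all through the assignment gate: a random
pair rarely has exactly one option below 3.0 with all others beyond 5.0.
Real unambiguous contacts are retained and a growing number of real
ambiguous contacts is assigned as resolution increases.

Known desk-scale limitations, stated plainly:

* *Phased* spurious contacts (injected with `ambiguity < 1`) largely
  evade elimination in a four-chain system: with so few territories, all
  pairs can be mutually adjacent and the minimizer accommodates random
  bridges instead of leaving them stretched beyond 3.0. The geometric
  frustration that defeats random bridges in a 46-chromosome nucleus has
  no desk-scale analogue; consequently `remove_stretched` rarely fires on
  the default fixtures (it is exercised by unit tests with constructed
  geometries).
* The fixture emulates territory packing, homolog ambiguity, subsampling
  and uniform spurious noise — not distance-dependent contact frequency,
  coverage biases, or any other realistic Hi-C noise structure.
* Absolute thresholds (3.0/5.0) presuppose structures at liquid-like bead
  density; systems much smaller than ~100 beads per chain leave little
  headroom between typical distances and the 5.0 rejection bound, which is
  why assignment activity concentrates at the finest ladder level.

Ground-truth recovery is verified on a three-chain mixed globule with
dense unambiguous contacts: among five independent minimizations the
lowest-energy structure matches the truth within one bead diameter after
mirror resolution (final energy cleanly ranks annealing basins, and
selecting structures by energy is standard practice for this kind of
protocol). Bond/contact length modes on that reconstruction fall within
[0.9, 1.1] and [1.35, 1.65].

## Numerical details

* Cell-list neighbor search with cell size = `r_cut`, falling back to the
  O(N²) loop for small or spatially sparse systems; the two are exactly
  equivalent (same pair set; equality to 1e-10 relative is asserted over
  random instances).
* Energies and forces are invariant under rigid motion and reflection to
  floating precision; forces match central differences to ~1e-6 relative.
* Divergence (any non-finite coordinate) aborts a stage with the stage
  label and step index.
* Degenerate inputs: empty contact lists are an error in the ladder (a
  resolution with zero usable contacts cannot be minimized meaningfully);
  zero close pairs make the recovered-contact fraction "not applicable"
  (`None`); chirality 0 structures are skipped by mirror normalization
  with a warning.
* Pruning ties are broken by bead index (stable argsort), and a warning is
  emitted when all counts are equal.
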