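"""Contact-list and structure I/O, and bp→bead mapping.

Input contacts are pairs-like TSV (two genomic loci per line). Homolog
information, when present, rides on the chromosome names — either
``chr1(mat)``/``chr1(pat)`` suffixes or ``chr1a``/``chr1b`` — or sits in a
dedicated column of the 6-column dialect. Bins are 0-based half-open:
bead ``k`` covers ``[k·res, (k+1)·res)``.

When contacts are mapped onto beads at a resolution, three omission rules
apply: a contact whose two loci fall in the same bead is dropped (it can
become informative again at a higher resolution), a contact between beads
already joined by a bond is dropped, and duplicate bead pairs collapse to
one restraint — the contact potential amplitude is fixed regardless of how
many reads support a pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Conformation, GenomeModel, HOMOLOG_LABELS, MATERNAL, PATERNAL


class ContactParseError(ValueError):
    """Raised for unresolvable contact-list content (unknown chromosomes)."""


_LABEL_ALIASES = {
    "mat": MATERNAL, "maternal": MATERNAL, "m": MATERNAL, "a": MATERNAL,
    "pat": PATERNAL, "paternal": PATERNAL, "p": PATERNAL, "b": PATERNAL,
    ".": None, "?": None, "u": None, "unknown": None, "": None,
}


def _endpoint_key(chrom: str, pos: int, homol: str | None):
    return (chrom, int(pos), homol if homol is not None else "~")


@dataclass(frozen=True)
class ContactRecord:
    """One Hi-C contact: two genomic loci with optional homolog labels.

    ``(A, B)`` and ``(B, A)`` denote the same physical contact; records are
    stored with endpoints in canonical order. A record with both labels
    known (or on haploid chromosomes) is unambiguous; one unknown side on a
    homologous pair gives 2 candidate assignments, two unknown sides up to 4.
    """

    chrom_a: str
    pos_a: int
    homol_a: str | None
    chrom_b: str
    pos_b: int
    homol_b: str | None
    multiplicity: int = 1

    def __post_init__(self):
        if self.homol_a not in (None, *HOMOLOG_LABELS):
            raise ValueError(f"bad homolog label {self.homol_a!r}")
        if self.homol_b not in (None, *HOMOLOG_LABELS):
            raise ValueError(f"bad homolog label {self.homol_b!r}")

    def canonical(self) -> "ContactRecord":
        a = _endpoint_key(self.chrom_a, self.pos_a, self.homol_a)
        b = _endpoint_key(self.chrom_b, self.pos_b, self.homol_b)
        if b < a:
            return ContactRecord(
                self.chrom_b, self.pos_b, self.homol_b,
                self.chrom_a, self.pos_a, self.homol_a, self.multiplicity,
            )
        return self

    @property
    def key(self):
        """Canonical identity (ignores multiplicity)."""
        c = self.canonical()
        return (
            _endpoint_key(c.chrom_a, c.pos_a, c.homol_a),
            _endpoint_key(c.chrom_b, c.pos_b, c.homol_b),
        )

    def with_homologs(self, homol_a, homol_b) -> "ContactRecord":
        return replace(self, homol_a=homol_a, homol_b=homol_b)


@dataclass(frozen=True)
class BeadContact:
    """A deduplicated bead-level contact restraint.

    ``multiplicity`` counts the underlying records but never scales the
    contact stiffness.
    """

    bead_i: int
    bead_j: int
    multiplicity: int = 1

    def __post_init__(self):
        if self.bead_i >= self.bead_j:
            raise ValueError("bead_i must be < bead_j")


def read_chrom_sizes(path) -> dict[str, int]:
    """2-column TSV (name, length in bp) → ordered mapping."""
    sizes: dict[str, int] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: expected 'name<TAB>length'")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    Path(path).write_text(
        "".join(f"{n}\t{l}\n" for n, l in sizes.items())
    )


def parse_chrom_token(token: str, known: Iterable[str]):
    """Split a chromosome token into (name, homolog label or None).

    Accepts ``chr1``, ``chr1(mat)``, ``chr1(pat)`` and — when the bare name
    exists in the genome table and the full token does not — the ``chr1a`` /
    ``chr1b`` convention.
    """
    known = set(known)
    if token in known:
        return token, None
    if token.endswith(")") and "(" in token:
        name, _, suf = token[:-1].rpartition("(")
        lab = _LABEL_ALIASES.get(suf.lower())
        if name in known and (suf.lower() in _LABEL_ALIASES):
            return name, lab
    if len(token) > 1 and token[-1] in ("a", "b") and token[:-1] in known:
        return token[:-1], _LABEL_ALIASES[token[-1]]
    raise ContactParseError(f"unknown chromosome {token!r}")


def canonicalize(records: Iterable[ContactRecord]) -> list[ContactRecord]:
    """Canonical endpoint order, duplicates merged (multiplicity summed),
    deterministic sort. Idempotent."""
    merged: dict = {}
    for r in records:
        c = r.canonical()
        prev = merged.get(c.key)
        if prev is None:
            merged[c.key] = c
        else:
            merged[c.key] = replace(prev, multiplicity=prev.multiplicity + c.multiplicity)
    return [merged[k] for k in sorted(merged)]


def _parse_label(tok: str):
    t = tok.lower()
    if t in _LABEL_ALIASES:
        return _LABEL_ALIASES[t]
    raise ContactParseError(f"unknown homolog label {tok!r}")


def read_contacts(path, sizes: Mapping[str, int], dialect: str = "auto") -> list[ContactRecord]:
    """Parse a contact list into canonical :class:`ContactRecord` s.

    Dialects: ``pairs`` — ``chromA posA chromB posB`` with optional homolog
    suffixes on the chromosome names (a 4DN ``.pairs`` header and a leading
    read-ID column are tolerated; extra columns ignored); ``sixcol`` —
    ``chromA posA homolA chromB posB homolB``. ``auto`` sniffs per line.
    Malformed lines are skipped with a warning listing line numbers; unknown
    chromosome names are a hard error listing all offenders.
    """
    known = set(sizes)
    records: list[ContactRecord] = []
    bad_lines: list[int] = []
    unknown: dict[str, int] = {}

    def endpoint(chrom_tok: str, pos_tok: str):
        name, lab = parse_chrom_token(chrom_tok, known)
        pos = int(pos_tok)
        if not (0 <= pos < sizes[name]):
            raise ValueError(f"position {pos} outside {name}")
        return name, pos, lab

    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        try:
            if dialect == "sixcol" or (
                dialect == "auto"
                and len(parts) >= 6
                and parts[2].lower() in _LABEL_ALIASES
                and parts[5].lower() in _LABEL_ALIASES
            ):
                ca, pa, ha = parts[0], parts[1], _parse_label(parts[2])
                cb, pb, hb = parts[3], parts[4], _parse_label(parts[5])
                na, qa, sa = endpoint(ca, pa)
                nb, qb, sb = endpoint(cb, pb)
                ha = sa if sa is not None else ha
                hb = sb if sb is not None else hb
            else:
                # pairs-like; tolerate a leading read-ID column
                off = 0
                if (
                    len(parts) >= 5
                    and not _is_chromish(parts[0], known)
                    and _is_chromish(parts[1], known)
                ):
                    off = 1
                if len(parts) - off < 4:
                    raise ValueError("too few columns")
                na, qa, ha = endpoint(parts[off], parts[off + 1])
                nb, qb, hb = endpoint(parts[off + 2], parts[off + 3])
            records.append(ContactRecord(na, qa, ha, nb, qb, hb))
        except ContactParseError as err:
            tok = str(err).split("'")[1] if "'" in str(err) else str(err)
            unknown[tok] = ln
        except (ValueError, IndexError):
            bad_lines.append(ln)
    if unknown:
        offenders = ", ".join(f"{t!r} (line {ln})" for t, ln in unknown.items())
        raise ContactParseError(
            f"{path}: chromosome names absent from the genome table: {offenders}"
        )
    if bad_lines:
        warnings.warn(
            f"{path}: skipped {len(bad_lines)} malformed line(s): "
            + ", ".join(map(str, bad_lines[:20])),
            stacklevel=2,
        )
    return canonicalize(records)


def _is_chromish(token: str, known) -> bool:
    try:
        parse_chrom_token(token, known)
        return True
    except ContactParseError:
        return False


def write_contacts(records: Sequence[ContactRecord], path) -> None:
    """6-column dialect plus a multiplicity column (ignored on read)."""
    with open(path, "w") as fh:
        fh.write("#chromA\tposA\thomolA\tchromB\tposB\thomolB\tmultiplicity\n")
        for r in records:
            fh.write(
                f"{r.chrom_a}\t{r.pos_a}\t{r.homol_a or '.'}\t"
                f"{r.chrom_b}\t{r.pos_b}\t{r.homol_b or '.'}\t{r.multiplicity}\n"
            )


# ---------------------------------------------------------------------------
# bp → bead mapping
# ---------------------------------------------------------------------------


def locus_to_bead(chrom: str, homolog: str | None, pos_bp: int, model: GenomeModel) -> int:
    """Bead whose half-open bin contains ``pos_bp``. Total and deterministic."""
    return model.locus_to_bead(chrom, homolog, pos_bp)


def is_concrete(record: ContactRecord, model: GenomeModel) -> bool:
    """True when both endpoints resolve to a unique chain of ``model``."""
    for chrom, hom in ((record.chrom_a, record.homol_a), (record.chrom_b, record.homol_b)):
        if hom is None and not model.has_chain(chrom, None):
            return False
    return True


@dataclass
class BeadContactSet:
    """Bead-level restraints plus the bookkeeping of the omission rules."""

    contacts: list[BeadContact] = field(default_factory=list)
    n_ambiguous_skipped: int = 0
    n_same_bead: int = 0
    n_bonded: int = 0
    n_duplicate: int = 0

    def pair_array(self) -> np.ndarray:
        if not self.contacts:
            return np.empty((0, 2), dtype=np.int64)
        return np.array([(c.bead_i, c.bead_j) for c in self.contacts], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.contacts)


def build_bead_contacts(records: Sequence[ContactRecord], model: GenomeModel) -> BeadContactSet:
    """Map concrete records to deduplicated bead pairs.

    Same-bead and bonded-neighbor pairs are omitted (the underlying record
    keeps its bp data and may re-enter at a higher resolution); records
    still ambiguous are skipped and counted.
    """
    out = BeadContactSet()
    seen: dict[tuple[int, int], int] = {}
    for r in records:
        if not is_concrete(r, model):
            out.n_ambiguous_skipped += 1
            continue
        i = model.locus_to_bead(r.chrom_a, r.homol_a, r.pos_a)
        j = model.locus_to_bead(r.chrom_b, r.homol_b, r.pos_b)
        if i == j:
            out.n_same_bead += 1
            continue
        if i > j:
            i, j = j, i
        if model.bead_chain[i] == model.bead_chain[j] and j == i + 1:
            out.n_bonded += 1
            continue
        if (i, j) in seen:
            out.n_duplicate += 1
            k = seen[(i, j)]
            c = out.contacts[k]
            out.contacts[k] = BeadContact(c.bead_i, c.bead_j, c.multiplicity + r.multiplicity)
        else:
            seen[(i, j)] = len(out.contacts)
            out.contacts.append(BeadContact(i, j, r.multiplicity))
    return out


# ---------------------------------------------------------------------------
# Structure files
# ---------------------------------------------------------------------------


def write_structure(
    conf: Conformation,
    path,
    format: str = "3dg",
    keep: np.ndarray | None = None,
    notes: Mapping | None = None,
) -> None:
    """Write a structure as a .3dg-style TSV or an approximate PDB.

    The TSV has one line per bead: chromosome, homolog, bin start (bp),
    x, y, z — with provenance in ``#`` header lines. ``keep`` restricts the
    output to a subset of beads (e.g., after edge pruning); the header then
    notes the filter. The PDB export is approximate by design: beads are
    not atoms, chains map to chromosome copies, coordinates are scaled as-is.
    """
    model = conf.model
    idx = np.arange(model.n_beads) if keep is None else np.asarray(keep, dtype=int)
    if format == "3dg":
        with open(path, "w") as fh:
            meta = {"resolution": model.resolution, **(dict(notes) if notes else {})}
            if conf.provenance:
                meta.update(conf.provenance)
            if keep is not None:
                meta["filtered_beads"] = int(model.n_beads - len(idx))
            fh.write("#diplochrom 3dg " + json.dumps(meta, default=str) + "\n")
            for b in idx:
                c = model.chains[model.bead_chain[b]]
                x, y, z = conf.coords[b]
                fh.write(
                    f"{c.name}\t{c.homolog or '.'}\t{model.bead_start_bp(b)}\t"
                    f"{x:.6f}\t{y:.6f}\t{z:.6f}\n"
                )
    elif format == "pdb":
        with open(path, "w") as fh:
            fh.write("REMARK   approximate bead export: beads are not atoms\n")
            serial = 0
            for ci, c in enumerate(model.chains):
                chain_id = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789"[ci % 36]
                for b in idx:
                    if model.bead_chain[b] != ci:
                        continue
                    serial += 1
                    x, y, z = conf.coords[b]
                    fh.write(
                        f"HETATM{serial % 100000:5d}  C   BEA {chain_id}"
                        f"{(int(model.bead_bin[b]) + 1) % 10000:4d}    "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                    )
                fh.write("TER\n")
            fh.write("END\n")
    else:
        raise ValueError(f"unknown structure format {format!r}")


def read_structure(path, model: GenomeModel) -> tuple[Conformation, np.ndarray]:
    """Read a .3dg-style TSV written by :func:`write_structure`.

    Returns the conformation plus the array of bead indices present in the
    file (pruned files cover a subset; absent beads get NaN-free zeros and
    are excluded from the index array).
    """
    coords = np.zeros((model.n_beads, 3))
    present: list[int] = []
    prov: dict = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "3dg" in line and "{" in line:
                try:
                    prov = json.loads(line[line.index("{"):])
                except json.JSONDecodeError:
                    pass
            continue
        chrom, hom, start, x, y, z = line.split("\t")
        b = model.locus_to_bead(chrom, None if hom == "." else hom, int(start))
        coords[b] = (float(x), float(y), float(z))
        present.append(b)
    conf = Conformation(model, coords, prov)
    return conf, np.array(sorted(present), dtype=int)


def write_bead_contacts(cset: BeadContactSet, path) -> None:
    pd.DataFrame(
        [(c.bead_i, c.bead_j, c.multiplicity) for c in cset.contacts],
        columns=["bead_i", "bead_j", "multiplicity"],
    ).to_csv(path, sep="\t", index=False)


def read_track(path, model: GenomeModel) -> np.ndarray:
    """bedGraph-style TSV (chrom, start, end, value) → per-bead values.

    The value of a bin applies to both homologs of its chromosome. Bins must
    align with the model's bead bins; a bead not covered gets 0.
    """
    vals = np.zeros(model.n_beads)
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, _end, value = line.split()[:4]
        for hom in model.homologs_of(chrom):
            b = model.locus_to_bead(chrom, hom, int(start))
            vals[b] = float(value)
    return vals


def write_track(model: GenomeModel, values: np.ndarray, path) -> None:
    """Write one bedGraph line per bin of the first homolog of each chromosome."""
    with open(path, "w") as fh:
        done = set()
        for b in range(model.n_beads):
            c = model.chains[model.bead_chain[b]]
            lo = model.bead_start_bp(b)
            key = (c.name, lo)
            if key in done:
                continue
            done.add(key)
            hi = min(lo + model.resolution, c.length_bp)
            fh.write(f"{c.name}\t{lo}\t{hi}\t{values[b]:.6g}\n")
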