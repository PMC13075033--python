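"""Data model and file I/O for polyploid codominant genotypes.

A panel couples SSR loci, scored as multisets of fragment sizes (bp) with at
most ``ploidy`` entries per accession, with one optional multiallelic S-locus
scored as a set of allele labels (e.g. ``S1``, ``S36b2``).  Allele dosage in a
tetraploid electropherogram is ambiguous, so cells hold the distinct alleles
that were observed; nothing here imputes copy number.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Optional, Sequence

__all__ = [
    "GenotypeError",
    "LocusDef",
    "AccessionGenotype",
    "GenotypeTable",
    "GroupAssignment",
    "Diagnostic",
    "read_genotypes",
    "write_genotypes",
    "validate",
]

SSR = "ssr"
S_LOCUS = "s_locus"


class GenotypeError(ValueError):
    """Raised for malformed genotype tables or files."""


@dataclass(frozen=True)
class LocusDef:
    """Definition of one marker locus.

    ``repeat_unit`` (bp) is required for SSR loci: it is the divisor that
    converts a fragment-size difference into repeat units for stepwise
    distance models.  The S-locus has no repeat structure and no unit.
    """

    name: str
    marker_type: str = SSR
    repeat_unit: Optional[int] = None
    size_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.marker_type not in (SSR, S_LOCUS):
            raise GenotypeError(f"unknown marker_type {self.marker_type!r}")
        if self.marker_type == SSR:
            if self.repeat_unit is None or self.repeat_unit < 1:
                raise GenotypeError(
                    f"locus {self.name!r}: SSR loci need repeat_unit >= 1"
                )
        elif self.repeat_unit is not None:
            raise GenotypeError(f"locus {self.name!r}: s_locus has no repeat_unit")
        if self.size_range is not None and self.size_range[0] > self.size_range[1]:
            raise GenotypeError(f"locus {self.name!r}: inverted size_range")


@dataclass(frozen=True)
class AccessionGenotype:
    """One accession's multilocus genotype.

    ``ssr_alleles`` maps locus name to a sorted tuple of fragment sizes;
    a locus absent from the map is missing (failed amplification).
    ``s_alleles`` is the set of S-allele labels; ``None`` when untyped.
    """

    accession_id: str
    group: Optional[str] = None
    ssr_alleles: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    s_alleles: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        norm = {loc: tuple(sorted(cell)) for loc, cell in self.ssr_alleles.items()}
        object.__setattr__(self, "ssr_alleles", norm)
        if self.s_alleles is not None:
            object.__setattr__(self, "s_alleles", frozenset(self.s_alleles))


@dataclass(frozen=True)
class GenotypeTable:
    """An ordered panel of accessions typed at an ordered list of loci."""

    loci: tuple[LocusDef, ...]
    accessions: tuple[AccessionGenotype, ...]
    ploidy: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "loci", tuple(self.loci))
        object.__setattr__(self, "accessions", tuple(self.accessions))
        if not self.loci or not self.accessions:
            raise GenotypeError("table needs at least one locus and one accession")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise GenotypeError("duplicate locus names")
        if sum(1 for l in self.loci if l.marker_type == S_LOCUS) > 1:
            raise GenotypeError("at most one s_locus per panel")
        ids = [a.accession_id for a in self.accessions]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise GenotypeError(f"duplicate accession id(s): {sorted(dupes)}")
        ssr_names = {l.name for l in self.loci if l.marker_type == SSR}
        for acc in self.accessions:
            for loc, cell in acc.ssr_alleles.items():
                if loc not in ssr_names:
                    raise GenotypeError(
                        f"accession {acc.accession_id!r} references undeclared locus {loc!r}"
                    )
                if not cell:
                    raise GenotypeError(
                        f"accession {acc.accession_id!r}, locus {loc!r}: empty cell "
                        "must be encoded as a missing locus"
                    )
                if len(cell) > self.ploidy:
                    raise GenotypeError(
                        f"ploidy exceeded: accession {acc.accession_id!r}, locus "
                        f"{loc!r} has {len(cell)} alleles (ploidy {self.ploidy})"
                    )
            if acc.s_alleles is not None:
                if not acc.s_alleles:
                    raise GenotypeError(
                        f"accession {acc.accession_id!r}: empty S-allele set"
                    )
                if len(acc.s_alleles) > self.ploidy:
                    raise GenotypeError(
                        f"ploidy exceeded: accession {acc.accession_id!r} carries "
                        f"{len(acc.s_alleles)} S-alleles (ploidy {self.ploidy})"
                    )

    # -- convenience accessors -------------------------------------------------
    @property
    def accession_ids(self) -> tuple[str, ...]:
        return tuple(a.accession_id for a in self.accessions)

    @property
    def ssr_loci(self) -> tuple[LocusDef, ...]:
        return tuple(l for l in self.loci if l.marker_type == SSR)

    @property
    def s_locus(self) -> Optional[LocusDef]:
        for l in self.loci:
            if l.marker_type == S_LOCUS:
                return l
        return None

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def __iter__(self) -> Iterator[AccessionGenotype]:
        return iter(self.accessions)

    def __len__(self) -> int:
        return len(self.accessions)


@dataclass(frozen=True)
class GroupAssignment:
    """Map accession id -> group label."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))
        if not self.assignments:
            raise GenotypeError("empty group assignment")

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g, None)
        return tuple(seen)

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(i for i, g in self.assignments.items() if g == group)

    def validate_against(self, table: GenotypeTable) -> None:
        known = set(table.accession_ids)
        unknown = sorted(set(self.assignments) - known)
        if unknown:
            raise GenotypeError(f"group assignment for unknown accession(s): {unknown}")

    @classmethod
    def from_table(cls, table: GenotypeTable) -> "GroupAssignment":
        pairs = {a.accession_id: a.group for a in table if a.group is not None}
        if not pairs:
            raise GenotypeError("no group labels present in table")
        return cls(pairs)

    @classmethod
    def from_csv(cls, path) -> "GroupAssignment":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls({r["accession"]: r["group"] for r in rows})

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["accession", "group"])
            for acc, grp in self.assignments.items():
                w.writerow([acc, grp])


@dataclass(frozen=True)
class Diagnostic:
    """A non-fatal validation finding."""

    kind: str  # dosage_or_null | size_range | missing_locus | small_group
    accession: Optional[str]
    locus: Optional[str]
    message: str


# ---------------------------------------------------------------------------
# file I/O
#
# Genotype CSV dialect: header
#   accession,group,<locus>.1,...,<locus>.<ploidy>,...,<s_locus_name>
# one row per accession; blank SSR sub-columns mean fewer than ploidy alleles
# observed; the S cell is slash-separated labels.  Locus metadata CSV:
#   locus,marker_type,repeat_unit,min_bp,max_bp
# ---------------------------------------------------------------------------


def read_locus_defs(path) -> tuple[LocusDef, ...]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise GenotypeError(f"no loci in {path}")
    defs = []
    for r in rows:
        mtype = r["marker_type"].strip()
        unit = r.get("repeat_unit", "").strip()
        lo, hi = r.get("min_bp", "").strip(), r.get("max_bp", "").strip()
        defs.append(
            LocusDef(
                name=r["locus"].strip(),
                marker_type=mtype,
                repeat_unit=int(unit) if unit else None,
                size_range=(int(lo), int(hi)) if lo and hi else None,
            )
        )
    return tuple(defs)


def write_locus_defs(loci: Iterable[LocusDef], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["locus", "marker_type", "repeat_unit", "min_bp", "max_bp"])
        for l in loci:
            lo, hi = l.size_range if l.size_range else ("", "")
            w.writerow([l.name, l.marker_type, l.repeat_unit or "", lo, hi])


def read_genotypes(path, locus_meta, ploidy: int = 4) -> GenotypeTable:
    """Read a genotype CSV plus its locus-metadata CSV into a validated table."""
    loci = read_locus_defs(locus_meta)
    ssr = [l for l in loci if l.marker_type == SSR]
    s_loc = next((l for l in loci if l.marker_type == S_LOCUS), None)

    expected = ["accession", "group"]
    for l in ssr:
        expected += [f"{l.name}.{k}" for k in range(1, ploidy + 1)]
    if s_loc is not None:
        expected.append(s_loc.name)

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != expected:
            raise GenotypeError(
                f"unexpected genotype header in {path}; expected {expected}"
            )
        accs: list[AccessionGenotype] = []
        seen: set[str] = set()
        for row in reader:
            if not row or not any(c.strip() for c in row):
                continue
            acc_id = row[0].strip()
            if acc_id in seen:
                raise GenotypeError(f"duplicate accession id {acc_id!r}")
            seen.add(acc_id)
            group = row[1].strip() or None
            cells: dict[str, tuple[int, ...]] = {}
            col = 2
            for l in ssr:
                raw = [c.strip() for c in row[col : col + ploidy]]
                col += ploidy
                vals = []
                for c in raw:
                    if not c:
                        continue
                    try:
                        vals.append(int(c))
                    except ValueError:
                        raise GenotypeError(
                            f"accession {acc_id!r}, locus {l.name!r}: "
                            f"non-integer SSR allele size {c!r}"
                        ) from None
                if vals:
                    cells[l.name] = tuple(sorted(vals))
            s_set: Optional[frozenset[str]] = None
            if s_loc is not None:
                raw_s = row[col].strip() if col < len(row) else ""
                if raw_s:
                    s_set = frozenset(x.strip() for x in raw_s.split("/") if x.strip())
            accs.append(
                AccessionGenotype(
                    accession_id=acc_id, group=group, ssr_alleles=cells, s_alleles=s_set
                )
            )
    return GenotypeTable(loci=tuple(loci), accessions=tuple(accs), ploidy=ploidy)


def write_genotypes(table: GenotypeTable, path) -> None:
    """Write the genotype CSV; ``read_genotypes`` on the result round-trips."""
    ssr = table.ssr_loci
    s_loc = table.s_locus
    header = ["accession", "group"]
    for l in ssr:
        header += [f"{l.name}.{k}" for k in range(1, table.ploidy + 1)]
    if s_loc is not None:
        header.append(s_loc.name)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for acc in table:
            row = [acc.accession_id, acc.group or ""]
            for l in ssr:
                cell = acc.ssr_alleles.get(l.name, ())
                padded = [str(v) for v in cell] + [""] * (table.ploidy - len(cell))
                row += padded
            if s_loc is not None:
                row.append(
                    "/".join(sorted(acc.s_alleles)) if acc.s_alleles is not None else ""
                )
            w.writerow(row)


def validate(table: GenotypeTable) -> list[Diagnostic]:
    """Non-fatal quality diagnostics.  Pure: never mutates the table.

    Fewer distinct alleles than the ploidy at a locus is flagged (it may
    reflect allele dosage or null alleles — indistinguishable in routine
    polyploid scoring); observed sizes outside a declared range are flagged;
    wholly missing cells are reported.
    """
    diags: list[Diagnostic] = []
    observed_range: dict[str, tuple[int, int]] = {}
    for acc in table:
        for l in table.ssr_loci:
            cell = acc.ssr_alleles.get(l.name)
            if cell is None:
                diags.append(
                    Diagnostic(
                        "missing_locus",
                        acc.accession_id,
                        l.name,
                        f"{acc.accession_id}: no alleles scored at {l.name}",
                    )
                )
                continue
            if len(set(cell)) < table.ploidy:
                diags.append(
                    Diagnostic(
                        "dosage_or_null",
                        acc.accession_id,
                        l.name,
                        f"{acc.accession_id}: {len(set(cell))} distinct allele(s) at "
                        f"{l.name} (< ploidy {table.ploidy}); possible dosage/null",
                    )
                )
            lo, hi = min(cell), max(cell)
            cur = observed_range.get(l.name)
            observed_range[l.name] = (
                (lo, hi) if cur is None else (min(cur[0], lo), max(cur[1], hi))
            )
            if l.size_range is not None and (lo < l.size_range[0] or hi > l.size_range[1]):
                bad = [v for v in cell if not l.size_range[0] <= v <= l.size_range[1]]
                diags.append(
                    Diagnostic(
                        "size_range",
                        acc.accession_id,
                        l.name,
                        f"{acc.accession_id}: size(s) {bad} at {l.name} outside "
                        f"declared range {l.size_range}",
                    )
                )
        if table.s_locus is not None and acc.s_alleles is None:
            diags.append(
                Diagnostic(
                    "missing_locus",
                    acc.accession_id,
                    table.s_locus.name,
                    f"{acc.accession_id}: no S-alleles scored",
                )
            )
    return diags


def observed_size_ranges(table: GenotypeTable) -> dict[str, tuple[int, int]]:
    """Per-SSR-locus (min, max) fragment size actually observed."""
    out: dict[str, tuple[int, int]] = {}
    for acc in table:
        for loc, cell in acc.ssr_alleles.items():
            cur = out.get(loc)
            lo, hi = min(cell), max(cell)
            out[loc] = (lo, hi) if cur is None else (min(cur[0], lo), max(cur[1], hi))
    return out
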