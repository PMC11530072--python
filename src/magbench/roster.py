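"""Species rosters and taxonomic triplets for mock-community design.

A benchmark community group holds 42 species: 33 bacteria, 6 archaea and
3 fungi.  Within each group, 36 prokaryotes are organised into 12 taxonomic
triplets — a *reference* species, a *very closely related* partner from the
same genus, and a *closely related* partner from the same family but a
different genus.  Three bacteria with unusual genome topology (linear or
multiple replicons) and the three fungi sit outside the triplet structure.

This module loads roster tables, validates the composition invariants, and
builds the triplets with a seeded random choice of reference species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RosterStructureError, RosterValidationError, SchemaError

DOMAINS = ("bacteria", "archaea", "eukaryote")
TOPOLOGIES = ("single_circular", "linear", "multiple")

#: Required composition of every community group.
GROUP_SIZE = 42
DOMAIN_COUNTS = {"bacteria": 33, "archaea": 6, "eukaryote": 3}
N_TRIPLETS = 12
N_SPECIALS = 3
N_FUNGI = 3

ROSTER_COLUMNS = [
    "species_id",
    "name",
    "domain",
    "phylum",
    "family",
    "genus",
    "topology",
    "genome_ref",
    "group",
]


def normalize_name(name: str) -> str:
    """Normalize a binomial to lower-case ``genus epithet``.

    Matching of recovered taxonomy against the community roster is done at
    species rank, case-insensitively, on the first two whitespace-separated
    tokens.  Abbreviated genus names are NOT expanded.
    """
    parts = name.split()
    return " ".join(p.lower() for p in parts[:2])


@dataclass(frozen=True)
class SpeciesRecord:
    """One organism in the roster."""

    species_id: str
    name: str
    domain: str
    phylum: str
    family: str
    genus: str
    topology: str = "single_circular"
    genome_ref: str = ""
    genome_length: int | None = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise RosterValidationError(
                f"{self.species_id}: domain {self.domain!r} not in {DOMAINS}"
            )
        if self.topology not in TOPOLOGIES:
            raise RosterValidationError(
                f"{self.species_id}: topology {self.topology!r} not in {TOPOLOGIES}"
            )
        if self.genome_length is not None and self.genome_length <= 0:
            raise RosterValidationError(
                f"{self.species_id}: genome_length must be positive"
            )

    @property
    def normalized_name(self) -> str:
        return normalize_name(self.name)

    @property
    def is_fungus(self) -> bool:
        return self.domain == "eukaryote"

    @property
    def is_special(self) -> bool:
        """Bacteria with linear or multi-replicon genomes sit outside triplets."""
        return self.domain == "bacteria" and self.topology != "single_circular"


@dataclass(frozen=True)
class Triplet:
    """A reference species with its same-genus and same-family partners."""

    reference_id: str
    very_close_id: str
    close_id: str

    def ids(self) -> tuple[str, str, str]:
        return (self.reference_id, self.very_close_id, self.close_id)


@dataclass
class SpeciesGroup:
    """One replicate community group of 42 species."""

    group_label: str
    members: list[SpeciesRecord]
    triplets: list[Triplet] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {m.species_id: m for m in self.members}

    def __getitem__(self, species_id: str) -> SpeciesRecord:
        return self._by_id[species_id]

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._by_id

    @property
    def specials(self) -> list[str]:
        return [m.species_id for m in self.members if m.is_special]

    @property
    def fungi(self) -> list[str]:
        return [m.species_id for m in self.members if m.is_fungus]

    @property
    def truth_names(self) -> set[str]:
        """Normalized species names — the ground-truth set for evaluation."""
        return {m.normalized_name for m in self.members}

    def triplet_pairs(self, relatedness_class: str) -> list[tuple[str, str]]:
        """Normalized-name pairs for one relatedness class.

        ``very_close`` pairs a triplet's reference with its same-genus
        partner; ``close`` pairs it with the same-family partner.
        """
        if relatedness_class not in ("very_close", "close"):
            raise ValueError(f"unknown relatedness class {relatedness_class!r}")
        pairs = []
        for t in self.triplets:
            partner = t.very_close_id if relatedness_class == "very_close" else t.close_id
            pairs.append(
                (self[t.reference_id].normalized_name, self[partner].normalized_name)
            )
        return pairs


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    group_label: str
    checks: list[ValidationCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]


def _triplet_families(group: SpeciesGroup) -> dict[tuple[str, str], list[SpeciesRecord]]:
    """Prokaryotes eligible for triplets, keyed by (phylum, family)."""
    fams: dict[tuple[str, str], list[SpeciesRecord]] = {}
    for m in group.members:
        if m.is_fungus or m.is_special:
            continue
        fams.setdefault((m.phylum, m.family), []).append(m)
    return fams


def validate_group(group: SpeciesGroup) -> ValidationReport:
    """Check every composition invariant; report-only, never raises.

    Triplet-specific checks run only when triplets have been built.
    """
    checks: list[ValidationCheck] = []

    n = len(group.members)
    checks.append(
        ValidationCheck("member_count", n == GROUP_SIZE, f"|members| = {n}, expected {GROUP_SIZE}")
    )

    counts = {d: 0 for d in DOMAINS}
    for m in group.members:
        counts[m.domain] += 1
    checks.append(
        ValidationCheck(
            "domain_counts",
            counts == DOMAIN_COUNTS,
            f"domain counts {counts}, expected {DOMAIN_COUNTS}",
        )
    )

    names = [m.normalized_name for m in group.members]
    dupes = sorted({x for x in names if names.count(x) > 1})
    checks.append(
        ValidationCheck("unique_names", not dupes, f"duplicate normalized names: {dupes}")
    )

    n_special = len(group.specials)
    checks.append(
        ValidationCheck(
            "special_count", n_special == N_SPECIALS, f"{n_special} special-topology bacteria, expected {N_SPECIALS}"
        )
    )
    n_fungi = len(group.fungi)
    checks.append(
        ValidationCheck("fungi_count", n_fungi == N_FUNGI, f"{n_fungi} fungi, expected {N_FUNGI}")
    )

    # Triplet constructibility: the 36 eligible prokaryotes must partition
    # into 12 (phylum, family) sets of 3 with a 2+1 genus split.
    fams = _triplet_families(group)
    bad = []
    for key, members in sorted(fams.items()):
        genera: dict[str, int] = {}
        for m in members:
            genera[m.genus] = genera.get(m.genus, 0) + 1
        if len(members) != 3 or sorted(genera.values()) != [1, 2]:
            bad.append(f"{key[0]}/{key[1]}: {len(members)} members, genus split {sorted(genera.values())}")
    checks.append(
        ValidationCheck(
            "triplet_families",
            len(fams) == N_TRIPLETS and not bad,
            f"{len(fams)} candidate families (need {N_TRIPLETS}); violations: {bad}",
        )
    )

    if group.triplets:
        checks.append(
            ValidationCheck(
                "triplet_count",
                len(group.triplets) == N_TRIPLETS,
                f"{len(group.triplets)} triplets, expected {N_TRIPLETS}",
            )
        )
        rule_ok, rule_detail = True, ""
        excluded = set(group.specials) | set(group.fungi)
        seen: set[str] = set()
        for t in group.triplets:
            if any(sid not in group for sid in t.ids()):
                rule_ok, rule_detail = False, f"unknown species in {t}"
                continue
            seen.update(t.ids())
            if not rule_ok:
                continue  # keep collecting membership, report first rule failure
            ref, vc, cl = (group[s] for s in t.ids())
            if ref.genus != vc.genus or ref.normalized_name == vc.normalized_name:
                rule_ok, rule_detail = False, f"{vc.name} is not a same-genus partner of {ref.name}"
            elif ref.family != cl.family or ref.genus == cl.genus:
                rule_ok, rule_detail = False, f"{cl.name} must share family but not genus with {ref.name}"
            elif not (ref.phylum == vc.phylum == cl.phylum):
                rule_ok, rule_detail = False, f"triplet of {ref.name} spans phyla"
        checks.append(ValidationCheck("triplet_rules", rule_ok, rule_detail))
        overlap = seen & excluded
        checks.append(
            ValidationCheck(
                "triplet_disjoint_from_specials_fungi",
                not overlap,
                f"species in triplets that are special/fungal: {sorted(overlap)}",
            )
        )
        checks.append(
            ValidationCheck(
                "triplet_coverage",
                len(seen) == 3 * N_TRIPLETS,
                f"{len(seen)} distinct species covered by triplets, expected {3 * N_TRIPLETS}",
            )
        )

    return ValidationReport(group.group_label, checks)


def build_triplets(group: SpeciesGroup, seed: int) -> list[Triplet]:
    """Construct the 12 taxonomic triplets of a group.

    Within each eligible (phylum, family) set of three prokaryotes the
    reference is drawn with a seeded RNG from the two same-genus species;
    the other becomes the very-closely-related partner and the remaining
    single-genus species the closely-related partner.  Deterministic under
    the seed.
    """
    rng = np.random.default_rng(seed)
    fams = _triplet_families(group)
    triplets: list[Triplet] = []
    missing: list[str] = []
    for (phylum, family), members in sorted(fams.items(), key=lambda kv: kv[0]):
        genera: dict[str, list[SpeciesRecord]] = {}
        for m in sorted(members, key=lambda m: m.species_id):
            genera.setdefault(m.genus, []).append(m)
        pair_genera = [g for g, ms in genera.items() if len(ms) >= 2]
        single_genera = [g for g, ms in genera.items() if g not in pair_genera]
        if len(members) != 3 or not pair_genera or not single_genera:
            missing.append(f"{phylum}/{family}")
            continue
        pair = genera[pair_genera[0]]
        idx = int(rng.integers(len(pair)))
        reference = pair[idx]
        very_close = pair[1 - idx]
        close = genera[single_genera[0]][0]
        triplets.append(Triplet(reference.species_id, very_close.species_id, close.species_id))
    if len(triplets) != N_TRIPLETS:
        raise RosterStructureError(
            f"group {group.group_label}: constructed {len(triplets)} triplets, "
            f"expected {N_TRIPLETS}; families lacking a genus-pair plus family-mate: {missing}"
        )
    return triplets


def load_roster(table: str | Path | pd.DataFrame) -> list[SpeciesGroup]:
    """Load a roster TSV (or DataFrame) into validated species groups.

    The table must carry the columns ``species_id, name, domain, phylum,
    family, genus, topology, genome_ref, group`` (``genome_length`` optional).
    Raises :class:`SchemaError` on missing columns and
    :class:`RosterValidationError` naming the violated composition count.
    Triplets are *not* built here — see :func:`build_triplets`.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)

    missing = [c for c in ROSTER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"roster table is missing required columns: {missing}")

    groups: list[SpeciesGroup] = []
    for label, sub in df.groupby("group", sort=True):
        members = []
        for row in sub.itertuples(index=False):
            glen = getattr(row, "genome_length", None)
            glen = int(glen) if glen not in (None, "", "NA") else None
            members.append(
                SpeciesRecord(
                    species_id=row.species_id,
                    name=row.name,
                    domain=row.domain,
                    phylum=row.phylum,
                    family=row.family,
                    genus=row.genus,
                    topology=row.topology,
                    genome_ref=row.genome_ref,
                    genome_length=glen,
                )
            )
        group = SpeciesGroup(group_label=str(label), members=members)
        report = validate_group(group)
        if not report.passed:
            details = "; ".join(f"{c.name}: {c.detail}" for c in report.failures())
            raise RosterValidationError(f"group {label} failed validation — {details}")
        groups.append(group)
    return groups


def roster_to_frame(groups: list[SpeciesGroup]) -> pd.DataFrame:
    """Flatten groups back into the tabular roster dialect."""
    rows = []
    for g in groups:
        for m in g.members:
            rows.append(
                {
                    "species_id": m.species_id,
                    "name": m.name,
                    "domain": m.domain,
                    "phylum": m.phylum,
                    "family": m.family,
                    "genus": m.genus,
                    "topology": m.topology,
                    "genome_ref": m.genome_ref,
                    "group": g.group_label,
                    "genome_length": m.genome_length if m.genome_length is not None else "",
                }
            )
    return pd.DataFrame(rows)


def write_roster(groups: list[SpeciesGroup], path: str | Path) -> None:
    roster_to_frame(groups).to_csv(path, sep="\t", index=False)
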