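"""The factorial benchmark design: 23 community profiles per species group.

Each community profile fixes an abundance distribution, a taxonomic
relatedness arrangement, and a sequencing depth (in read pairs):

* 12 profiles — the four decay distributions (log/exp, with and without
  plateaus) crossed with the three relatedness arrangements (very closely
  related, closely related, not closely related) at 60 M read pairs;
* 10 profiles — log and exp decay crossed with all five depths
  (10/30/60/120/180 M) under a random arrangement;
* 1 profile — equal abundance, ordered arrangement, 60 M.

Three species groups (A, B, C) act as biological replicates, for 69
simulated communities in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AbundanceProfile, make_profile
from .roster import SpeciesGroup

DEPTHS = (10_000_000, 30_000_000, 60_000_000, 120_000_000, 180_000_000)
BASE_DEPTH = 60_000_000
RELATEDNESS = ("ordered", "random", "very_close", "close", "not_close")
GROUP_LABELS = ("A", "B", "C")


@dataclass(frozen=True)
class CommunityProfile:
    """One cell of the factorial design."""

    group_label: str
    abundance_kind: str
    relatedness: str
    depth: int  # read pairs
    seed: int

    @property
    def profile_id(self) -> str:
        return (
            f"{self.group_label}-{self.abundance_kind}-{self.relatedness}-"
            f"{self.depth // 1_000_000}M"
        )


@dataclass(frozen=True)
class Assignment:
    rank: int  # 1-based abundance rank
    species_id: str
    abundance: float
    read_pairs: int


@dataclass
class CommunitySpec:
    """A fully arranged community: species -> (abundance, read budget)."""

    profile: CommunityProfile
    assignments: list[Assignment]

    @property
    def total_pairs(self) -> int:
        return sum(a.read_pairs for a in self.assignments)

    @property
    def total_reads(self) -> int:
        """Total individual reads R in the library (two mates per pair)."""
        return 2 * self.profile.depth

    def budgets(self) -> dict[str, int]:
        return {a.species_id: a.read_pairs for a in self.assignments}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [a.rank for a in self.assignments],
                "species_id": [a.species_id for a in self.assignments],
                "abundance": [a.abundance for a in self.assignments],
                "read_pairs": [a.read_pairs for a in self.assignments],
            }
        )


def _derive_seed(master_seed: int, group_label: str, index: int) -> int:
    ss = np.random.SeedSequence([master_seed, ord(group_label[0]), index])
    return int(ss.generate_state(1)[0] % (2**31))


def enumerate_design(group_label: str, master_seed: int = 17) -> list[CommunityProfile]:
    """Enumerate the 23 community profiles of one species group.

    Profile order is deterministic and the per-profile seeds are derived
    reproducibly from the master seed, so the whole design is a pure
    function of (group_label, master_seed).
    """
    profiles: list[CommunityProfile] = []
    i = 0

    def add(kind: str, rel: str, depth: int) -> None:
        nonlocal i
        profiles.append(
            CommunityProfile(
                group_label=group_label,
                abundance_kind=kind,
                relatedness=rel,
                depth=depth,
                seed=_derive_seed(master_seed, group_label, i),
            )
        )
        i += 1

    for kind in ("log_decay", "exp_decay", "log_decay_plateau", "exp_decay_plateau"):
        for rel in ("very_close", "close", "not_close"):
            add(kind, rel, BASE_DEPTH)
    for kind in ("log_decay", "exp_decay"):
        for depth in DEPTHS:
            add(kind, "random", depth)
    add("equal", "ordered", BASE_DEPTH)
    return profiles


def full_design(master_seed: int = 17) -> list[CommunityProfile]:
    """All 69 profiles across the three replicate groups."""
    out: list[CommunityProfile] = []
    for label in GROUP_LABELS:
        out.extend(enumerate_design(label, master_seed))
    return out


def allocate_reads(abundances: np.ndarray, depth: int) -> np.ndarray:
    """Integer read-pair budgets by largest-remainder rounding of depth × aᵢ.

    Budgets sum to the depth exactly; ties in fractional remainder go to the
    lower (more abundant) rank first.
    """
    a = np.asarray(abundances, dtype=float)
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    if depth <= 0:
        raise ValueError("depth must be positive")
    exact = a * depth
    base = np.floor(exact).astype(np.int64)
    short = depth - int(base.sum())
    # stable sort keeps lower ranks first among equal remainders
    order = np.argsort(-(exact - base), kind="stable")
    base[order[:short]] += 1
    return base


def arrange_community(
    profile: CommunityProfile, group: SpeciesGroup, abundance: AbundanceProfile
) -> CommunitySpec:
    """Assign species to abundance ranks per the relatedness rule.

    * ``ordered`` — triplets in listed order (reference, very-close, close),
      then special-topology bacteria, then fungi.
    * ``random`` — seeded uniform shuffle.
    * ``very_close`` / ``close`` — each triplet's (reference, partner) pair
      occupies adjacent ranks so related species sit at similar abundances;
      the remaining species interleave by seeded shuffle.
    * ``not_close`` — each triplet's three members are spread at least n/3
      ranks apart so related species never share similar abundances.

    Fungi and special-topology bacteria are never rank-constrained.
    Deterministic under the profile seed.
    """
    n = len(group.members)
    if n != abundance.n_species:
        raise ValueError(
            f"group has {n} members but abundance profile covers {abundance.n_species}"
        )
    if profile.relatedness not in RELATEDNESS:
        raise ValueError(f"unknown relatedness {profile.relatedness!r}")
    if profile.relatedness != "random" and not group.triplets:
        raise ValueError("group triplets must be built before arranging this profile")

    rng = np.random.default_rng(profile.seed)
    specials = sorted(group.specials)
    fungi = sorted(group.fungi)

    def shuffled(items: list[str]) -> list[str]:
        items = list(items)
        rng.shuffle(items)
        return items

    rel = profile.relatedness
    if rel == "ordered":
        order = [sid for t in group.triplets for sid in t.ids()] + specials + fungi
    elif rel == "random":
        order = shuffled([m.species_id for m in group.members])
    elif rel in ("very_close", "close"):
        pairs = []
        for t in shuffled_triplets(group, rng):
            partner = t.very_close_id if rel == "very_close" else t.close_id
            pair = [t.reference_id, partner]
            rng.shuffle(pair)
            pairs.append(pair)
        leftover = [
            (t.close_id if rel == "very_close" else t.very_close_id) for t in group.triplets
        ]
        fillers = shuffled(leftover + specials + fungi)
        order = []
        for pair in pairs:
            order.extend(pair)
            if fillers:
                order.append(fillers.pop())
        order.extend(fillers)
    else:  # not_close
        t_list = shuffled_triplets(group, rng)
        third = n // 3
        if len(t_list) > third:
            raise ValueError("too many triplets to spread across thirds of the ranking")
        slots: list[str | None] = [None] * n
        for i, t in enumerate(t_list):
            slots[i] = t.reference_id
            slots[third + i] = t.very_close_id
            slots[2 * third + i] = t.close_id
        fillers = shuffled(specials + fungi)
        for j in range(n):
            if slots[j] is None:
                slots[j] = fillers.pop()
        order = [s for s in slots if s is not None]

    if sorted(order) != sorted(m.species_id for m in group.members):
        raise AssertionError("arrangement lost or duplicated species")  # pragma: no cover

    a = abundance.as_array()
    budgets = allocate_reads(a, profile.depth)
    assignments = [
        Assignment(rank=i + 1, species_id=sid, abundance=float(a[i]), read_pairs=int(budgets[i]))
        for i, sid in enumerate(order)
    ]
    return CommunitySpec(profile=profile, assignments=assignments)


def shuffled_triplets(group: SpeciesGroup, rng: np.random.Generator):
    t_list = list(group.triplets)
    rng.shuffle(t_list)
    return t_list


def build_spec(
    profile: CommunityProfile, group: SpeciesGroup, floor: float | None = None
) -> CommunitySpec:
    """Convenience: make the profile's abundance distribution and arrange it."""
    kwargs = {} if floor is None else {"floor": floor}
    ab = make_profile(profile.abundance_kind, len(group.members), **kwargs)
    return arrange_community(profile, group, ab)


def write_design(
    profiles: list[CommunityProfile],
    specs: list[CommunitySpec],
    out_dir: str | Path,
) -> Path:
    """Write one spec TSV per profile plus a design manifest TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for prof, spec in zip(profiles, specs):
        spec.to_frame().to_csv(out / f"{prof.profile_id}.spec.tsv", sep="\t", index=False)
        rows.append(
            {
                "profile_id": prof.profile_id,
                "group": prof.group_label,
                "abundance_kind": prof.abundance_kind,
                "relatedness": prof.relatedness,
                "depth": prof.depth,
                "seed": prof.seed,
            }
        )
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
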