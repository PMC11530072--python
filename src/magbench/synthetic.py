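"""Synthetic study inputs: rosters, genomes, and a parameterized mock binner.

Everything the pipeline consumes can be generated here with no downloads:

* :func:`gen_taxonomy` fabricates replicate species groups with the full
  benchmark structure — 42 species each (33 bacteria / 6 archaea / 3 fungi),
  12 taxonomic triplets per group (10 bacterial, 2 archaeal), three
  special-topology bacteria (linear or multi-replicon) and three fungi.
* :func:`gen_genomes` writes random-sequence replicons honouring each
  species' topology and a target GC range.
* :func:`mock_binner` emulates the *outcome* of a binning pipeline on a
  community spec: per-species detection (optionally gated on fold
  coverage), completeness/contamination draws, multiple bins per species,
  and off-roster false positives labelled as taxonomic siblings.  It
  operates on the design truth rather than on reads, which keeps benchmark
  experiments fast while preserving the coverage dependence of detection.

All generators are deterministic under their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import warnings

import numpy as np

from .design import CommunitySpec
from .evaluate import BinRecord
from .roster import SpeciesGroup, SpeciesRecord, build_triplets

_SYL1 = ["Aceto", "Bacillo", "Clostri", "Deino", "Entero", "Flavo", "Geo",
         "Halo", "Igni", "Janti", "Korar", "Lacto", "Metha", "Nitro", "Ocea",
         "Pyro", "Querco", "Rhodo", "Sulfo", "Thermo", "Ulvi", "Vibrio",
         "Xantho", "Yersi", "Zymo"]
_SYL2 = ["bacter", "coccus", "monas", "bacillus", "archaeum", "spira",
         "myces", "sphaera", "vibrio", "globus", "plasma", "thrix"]
_EPI = ["albus", "brevis", "casei", "durans", "elegans", "fragilis",
        "gracilis", "halophilus", "insolitus", "jejuni", "kandleri",
        "longus", "marinus", "natans", "oralis", "pallidus", "quietus",
        "ruber", "subtilis", "tenax", "undae", "vulgaris", "xylosus"]


class _NameForge:
    """Deterministic, collision-free fabricated taxonomy labels."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.used_genera: set[str] = set()
        self.used_names: set[str] = set()

    def genus(self) -> str:
        while True:
            g = self.rng.choice(_SYL1) + self.rng.choice(_SYL2)
            if g not in self.used_genera:
                self.used_genera.add(g)
                return g
            g += self.rng.choice(["ella", "oides", "ium"])
            if g not in self.used_genera:
                self.used_genera.add(g)
                return g

    def species(self, genus: str) -> str:
        for _ in range(100):
            epi = self.rng.choice(_EPI)
            if self.rng.random() < 0.5:
                epi += self.rng.choice(["", "i", "is", "ensis"])
            name = f"{genus} {epi}"
            if name.lower() not in self.used_names:
                self.used_names.add(name.lower())
                return name
        # syllable space exhausted for this genus: number the epithet
        k = 1
        while f"{genus} sp{k}".lower() in self.used_names:
            k += 1
        name = f"{genus} sp{k}"
        self.used_names.add(name.lower())
        return name


def _genome_length(rng: np.random.Generator, domain: str) -> int:
    lo, hi = {
        "bacteria": (2_000_000, 6_000_000),
        "archaea": (1_500_000, 3_500_000),
        "eukaryote": (10_000_000, 40_000_000),
    }[domain]
    return int(rng.integers(lo, hi))


def gen_taxonomy(n_groups: int = 3, seed: int = 0) -> list[SpeciesGroup]:
    """Fabricate replicate species groups with the benchmark composition.

    Each group holds 12 triplet families (phylum/family of three species,
    two sharing a genus), three special-topology bacteria and three fungi.
    Genus and family labels are fabricated, so off-roster sibling species
    names always exist for the mock binner's false-positive modes.
    Triplets are built with a seed derived from *seed*; the same seed
    reproduces the same rosters exactly.
    """
    rng = np.random.default_rng(seed)
    forge = _NameForge(rng)
    groups: list[SpeciesGroup] = []
    for gi in range(n_groups):
        label = chr(ord("A") + gi)
        members: list[SpeciesRecord] = []
        idx = 0

        def add(name: str, domain: str, phylum: str, family: str, genus: str,
                topology: str = "single_circular") -> None:
            nonlocal idx
            members.append(
                SpeciesRecord(
                    species_id=f"{label}{idx:02d}",
                    name=name,
                    domain=domain,
                    phylum=phylum,
                    family=family,
                    genus=genus,
                    topology=topology,
                    genome_ref=f"synthetic:{label}{idx:02d}",
                    genome_length=_genome_length(rng, domain),
                )
            )
            idx += 1

        # 12 triplet families: 10 bacterial + 2 archaeal (6 archaea total)
        for t in range(12):
            domain = "bacteria" if t < 10 else "archaea"
            phylum = f"p{label}{t:02d}"
            family = f"f{label}{t:02d}"
            g_pair = forge.genus()
            g_single = forge.genus()
            add(forge.species(g_pair), domain, phylum, family, g_pair)
            add(forge.species(g_pair), domain, phylum, family, g_pair)
            add(forge.species(g_single), domain, phylum, family, g_single)

        # 3 special-topology bacteria, outside any triplet family
        special_topos = ["linear", "multiple",
                         str(rng.choice(["linear", "multiple"]))]
        for s, topo in enumerate(special_topos):
            g = forge.genus()
            add(forge.species(g), "bacteria", f"pspec{label}{s}", f"fspec{label}{s}", g,
                topology=topo)

        # 3 fungi
        for s in range(3):
            g = forge.genus()
            add(forge.species(g), "eukaryote", f"pfun{label}{s}", f"ffun{label}{s}", g,
                topology="multiple")

        group = SpeciesGroup(group_label=label, members=members)
        group.triplets = build_triplets(group, seed=int(rng.integers(2**31)))
        groups.append(group)
    return groups


def gen_genomes(
    group: SpeciesGroup,
    length_range: tuple[int, int] = (100_000, 1_000_000),
    gc_range: tuple[float, float] = (0.35, 0.65),
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Random genome sequences per species, honouring topology.

    Species with ``multiple`` topology get 2–3 replicons, ``linear`` a
    single linear replicon.  Base composition is drawn to hit a GC fraction
    uniform in *gc_range*.  Lengths are for test-scale work, far below real
    genome sizes; pass a larger range for realism.  When *out_dir* is given,
    one FASTA per species is written in the dialect the simulator reads
    (linear replicons flagged ``topology=linear`` in the description).

    Returns a :class:`~magbench.simreads.GenomeCollection`.
    """
    from .simreads import GenomeCollection

    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ValueError("length_range must be positive and ordered")
    rng = np.random.default_rng(seed)
    coll = GenomeCollection()
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for m in group.members:
        total = int(rng.integers(lo, hi + 1))
        if m.topology == "multiple":
            n_rep = int(rng.integers(2, 4))
            cuts = np.sort(rng.integers(1, total, size=n_rep - 1))
            sizes = np.diff(np.concatenate(([0], cuts, [total])))
        else:
            sizes = np.array([total])
        gc = rng.uniform(*gc_range)
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        circular = m.topology != "linear"
        for ri, size in enumerate(sizes):
            seq = rng.choice(bases, size=int(size), p=p).tobytes().decode()
            coll.add(m.species_id, f"{m.species_id}_r{ri}", seq, circular=circular)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sid, reps in coll.replicons.items():
            with open(out / f"{sid}.fa", "w") as fh:
                for rep in reps:
                    topo = "circular" if rep.circular else "linear"
                    fh.write(f">{rep.name} topology={topo}\n")
                    for i in range(0, len(rep.seq), 80):
                        fh.write(rep.seq[i : i + 80] + "\n")
    return coll


FP_MODES = ("sibling_genus", "sibling_family", "random_label")


@dataclass(frozen=True)
class MockBinnerParams:
    """Behavioral knobs of the mock binning pipeline.

    *p_detect* is the per-species probability of recovering at least one
    bin; with *detection_threshold* set, species whose truth fold coverage
    (L × reads / genome length) falls below it are never detected.
    *p_fp* is the per-species probability of also emitting one off-roster
    bin, labelled per *fp_mode*.  Completeness/contamination draws are
    normal, truncated to valid percentage ranges; defaults sit near the
    quality levels typical of curated MAG sets (≈97 % complete, ≈1 %
    contaminated) so most bins pass the quality filter.
    """

    p_detect: float = 0.95
    completeness_mean: float = 97.0
    completeness_sd: float = 4.0
    contamination_mean: float = 1.0
    contamination_sd: float = 1.5
    p_fp: float = 0.05
    fp_mode: str = "sibling_genus"
    bins_per_species_mean: float = 1.0
    detection_threshold: float | None = None
    read_length: float = 125.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_detect", "p_fp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.completeness_sd < 0 or self.contamination_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.bins_per_species_mean < 1.0:
            raise ValueError("bins_per_species_mean must be >= 1")
        if self.fp_mode not in FP_MODES:
            raise ValueError(f"fp_mode must be one of {FP_MODES}")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _fp_label(rec: SpeciesRecord, params: MockBinnerParams,
              rng: np.random.Generator) -> str:
    mode = params.fp_mode
    if mode in ("sibling_genus", "sibling_family") and not rec.genus:
        warnings.warn(
            f"species {rec.species_id} has no genus label; "
            "falling back to a random off-roster label",
            stacklevel=2,
        )
        mode = "random_label"
    if mode == "sibling_genus":
        return f"{rec.genus} fictus{rec.species_id.lower()}"
    if mode == "sibling_family":
        return f"Para{rec.genus.lower()} fictus{rec.species_id.lower()}"
    return f"Incertae ignotus{rec.species_id.lower()}"


def mock_binner(
    spec: CommunitySpec,
    group: SpeciesGroup,
    params: MockBinnerParams,
    pipeline: str = "mock",
    seed: int | None = None,
) -> list[BinRecord]:
    """Emulate a binning pipeline's output bins for one community spec.

    For every species in the spec, detection succeeds with ``p_detect``
    (and only if its truth coverage clears ``detection_threshold`` when
    set).  Detected species yield one or more bins whose mapped reads sum
    to the species' full read budget (two mates per pair) and whose sizes
    scale with drawn completeness.  Off-roster false-positive bins carry a
    unique sibling label per emitting species, so species-level FP counts
    equal the number of FP emissions.  Deterministic under the seed.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    bins: list[BinRecord] = []
    pid = spec.profile.profile_id
    for assign in spec.assignments:
        rec = group[assign.species_id]
        g_len = rec.genome_length or 3_000_000
        n_reads = 2 * assign.read_pairs
        cov = params.read_length * n_reads / g_len

        detected = rng.random() < params.p_detect
        if params.detection_threshold is not None and cov < params.detection_threshold:
            detected = False
        if detected:
            n_bins = 1 + int(rng.poisson(params.bins_per_species_mean - 1.0))
            comps = [
                _truncated_normal(rng, params.completeness_mean,
                                  params.completeness_sd, 0.0, 100.0)
                for _ in range(n_bins)
            ]
            weights = np.asarray(comps, dtype=float)
            shares = rng.multinomial(n_reads, weights / weights.sum())
            for bi, (comp, n_mapped) in enumerate(zip(comps, shares)):
                cont = _truncated_normal(rng, params.contamination_mean,
                                         params.contamination_sd, 0.0, 100.0)
                size = max(1, round(g_len * comp / 100.0))
                bins.append(
                    BinRecord(
                        bin_id=f"{pid}:{rec.species_id}:{bi}",
                        profile_id=pid,
                        pipeline=pipeline,
                        completeness=comp,
                        contamination=cont,
                        assigned_species=rec.name,
                        mapped_reads=int(n_mapped),
                        bin_size_bp=size,
                    )
                )
        if rng.random() < params.p_fp:
            comp = _truncated_normal(rng, params.completeness_mean,
                                     params.completeness_sd, 0.0, 100.0)
            cont = _truncated_normal(rng, params.contamination_mean,
                                     params.contamination_sd, 0.0, 100.0)
            fp_size = max(1, round(g_len * rng.uniform(0.3, 1.0)))
            fp_reads = int(round(n_reads * rng.uniform(0.01, 0.2)))
            bins.append(
                BinRecord(
                    bin_id=f"{pid}:{rec.species_id}:fp",
                    profile_id=pid,
                    pipeline=pipeline,
                    completeness=comp,
                    contamination=cont,
                    assigned_species=_fp_label(rec, params, rng),
                    mapped_reads=fp_reads,
                    bin_size_bp=fp_size,
                )
            )
    return bins
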