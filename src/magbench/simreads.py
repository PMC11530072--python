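"""Paired-end shotgun read simulation with truth provenance.

Generates overlapping 125 bp mates from 180 bp fragments drawn uniformly
from each species' replicons, proportional to the community spec's per-
species read-pair budgets.  Every read header encodes its origin
(species, replicon, fragment start, strand) so downstream metrics can be
verified against exact truth rather than by re-mapping.

Coordinates are 0-based and half-open on the forward strand; fragments on
circular replicons may wrap past the origin.  The error model is a uniform
per-base substitution rate (default 0 — error-free truth libraries);
quality strings are a constant high-quality symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import warnings

import numpy as np
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .design import CommunitySpec
from .errors import MissingGenomeError

READ_LENGTH = 125
FRAGMENT_LENGTH = 180
QUALITY_CHAR = "I"  # Phred 40

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class Replicon:
    name: str
    seq: str
    circular: bool = True

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeCollection:
    """Species -> replicons, loaded from per-species FASTA files.

    A replicon is treated as circular unless its FASTA description carries
    a ``topology=linear`` tag.
    """

    replicons: dict[str, list[Replicon]] = field(default_factory=dict)

    def add(self, species_id: str, name: str, seq: str, circular: bool = True) -> None:
        self.replicons.setdefault(species_id, []).append(Replicon(name, seq.upper(), circular))

    @classmethod
    def from_dir(cls, path: str | Path) -> "GenomeCollection":
        """Load every ``<species_id>.fa``/``.fasta`` file in a directory."""
        coll = cls()
        for fa in sorted(Path(path).iterdir()):
            if fa.suffix not in (".fa", ".fasta", ".fna"):
                continue
            sid = fa.stem
            for rec in SeqIO.parse(str(fa), "fasta"):
                circular = "topology=linear" not in rec.description
                coll.add(sid, rec.id, str(rec.seq), circular)
        return coll

    def genome_length(self, species_id: str) -> int:
        return sum(len(r) for r in self.replicons[species_id])

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.replicons


@dataclass(frozen=True)
class ReadOrigin:
    """Parsed truth provenance from a read header."""

    profile_id: str
    species_id: str
    replicon: str
    start: int
    strand: str
    pair_index: int


@dataclass
class ReadLibrary:
    profile_id: str
    mate1_path: Path
    mate2_path: Path
    truth_path: Path
    read_length: int
    fragment_length: int
    error_rate: float
    total_pairs: int
    pairs_per_species: dict[str, int]


def format_header(origin: ReadOrigin, mate: int) -> str:
    return (
        f"@{origin.profile_id}|{origin.species_id}|{origin.replicon}|"
        f"{origin.start}|{origin.strand}|{origin.pair_index}/{mate}"
    )


def parse_header(header: str) -> tuple[ReadOrigin, int]:
    body = header.lstrip("@").split()[0]
    core, mate = body.rsplit("/", 1)
    profile, sid, replicon, start, strand, idx = core.split("|")
    return (
        ReadOrigin(profile, sid, replicon, int(start), strand, int(idx)),
        int(mate),
    )


def extract_fragment(replicon: Replicon, start: int, strand: str, length: int) -> str:
    """The fragment a read pair was cut from, on its sequencing strand."""
    s = replicon.seq
    end = start + length
    frag = s[start:end] if end <= len(s) else s[start:] + s[: end - len(s)]
    return reverse_complement(frag) if strand == "-" else frag


def mates_from_fragment(fragment: str, read_length: int = READ_LENGTH) -> tuple[str, str]:
    """Mate 1 is the fragment's head; mate 2 the reverse complement of its tail."""
    return fragment[:read_length], reverse_complement(fragment[-read_length:])


def _apply_errors(read: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        # substitute with a uniformly chosen *different* base
        offsets = rng.integers(1, 4, size=hits.size)
        idx = np.searchsorted(_BASES, arr[hits])
        idx[idx >= 4] = 0  # non-ACGT characters mutate from 'A'
        arr[hits] = _BASES[(idx + offsets) % 4]
    return arr.tobytes().decode()


def simulate_library(
    spec: CommunitySpec,
    genomes: GenomeCollection,
    seed: int = 0,
    error_rate: float = 0.0,
    out_dir: str | Path = ".",
    read_length: int = READ_LENGTH,
    fragment_length: int = FRAGMENT_LENGTH,
) -> ReadLibrary:
    """Simulate a paired-end library for one community spec.

    Per-species pair counts equal the spec's budgets exactly.  Fragment
    starts are uniform over each species' replicons weighted by effective
    length (circular: full length with wrap-around; linear: positions that
    fit the whole fragment).  Deterministic under the seed.
    """
    if fragment_length < read_length:
        raise ValueError("fragment_length must be at least read_length")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pid = spec.profile.profile_id
    m1_path = out / f"{pid}_R1.fastq"
    m2_path = out / f"{pid}_R2.fastq"
    truth_path = out / f"{pid}_truth.tsv"
    qual = QUALITY_CHAR * read_length

    pairs_per_species: dict[str, int] = {}
    with open(m1_path, "w") as f1, open(m2_path, "w") as f2:
        for assign in spec.assignments:
            sid, budget = assign.species_id, assign.read_pairs
            if sid not in genomes:
                raise MissingGenomeError(f"no genome sequence for species {sid!r}")
            reps, eff = [], []
            for rep in genomes.replicons[sid]:
                e = len(rep) if rep.circular else len(rep) - fragment_length + 1
                if e <= 0:
                    warnings.warn(
                        f"replicon {rep.name} of {sid} is shorter than the fragment; skipped",
                        stacklevel=2,
                    )
                    continue
                reps.append(rep)
                eff.append(e)
            if not reps:
                raise MissingGenomeError(
                    f"species {sid!r} has no replicon long enough for a {fragment_length} bp fragment"
                )
            weights = np.asarray(eff, dtype=float)
            counts = rng.multinomial(budget, weights / weights.sum())
            emitted = 0
            for rep, e, cnt in zip(reps, eff, counts):
                if cnt == 0:
                    continue
                starts = rng.integers(0, e, size=cnt)
                strands = rng.integers(0, 2, size=cnt)
                for start, sflag in zip(starts, strands):
                    strand = "+" if sflag == 0 else "-"
                    origin = ReadOrigin(pid, sid, rep.name, int(start), strand, emitted)
                    frag = extract_fragment(rep, int(start), strand, fragment_length)
                    m1, m2 = mates_from_fragment(frag, read_length)
                    m1 = _apply_errors(m1, rng, error_rate)
                    m2 = _apply_errors(m2, rng, error_rate)
                    f1.write(f"{format_header(origin, 1)}\n{m1}\n+\n{qual}\n")
                    f2.write(f"{format_header(origin, 2)}\n{m2}\n+\n{qual}\n")
                    emitted += 1
            pairs_per_species[sid] = emitted

    with open(truth_path, "w") as ft:
        ft.write("species_id\tpairs_emitted\n")
        for assign in spec.assignments:
            ft.write(f"{assign.species_id}\t{pairs_per_species[assign.species_id]}\n")

    return ReadLibrary(
        profile_id=pid,
        mate1_path=m1_path,
        mate2_path=m2_path,
        truth_path=truth_path,
        read_length=read_length,
        fragment_length=fragment_length,
        error_rate=error_rate,
        total_pairs=sum(pairs_per_species.values()),
        pairs_per_species=pairs_per_species,
    )


def read_paired_fastq(mate1_path: str | Path, mate2_path: str | Path):
    """Yield (header1, seq1, header2, seq2) from a pair of FASTQ files."""
    with open(mate1_path) as f1, open(mate2_path) as f2:
        while True:
            h1 = f1.readline().strip()
            if not h1:
                return
            s1 = f1.readline().strip()
            f1.readline()
            f1.readline()
            h2 = f2.readline().strip()
            s2 = f2.readline().strip()
            f2.readline()
            f2.readline()
            yield h1, s1, h2, s2
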