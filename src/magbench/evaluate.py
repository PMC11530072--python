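"""Bin quality filtering and MAG-recovery metrics.

Quality score = completeness − 5 × contamination; only bins scoring
strictly above 50 enter the evaluation.  Against the known community
roster, passing bins are classified at species rank:

* TP — an original species recovered by at least one passing bin
  (counted once per species regardless of bin multiplicity);
* FP — a passing bin whose assigned species is absent from the original
  community (counted both per bin and per unique off-roster species);
* FN — an original species with no passing bin.

Accuracy(%) = TP / (TP + FP) × 100.  Per-bin fold coverage is
L × N / G (mean read length × mapped reads / bin size) and relative
abundance is N / R (mapped reads / total library reads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .roster import normalize_name

QUALITY_THRESHOLD = 50.0
UNASSIGNED = "unassigned"
DEFAULT_READ_LENGTH = 125


@dataclass(frozen=True)
class BinRecord:
    """One recovered bin/MAG with its quality and mapping statistics."""

    bin_id: str
    profile_id: str
    pipeline: str
    completeness: float  # percent
    contamination: float  # percent
    assigned_species: str  # binomial, or "unassigned"
    mapped_reads: int  # N, individual reads
    bin_size_bp: int  # G

    def __post_init__(self) -> None:
        quality_score(self.completeness, self.contamination)  # range check
        if self.mapped_reads < 0:
            raise ValueError(f"bin {self.bin_id}: mapped_reads must be >= 0")
        if self.bin_size_bp <= 0:
            raise ValueError(f"bin {self.bin_id}: bin_size_bp must be positive")

    @property
    def quality(self) -> float:
        return quality_score(self.completeness, self.contamination)

    @property
    def species_key(self) -> str:
        return normalize_name(self.assigned_species)

    @property
    def is_assigned(self) -> bool:
        return self.assigned_species.strip().lower() not in ("", UNASSIGNED, "na")


def quality_score(completeness: float, contamination: float) -> float:
    """completeness − 5 × contamination (may be negative)."""
    if not 0.0 <= completeness <= 100.0:
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0.0:
        raise ValueError(f"contamination {contamination} must be >= 0")
    return completeness - 5.0 * contamination


def filter_bins(bins: list[BinRecord], threshold: float = QUALITY_THRESHOLD) -> list[BinRecord]:
    """Bins scoring strictly above the threshold, order preserved."""
    return [b for b in bins if b.quality > threshold]


def accuracy(tp: int, fp: int) -> float:
    """TP/(TP+FP) as a percent; NaN when no positives were called."""
    if tp < 0 or fp < 0:
        raise ValueError("TP and FP must be non-negative")
    if tp + fp == 0:
        return math.nan
    return 100.0 * tp / (tp + fp)


@dataclass
class RecoveryTable:
    """Species-level recovery outcome for one (profile, pipeline)."""

    profile_id: str
    pipeline: str
    truth: set[str]
    tp_species: set[str]
    fn_species: set[str]
    fp_bins: list[BinRecord]
    fp_species: set[str]
    unassigned_bins: list[BinRecord] = field(default_factory=list)
    pair_recovery: dict[str, float] = field(default_factory=dict)

    @property
    def n_tp(self) -> int:
        return len(self.tp_species)

    @property
    def n_fn(self) -> int:
        return len(self.fn_species)

    @property
    def n_fp_bins(self) -> int:
        return len(self.fp_bins)

    @property
    def n_fp_species(self) -> int:
        return len(self.fp_species)

    def accuracy(self, fp_level: str = "species") -> float:
        """Eq-style accuracy; FP counted per unique species by default,
        per bin with ``fp_level='bin'``."""
        fp = self.n_fp_species if fp_level == "species" else self.n_fp_bins
        return accuracy(self.n_tp, fp)


def classify_recovery(
    bins: list[BinRecord],
    truth: set[str],
    pairs: dict[str, list[tuple[str, str]]] | None = None,
    profile_id: str = "",
    pipeline: str = "",
) -> RecoveryTable:
    """Classify pre-filtered bins against the original community.

    *truth* is the set of normalized original species names.  Bins without
    an assigned taxonomy are set aside, never counted as FP.  *pairs*
    optionally maps a relatedness class to its species-name pairs so
    pair-recovery fractions are filled in.
    """
    if not truth:
        raise ValueError("truth species set must be non-empty")
    truth = {normalize_name(t) for t in truth}
    tp: set[str] = set()
    fp_bins: list[BinRecord] = []
    fp_species: set[str] = set()
    unassigned: list[BinRecord] = []
    for b in bins:
        if not b.is_assigned:
            unassigned.append(b)
            continue
        key = b.species_key
        if key in truth:
            tp.add(key)
        else:
            fp_bins.append(b)
            fp_species.add(key)

    table = RecoveryTable(
        profile_id=profile_id or (bins[0].profile_id if bins else ""),
        pipeline=pipeline or (bins[0].pipeline if bins else ""),
        truth=truth,
        tp_species=tp,
        fn_species=truth - tp,
        fp_bins=fp_bins,
        fp_species=fp_species,
        unassigned_bins=unassigned,
    )
    if pairs:
        for klass, plist in pairs.items():
            table.pair_recovery[klass] = species_pair_recovery(table, plist)
    return table


def species_pair_recovery(table: RecoveryTable, pairs: list[tuple[str, str]]) -> float:
    """Fraction of related species pairs with BOTH members recovered as TP."""
    if not pairs:
        return math.nan
    hits = sum(
        1
        for a, b in pairs
        if normalize_name(a) in table.tp_species and normalize_name(b) in table.tp_species
    )
    return hits / len(pairs)


def coverage(read_length: float, mapped_reads: int, bin_size_bp: int) -> float:
    """Fold coverage L × N / G."""
    if read_length <= 0:
        raise ValueError("read length must be positive")
    if bin_size_bp <= 0:
        raise ValueError("bin size must be positive")
    if mapped_reads < 0:
        raise ValueError("mapped reads must be >= 0")
    return read_length * mapped_reads / bin_size_bp


def relative_abundance(mapped_reads: int, total_reads: int) -> float:
    """N / R — a bin's share of all reads in its library."""
    if total_reads <= 0:
        raise ValueError("total library reads must be positive")
    if not 0 <= mapped_reads <= total_reads:
        raise ValueError("mapped reads must lie in [0, total reads]")
    return mapped_reads / total_reads


def detection_limit_summary(
    tables: list[RecoveryTable],
    bins: list[BinRecord],
    library_reads: dict[str, int],
    read_length: float = DEFAULT_READ_LENGTH,
) -> pd.DataFrame:
    """Per (profile, pipeline) abundance/coverage extremes of TPs and FPs.

    Reports the lowest relative abundance and fold coverage at which an
    original species was still recovered, and the highest at which a false
    positive was called, with the species names.  Missing extremes (e.g. no
    FP in a profile) come out as NaN/empty.
    """
    by_key = {(t.profile_id, t.pipeline): t for t in tables}
    rows = []
    for (pid, pipe), table in sorted(by_key.items()):
        r_total = library_reads[pid]
        tp_stats, fp_stats = [], []
        for b in bins:
            if b.profile_id != pid or b.pipeline != pipe or not b.is_assigned:
                continue
            stat = (
                relative_abundance(b.mapped_reads, r_total),
                coverage(read_length, b.mapped_reads, b.bin_size_bp),
                b.species_key,
            )
            if b.species_key in table.tp_species:
                tp_stats.append(stat)
            elif b.species_key in table.fp_species:
                fp_stats.append(stat)
        row: dict[str, object] = {"profile_id": pid, "pipeline": pipe}
        if tp_stats:
            ra, cov, name = min(tp_stats)
            row |= {"min_tp_abundance": ra, "min_tp_abundance_species": name}
            cov_min = min(tp_stats, key=lambda s: s[1])
            row |= {"min_tp_coverage": cov_min[1], "min_tp_coverage_species": cov_min[2]}
        else:
            row |= {
                "min_tp_abundance": math.nan,
                "min_tp_abundance_species": "",
                "min_tp_coverage": math.nan,
                "min_tp_coverage_species": "",
            }
        if fp_stats:
            ra, cov, name = max(fp_stats)
            row |= {"max_fp_abundance": ra, "max_fp_abundance_species": name}
            cov_max = max(fp_stats, key=lambda s: s[1])
            row |= {"max_fp_coverage": cov_max[1], "max_fp_coverage_species": cov_max[2]}
        else:
            row |= {
                "max_fp_abundance": math.nan,
                "max_fp_abundance_species": "",
                "max_fp_coverage": math.nan,
                "max_fp_coverage_species": "",
            }
        rows.append(row)
    return pd.DataFrame(rows)


BIN_COLUMNS = [
    "bin_id",
    "profile_id",
    "pipeline",
    "completeness",
    "contamination",
    "assigned_species",
    "mapped_reads",
    "bin_size_bp",
]


def read_bin_table(path: str | Path) -> list[BinRecord]:
    """Read the package's bin-table TSV dialect."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in BIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"bin table is missing required columns: {missing}")
    return [
        BinRecord(
            bin_id=r.bin_id,
            profile_id=r.profile_id,
            pipeline=r.pipeline,
            completeness=float(r.completeness),
            contamination=float(r.contamination),
            assigned_species=r.assigned_species,
            mapped_reads=int(r.mapped_reads),
            bin_size_bp=int(r.bin_size_bp),
        )
        for r in df.itertuples(index=False)
    ]


def write_bin_table(bins: list[BinRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "bin_id": b.bin_id,
                "profile_id": b.profile_id,
                "pipeline": b.pipeline,
                "completeness": b.completeness,
                "contamination": b.contamination,
                "assigned_species": b.assigned_species,
                "mapped_reads": b.mapped_reads,
                "bin_size_bp": b.bin_size_bp,
            }
            for b in bins
        ]
    ).to_csv(path, sep="\t", index=False)


def read_checkm_table(
    path: str | Path,
    profile_id: str,
    pipeline: str,
    species_map: dict[str, str] | None = None,
    mapped_reads: dict[str, int] | None = None,
    bin_sizes: dict[str, int] | None = None,
) -> list[BinRecord]:
    """Adapt CheckM's tab-separated quality output to :class:`BinRecord`.

    Expects at least ``Bin Id``, ``Completeness`` and ``Contamination``
    columns.  Taxonomy, mapped-read counts and bin sizes are supplied via
    the side mappings keyed by bin id (CheckM does not report them).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower().replace(" ", ""): c for c in df.columns}
    try:
        id_col = cols["binid"]
        comp_col = cols["completeness"]
        cont_col = cols["contamination"]
    except KeyError as exc:
        raise ValueError(f"CheckM table is missing column {exc}") from exc
    out = []
    for bid, comp, cont in df[[id_col, comp_col, cont_col]].itertuples(index=False, name=None):
        bid = str(bid)
        out.append(
            BinRecord(
                bin_id=bid,
                profile_id=profile_id,
                pipeline=pipeline,
                completeness=float(comp),
                contamination=float(cont),
                assigned_species=(species_map or {}).get(bid, UNASSIGNED),
                mapped_reads=(mapped_reads or {}).get(bid, 0),
                bin_size_bp=(bin_sizes or {}).get(bid, 1),
            )
        )
    return out


def metrics_panel(
    tables: list[RecoveryTable],
    profiles: dict[str, "object"],
) -> pd.DataFrame:
    """Long-format metric panel: one row per (profile, pipeline, metric).

    *profiles* maps profile_id to its :class:`~magbench.design.CommunityProfile`
    so design factors travel with each row.
    """
    rows = []
    for t in tables:
        prof = profiles[t.profile_id]
        base = {
            "profile_id": t.profile_id,
            "group": prof.group_label,
            "abundance_kind": prof.abundance_kind,
            "relatedness": prof.relatedness,
            "depth": prof.depth,
            "pipeline": t.pipeline,
        }
        metrics = {
            "tp": t.n_tp,
            "fn": t.n_fn,
            "fp_bins": t.n_fp_bins,
            "fp_species": t.n_fp_species,
            "accuracy": t.accuracy(),
        }
        for klass, frac in t.pair_recovery.items():
            metrics[f"pair_recovery_{klass}"] = frac
        for name, value in metrics.items():
            rows.append(base | {"metric": name, "value": value})
    return pd.DataFrame(rows)
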