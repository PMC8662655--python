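"""Sex-linkage classification of assembly scaffolds.

In a ZW system, females are hemizygous for Z-linked loci and are the
only carriers of the W.  With male (ZZ) and female (ZW) resequencing
data aligned to a female assembly, per-scaffold read coverage and
heterozygosity separate the chromosome classes:

- W-linked scaffolds attract only female reads (male coverage zero).
- Z-linked scaffolds show roughly half the female coverage relative to
  males, and a male-biased excess of heterozygous calls (hemizygous
  females cannot be heterozygous).
- Autosomes and the pseudoautosomal region (PAR) look the same in both
  sexes.

Coverage profiles are expected to be computed from mismatch-free
alignments (reads with zero mismatching bases), which sharpens the
male-coverage-zero signal on the W.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

VALID_SEXES = {"M", "F"}

W = "W"
Z = "Z"
AUTOSOME = "AUTOSOME"
UNASSIGNED = "UNASSIGNED"

ANCESTRAL = "ANCESTRAL"
ADDED = "ADDED"


@dataclass
class SampleObservation:
    """One sample's coverage/heterozygosity evidence on one scaffold."""

    sample_id: str
    sex: str  # 'M' or 'F'
    median_coverage: float
    heterozygosity: float

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(
                f"sample {self.sample_id!r}: sex must be 'M' or 'F', got {self.sex!r}"
            )
        if self.median_coverage < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative coverage")
        if not 0.0 <= self.heterozygosity <= 1.0:
            raise ValueError(f"sample {self.sample_id!r}: heterozygosity outside [0, 1]")


@dataclass
class ScaffoldProfile:
    scaffold_id: str
    length_bp: int
    samples: list[SampleObservation] = field(default_factory=list)

    def by_sex(self, sex: str) -> list[SampleObservation]:
        return [s for s in self.samples if s.sex == sex]


@dataclass
class ScaffoldCall:
    scaffold_id: str
    chrom_class: str  # W / Z / AUTOSOME / UNASSIGNED
    fem_median: float
    male_median: float
    cov_ratio: float | None
    het_diff: float
    rule_fired: str


@dataclass
class ClassifierConfig:
    """Thresholds of the coverage/heterozygosity classifier.

    Defaults reproduce the published decision rules literally, with
    strict inequalities: a W call needs female median coverage > 25x
    and male median coverage equal to zero; a Z call needs either a
    female/male coverage ratio < 0.55, or a ratio < 0.65 combined with
    an absolute male-female heterozygosity difference > 0.1.
    """

    w_fem_min: float = 25.0
    z_ratio_1: float = 0.55
    z_ratio_2: float = 0.65
    het_diff_min: float = 0.1
    male_zero_epsilon: float = 0.0  # tolerance for "male coverage is zero"
    summary: str = "median"  # per-sex summary of sample values: median or mean


def _summarise(values: Sequence[float], how: str) -> float:
    if how == "median":
        return float(statistics.median(values))
    if how == "mean":
        return float(statistics.mean(values))
    raise ValueError(f"unknown summary {how!r}")


def classify_scaffold(profile: ScaffoldProfile, cfg: ClassifierConfig | None = None) -> ScaffoldCall:
    """Classify a single scaffold. See :func:`classify_scaffolds`."""
    cfg = cfg or ClassifierConfig()
    males = profile.by_sex("M")
    females = profile.by_sex("F")
    if not males or not females:
        logger.warning(
            "scaffold %s: missing %s samples; UNASSIGNED",
            profile.scaffold_id,
            "male" if not males else "female",
        )
        return ScaffoldCall(profile.scaffold_id, UNASSIGNED, float("nan"),
                            float("nan"), None, float("nan"), "missing_sex")

    fem_median = _summarise([s.median_coverage for s in females], cfg.summary)
    male_median = _summarise([s.median_coverage for s in males], cfg.summary)
    het_f = _summarise([s.heterozygosity for s in females], cfg.summary)
    het_m = _summarise([s.heterozygosity for s in males], cfg.summary)
    het_diff = abs(het_m - het_f)

    male_is_zero = male_median <= cfg.male_zero_epsilon
    if male_is_zero and fem_median > cfg.w_fem_min:
        return ScaffoldCall(profile.scaffold_id, W, fem_median, male_median,
                            None, het_diff, "W:fem>%g,male=0" % cfg.w_fem_min)
    if male_is_zero:
        # No coverage ratio can be formed and the W rule did not fire.
        return ScaffoldCall(profile.scaffold_id, UNASSIGNED, fem_median,
                            male_median, None, het_diff, "male_zero_not_W")

    ratio = fem_median / male_median
    if ratio < cfg.z_ratio_1:
        return ScaffoldCall(profile.scaffold_id, Z, fem_median, male_median,
                            ratio, het_diff, "Z:ratio<%g" % cfg.z_ratio_1)
    if ratio < cfg.z_ratio_2 and het_diff > cfg.het_diff_min:
        return ScaffoldCall(
            profile.scaffold_id, Z, fem_median, male_median, ratio, het_diff,
            "Z:ratio<%g,het_diff>%g" % (cfg.z_ratio_2, cfg.het_diff_min))
    return ScaffoldCall(profile.scaffold_id, AUTOSOME, fem_median, male_median,
                        ratio, het_diff, "autosome_default")


def classify_scaffolds(
    profiles: Iterable[ScaffoldProfile], cfg: ClassifierConfig | None = None
) -> list[ScaffoldCall]:
    """Classify scaffolds as W, Z or autosomal from sex-stratified evidence.

    Evidence per scaffold is the per-sex summary (median by default) of
    per-sample median coverage and heterozygosity.  Rule precedence is
    W > Z > autosome; a scaffold with zero male coverage that fails the
    W rule is left unassigned because no coverage ratio can be formed.
    """
    return [classify_scaffold(p, cfg) for p in profiles]


# ---------------------------------------------------------------------------
# Ancestral vs. added region assignment from dual-reference homology ranges
# ---------------------------------------------------------------------------

@dataclass
class HomologyRange:
    """A scaffold range aligned to chromosomes of two outgroup references."""

    scaffold_id: str
    start: int  # 0-based half-open
    end: int
    target_a: str
    target_b: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.scaffold_id}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class HomologyConfig:
    min_range_bp: int = 10_000
    ancestral_targets: frozenset[str] = frozenset({"Z", "Z_random"})
    added_targets: frozenset[str] = frozenset({"4A", "4A_random"})
    unplaced_prefixes: tuple[str, ...] = ("scaffold", "chrUn", "un")


def _is_unplaced(name: str, cfg: HomologyConfig) -> bool:
    low = name.lower()
    return any(low.startswith(p.lower()) for p in cfg.unplaced_prefixes)


def _region_vote(target: str, cfg: HomologyConfig) -> str | None:
    """ANCESTRAL / ADDED / None (unplaced) for one reference target."""
    if target in cfg.ancestral_targets:
        return ANCESTRAL
    if target in cfg.added_targets:
        return ADDED
    if _is_unplaced(target, cfg):
        return None
    return UNASSIGNED


def assign_region_homology(
    ranges: Iterable[HomologyRange], cfg: HomologyConfig | None = None
) -> list[tuple[HomologyRange, str]]:
    """Assign scaffold ranges to the ancestral vs. added sex-chromosome region.

    A range belongs to the ancestral region if it aligns to chromosome Z
    (or Z_random) in both references, or to Z in one and an unplaced
    scaffold in the other; analogously for the added region with
    chromosome 4A.  Conflicting placements (Z in one reference, 4A in
    the other) are left unassigned.  Ranges shorter than
    ``cfg.min_range_bp`` are dropped from the output.
    """
    cfg = cfg or HomologyConfig()
    out: list[tuple[HomologyRange, str]] = []
    for rng in ranges:
        if rng.length < cfg.min_range_bp:
            logger.debug("range %s:%d-%d shorter than %d bp; ignored",
                         rng.scaffold_id, rng.start, rng.end, cfg.min_range_bp)
            continue
        vote_a = _region_vote(rng.target_a, cfg)
        vote_b = _region_vote(rng.target_b, cfg)
        votes = {v for v in (vote_a, vote_b) if v is not None}
        if votes in ({ANCESTRAL}, {ADDED}):
            region = votes.pop()
        else:
            # contradiction, both unplaced, or a target that is neither
            # a sex-chromosome name nor unplaced
            if ANCESTRAL in votes and ADDED in votes:
                logger.info("range %s:%d-%d has conflicting targets (%s / %s)",
                            rng.scaffold_id, rng.start, rng.end,
                            rng.target_a, rng.target_b)
            region = UNASSIGNED
        out.append((rng, region))
    return out


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_profiles_tsv(path: str) -> list[ScaffoldProfile]:
    """Read per-sample scaffold profiles.

    Columns: scaffold_id, length, sample_id, sex, median_coverage,
    heterozygosity.  Coverage values are assumed to come from
    mismatch-free alignments (the caller's responsibility).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"scaffold_id", "length", "sample_id", "sex",
                "median_coverage", "heterozygosity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    profiles: dict[str, ScaffoldProfile] = {}
    for row in df.itertuples(index=False):
        prof = profiles.setdefault(
            row.scaffold_id, ScaffoldProfile(row.scaffold_id, int(row.length)))
        prof.samples.append(SampleObservation(
            str(row.sample_id), str(row.sex),
            float(row.median_coverage), float(row.heterozygosity)))
    return list(profiles.values())


def calls_to_frame(calls: Iterable[ScaffoldCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.scaffold_id, c.chrom_class, c.fem_median, c.male_median,
          c.cov_ratio, c.het_diff, c.rule_fired) for c in calls],
        columns=["scaffold_id", "class", "fem_median", "male_median",
                 "cov_ratio", "het_diff", "rule_fired"],
    )


def read_homology_tsv(path: str) -> list[HomologyRange]:
    """BED-like TSV: scaffold_id, start, end, target_a, target_b (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["scaffold_id", "start", "end", "target_a", "target_b"],
                     header=0 if _has_header(path) else None)
    return [HomologyRange(str(r.scaffold_id), int(r.start), int(r.end),
                          str(r.target_a), str(r.target_b))
            for r in df.itertuples(index=False)]


def _has_header(path: str) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            return not (len(fields) >= 3 and fields[1].isdigit())
    return False
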