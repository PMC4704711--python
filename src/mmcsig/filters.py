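"""Strain-specific variant filtering, substitution spectra, and lethal candidates.

Reproduces the cohort-level post-processing applied to caller output from a
mutagenised multi-strain cohort: a variant is attributed to the mutagen when
it is homozygous in exactly one strain, absent from the composite parental,
and adequately covered.  Retained SNVs are pooled into a six-class
complementary-base-pair substitution spectrum; deletions are additionally
screened against homopolymer artifacts; heterozygous strain-unique deletions
inside a genetically mapped interval are candidate balancer-maintained
lethals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2_contingency

logger = logging.getLogger(__name__)

__all__ = [
    "SnvRecord",
    "DeletionRecord",
    "SpectrumCounts",
    "ChisqResult",
    "SPECTRUM_CLASSES",
    "call_zygosity",
    "filter_strain_specific_snvs",
    "filter_strain_specific_deletions",
    "classify_snv_spectrum",
    "compare_spectra_chisq",
    "identify_lethal_candidates",
    "reciprocal_overlap",
]

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnvRecord:
    """One single-nucleotide variant observation in one strain."""

    strain: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    depth: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref == alt")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"bases must be in ACGT, got {self.ref}>{self.alt}")
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError("need 0 <= alt_reads <= depth")


@dataclass(frozen=True)
class DeletionRecord:
    """One deletion call in one strain, with read-count evidence."""

    strain: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    depth: int
    supporting_reads: int
    zygosity_call: str = "ambiguous"  # {hom, het, ref, ambiguous}

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start > end")
        if not 0 <= self.supporting_reads <= self.depth:
            raise ValueError("need 0 <= supporting_reads <= depth")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: Six complementary-base-pair substitution classes.  A substitution and its
#: reverse complement fall in the same class (G>A and C>T are both G:C>A:T).
SPECTRUM_CLASSES: tuple[str, ...] = (
    "G:C>C:G",
    "A:T>C:G",
    "A:T>G:C",
    "G:C>T:A",
    "A:T>T:A",
    "G:C>A:T",
)

_CLASS_OF: dict[tuple[str, str], str] = {
    ("G", "C"): "G:C>C:G", ("C", "G"): "G:C>C:G",
    ("A", "C"): "A:T>C:G", ("T", "G"): "A:T>C:G",
    ("A", "G"): "A:T>G:C", ("T", "C"): "A:T>G:C",
    ("G", "T"): "G:C>T:A", ("C", "A"): "G:C>T:A",
    ("A", "T"): "A:T>T:A", ("T", "A"): "A:T>T:A",
    ("G", "A"): "G:C>A:T", ("C", "T"): "G:C>A:T",
}


@dataclass
class SpectrumCounts:
    """Counts per substitution class; total equals the number classified."""

    counts: dict[str, int] = field(default_factory=lambda: {c: 0 for c in SPECTRUM_CLASSES})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_array(self) -> np.ndarray:
        return np.array([self.counts[c] for c in SPECTRUM_CLASSES], dtype=np.int64)

    @classmethod
    def from_array(cls, arr: Sequence[int]) -> "SpectrumCounts":
        arr = list(arr)
        if len(arr) != len(SPECTRUM_CLASSES):
            raise ValueError(f"expected {len(SPECTRUM_CLASSES)} class counts")
        if any(int(v) < 0 for v in arr):
            raise ValueError("class counts must be non-negative")
        return cls(counts={c: int(v) for c, v in zip(SPECTRUM_CLASSES, arr)})


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    p_value: float
    low_expected: bool  # any expected cell count < 5


# ---------------------------------------------------------------------------
# zygosity
# ---------------------------------------------------------------------------

def call_zygosity(
    depth: int,
    variant_reads: int,
    hom_threshold: float = 0.90,
    het_band: tuple[float, float] = (0.35, 0.65),
    ref_threshold: float = 0.10,
) -> str:
    """Classify a site from read counts as hom / het / ref / ambiguous.

    Homozygous when the variant-read fraction is >= ``hom_threshold``
    (inclusive, matching the 0.9 caller parameter); heterozygous within
    ``het_band`` (operationalising "approximately 50%"); reference when
    <= ``ref_threshold``; anything between the bands is ambiguous.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0 <= variant_reads <= depth:
        raise ValueError("need 0 <= variant_reads <= depth")
    f = variant_reads / depth
    if f >= hom_threshold:
        return "hom"
    if het_band[0] <= f <= het_band[1]:
        return "het"
    if f <= ref_threshold:
        return "ref"
    return "ambiguous"


# ---------------------------------------------------------------------------
# strain-specific SNVs
# ---------------------------------------------------------------------------

def filter_strain_specific_snvs(
    cohort: Mapping[str, Sequence[SnvRecord]],
    parental: Sequence[SnvRecord] = (),
    min_depth: int = 8,
    hom_threshold: float = 0.90,
) -> dict[str, list[SnvRecord]]:
    """Retain SNVs homozygous in exactly one cohort strain and absent elsewhere.

    A record is retained when it (i) is homozygous per :func:`call_zygosity`,
    (ii) has depth >= ``min_depth`` (strictly more than seven overlapping
    reads at the default), (iii) its (chrom, pos, alt) key is homozygous in no
    other cohort strain, and (iv) the key is absent (not homozygous) in the
    composite parental.  Malformed records are rejected per record with a
    logged reason, never aborting the cohort.
    """
    if len(cohort) < 2:
        raise ValueError("cohort must contain at least two strains")

    def hom_keys(records: Iterable[SnvRecord]) -> set[tuple[str, int, str]]:
        keys = set()
        for r in records:
            try:
                if call_zygosity(r.depth, r.alt_reads, hom_threshold=hom_threshold) == "hom":
                    keys.add((r.chrom, r.pos, r.alt))
            except ValueError as exc:
                logger.debug("rejecting parental/cohort record %r: %s", r, exc)
        return keys

    parental_keys = hom_keys(parental)
    strain_hom: dict[str, set[tuple[str, int, str]]] = {
        s: hom_keys(records) for s, records in cohort.items()
    }
    # keys homozygous in more than one strain are excluded everywhere
    seen: dict[tuple[str, int, str], int] = {}
    for keys in strain_hom.values():
        for key in keys:
            seen[key] = seen.get(key, 0) + 1

    out: dict[str, list[SnvRecord]] = {s: [] for s in cohort}
    for strain, records in cohort.items():
        for r in records:
            try:
                zyg = call_zygosity(r.depth, r.alt_reads, hom_threshold=hom_threshold)
            except ValueError as exc:
                logger.debug("rejecting %s record at %s:%d: %s", strain, r.chrom, r.pos, exc)
                continue
            key = (r.chrom, r.pos, r.alt)
            if zyg != "hom":
                continue
            if r.depth < min_depth:
                logger.debug("depth filter: %s %s:%d depth=%d < %d", strain, r.chrom, r.pos, r.depth, min_depth)
                continue
            if seen.get(key, 0) > 1:
                logger.debug("shared across strains: %s %s:%d", strain, r.chrom, r.pos)
                continue
            if key in parental_keys:
                logger.debug("present in parental: %s %s:%d", strain, r.chrom, r.pos)
                continue
            out[strain].append(r)
    return out


# ---------------------------------------------------------------------------
# strain-specific deletions
# ---------------------------------------------------------------------------

def reciprocal_overlap(a: DeletionRecord, b: DeletionRecord) -> float:
    """Fraction of reciprocal overlap between two deletions (0 when disjoint).

    Returns ``min(olap/len(a), olap/len(b))`` so both events must be mostly
    covered for a high value.
    """
    if a.chrom != b.chrom:
        return 0.0
    olap = min(a.end, b.end) - max(a.start, b.start) + 1
    if olap <= 0:
        return 0.0
    return min(olap / a.length, olap / b.length)


def _is_homopolymer_artifact(rec: DeletionRecord, seqs: Mapping[str, str], run_threshold: int) -> bool:
    """True when the deleted segment sits inside a single-base reference run of
    length >= ``run_threshold`` — the classic indel-caller artifact context."""
    seq = seqs[rec.chrom]
    deleted = seq[rec.start - 1: rec.end].upper()
    if len(set(deleted)) != 1:
        return False
    base = deleted[0]
    i = rec.start - 1
    while i > 0 and seq[i - 1].upper() == base:
        i -= 1
    j = rec.end
    while j < len(seq) and seq[j].upper() == base:
        j += 1
    return (j - i) >= run_threshold


def filter_strain_specific_deletions(
    cohort: Mapping[str, Sequence[DeletionRecord]],
    parental: Sequence[DeletionRecord] = (),
    genome=None,
    homopolymer_run: int = 6,
    min_overlap: float = 0.8,
    hom_threshold: float = 0.90,
    het_band: tuple[float, float] = (0.35, 0.65),
) -> dict[str, list[DeletionRecord]]:
    """Retain homozygous deletions unique to one strain and outside homopolymers.

    Uniqueness uses a keyed match: two deletions are "the same event" when
    they share a chromosome and overlap reciprocally by >= ``min_overlap``
    (exact-coordinate matching is too strict against caller jitter).  Events
    matching the composite parental are removed.  When a ``genome`` (mapping
    or object with ``.sequences``) is supplied, deletions whose segment lies
    inside a single-base run of length >= ``homopolymer_run`` are rejected,
    and records with coordinates outside the reference are rejected with a
    logged reason.

    Zygosity is (re)called from read counts; the returned records carry the
    resulting ``zygosity_call``.  Only homozygous events pass.
    """
    seqs = None
    if genome is not None:
        seqs = genome.sequences if hasattr(genome, "sequences") else genome

    called: dict[str, list[DeletionRecord]] = {}
    for strain, records in cohort.items():
        kept = []
        for r in records:
            if seqs is not None:
                if r.chrom not in seqs or r.end > len(seqs[r.chrom]) or r.start < 1:
                    logger.debug("coordinates outside reference: %s %s:%d-%d", strain, r.chrom, r.start, r.end)
                    continue
            try:
                zyg = call_zygosity(
                    r.depth, r.supporting_reads, hom_threshold=hom_threshold, het_band=het_band
                )
            except ValueError as exc:
                logger.debug("rejecting %s deletion %s:%d-%d: %s", strain, r.chrom, r.start, r.end, exc)
                continue
            kept.append(replace(r, zygosity_call=zyg))
        called[strain] = kept

    out: dict[str, list[DeletionRecord]] = {s: [] for s in cohort}
    for strain, records in called.items():
        others = [r for s, recs in called.items() if s != strain for r in recs]
        for r in records:
            if r.zygosity_call != "hom":
                continue
            if any(reciprocal_overlap(r, o) >= min_overlap for o in others):
                logger.debug("shared across strains: %s %s:%d-%d", strain, r.chrom, r.start, r.end)
                continue
            if any(reciprocal_overlap(r, p) >= min_overlap for p in parental):
                logger.debug("present in parental: %s %s:%d-%d", strain, r.chrom, r.start, r.end)
                continue
            if seqs is not None and _is_homopolymer_artifact(r, seqs, homopolymer_run):
                logger.debug("homopolymer artifact: %s %s:%d-%d", strain, r.chrom, r.start, r.end)
                continue
            out[strain].append(r)
    return out


# ---------------------------------------------------------------------------
# substitution spectrum
# ---------------------------------------------------------------------------

def classify_snv_spectrum(snvs: Iterable[SnvRecord]) -> SpectrumCounts:
    """Tally pooled SNVs into the six complementary-base-pair classes."""
    spectrum = SpectrumCounts()
    for r in snvs:
        cls = _CLASS_OF.get((r.ref, r.alt))
        if cls is None:  # unreachable for validated records; belt and braces
            logger.debug("unclassifiable substitution %s>%s", r.ref, r.alt)
            continue
        spectrum.counts[cls] += 1
    return spectrum


def compare_spectra_chisq(counts_a: SpectrumCounts, counts_b: SpectrumCounts) -> ChisqResult:
    """Pearson chi-square comparison of two substitution spectra.

    Builds the 2x6 contingency table of class counts; classes empty in both
    spectra are dropped (with df reduced accordingly).  ``low_expected`` warns
    when any expected count is below 5, where the asymptotic p-value is
    unreliable.
    """
    a, b = counts_a.as_array(), counts_b.as_array()
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("cannot compare a spectrum with zero total")
    table = np.vstack([a, b])
    nonzero = table.sum(axis=0) > 0
    table = table[:, nonzero]
    if table.shape[1] < 2:
        raise ValueError("fewer than two non-empty classes; comparison undefined")
    stat, p, df, expected = chi2_contingency(table, correction=False)
    return ChisqResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        low_expected=bool((expected < 5).any()),
    )


# ---------------------------------------------------------------------------
# lethal candidates
# ---------------------------------------------------------------------------

def identify_lethal_candidates(
    deletions: Sequence[DeletionRecord],
    mapped_interval: tuple[str, int, int],
    cohort: Mapping[str, Sequence[DeletionRecord]] | None = None,
    min_overlap: float = 0.8,
) -> list[DeletionRecord]:
    """Candidate balancer-maintained lethal deletions for one strain.

    A candidate must (1) be heterozygous — the balancer keeps the lethal as a
    het, so supporting reads sit near 50%; (2) overlap the physical interval
    implied by three-factor mapping; (3) be unique to the strain within the
    cohort (reciprocal-overlap keyed match).
    """
    chrom, lo, hi = mapped_interval
    if lo > hi:
        raise ValueError(f"empty mapped interval {chrom}:{lo}-{hi}")
    strain = deletions[0].strain if deletions else None
    others: list[DeletionRecord] = []
    if cohort is not None:
        others = [r for s, recs in cohort.items() if s != strain for r in recs]
    out = []
    for r in deletions:
        if r.zygosity_call != "het":
            continue
        if r.chrom != chrom or r.end < lo or r.start > hi:
            continue
        if any(reciprocal_overlap(r, o) >= min_overlap for o in others):
            continue
        out.append(r)
    return out
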