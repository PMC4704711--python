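"""Bundled reference measurements from a mitomycin-C balancer screen.

These small tables — forward-screen tallies, the mapped lethal deletions with
their reported sizes and coordinates, the deletion junction sequences, and
cohort-level SNV totals — are the fixed inputs for the package's self-test
report and for validating the arithmetic of each operation against known
values.  In junction strings, lowercase letters are the deleted segment and
uppercase letters the flanking reference sequence; junctions of large
deletions print only the first and last five deleted bases
(``is_full = False``) with the hidden middle length implied by ``size``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .context import DeletionContext
from .screen import ScreenTally

__all__ = [
    "Junction",
    "DeletionLocus",
    "screen_tallies",
    "deletion_loci",
    "junctions",
    "MAPPING_ZONE_COUNTS",
    "MARKER_POSITIONS",
    "COHORT_SNV_TOTALS",
]


@dataclass(frozen=True)
class DeletionLocus:
    """A mapped lethal deletion: reported size plus physical coordinates."""

    allele: str
    reported_size: int  # bp, as reported
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive

    @property
    def coordinate_size(self) -> int:
        return self.end - self.start + 1

    @property
    def consistent(self) -> bool:
        """Whether the reported size agrees with the coordinate span."""
        return self.reported_size == self.coordinate_size


@dataclass(frozen=True)
class Junction:
    """One deletion junction: flanks plus deleted sequence (possibly partial)."""

    allele: str
    size: int           # deleted length, bp
    left_flank: str     # uppercase reference, 5' of the deletion
    deleted_prefix: str  # lowercase in the source notation
    deleted_suffix: str
    right_flank: str
    is_full: bool       # deleted segment printed in full

    @property
    def deleted(self) -> str:
        if not self.is_full:
            raise ValueError(f"junction {self.allele} ({self.size} bp) is not printed in full")
        return self.deleted_prefix

    def context(self) -> DeletionContext:
        """A :class:`DeletionContext` on placeholder coordinates (full junctions only)."""
        return DeletionContext(
            chrom=self.allele, start=1_000_001, end=1_000_000 + self.size,
            deleted_seq=self.deleted, left_flank=self.left_flank, right_flank=self.right_flank,
        )


def screen_tallies() -> list[tuple[ScreenTally, float]]:
    """Forward-screen tallies with the reported one-decimal frequency (%)."""
    rows = [
        ("1", 750, 437, 24, 5.5),
        ("1", 750, 550, 25, 4.5),
        ("1", 750, 436, 24, 5.5),
        ("2", 375, 145, 3, 2.1),
        ("2", 750, 580, 13, 2.2),
        ("2", 1400, 145, 1, 0.7),
    ]
    return [
        (ScreenTally(n_f1=n_f1, n_lethal=n_let, dose=dose, batch=batch), freq)
        for batch, dose, n_f1, n_let, freq in rows
    ]


def deletion_loci() -> list[DeletionLocus]:
    """The seven mapped lethal deletions on chromosome I.

    Two entries (h2718, h2787) have reported sizes that disagree with their
    own coordinate spans (21 vs 23 bp and 15,059 vs 15,061 bp); they are kept
    verbatim and flagged via :attr:`DeletionLocus.consistent`, never silently
    corrected.
    """
    rows = [
        ("h2717", 318_826, "I", 753_745, 1_072_570),
        ("h2727", 2_382, "I", 1_742_835, 1_745_216),
        ("h2733", 8, "I", 1_833_730, 1_833_737),
        ("h2758", 4_962, "I", 2_100_906, 2_105_867),
        ("h2718", 21, "I", 2_897_024, 2_897_046),
        ("h2787", 15_059, "I", 5_112_626, 5_127_686),
        ("h2755", 4_877, "I", 6_175_541, 6_180_417),
    ]
    return [DeletionLocus(*row) for row in rows]


def _full(allele: str, size: int, left: str, deleted: str, right: str) -> Junction:
    assert len(deleted) == size, (allele, size, deleted)
    return Junction(allele, size, left, deleted, deleted, right, is_full=True)


def _partial(allele: str, size: int, left: str, prefix: str, suffix: str, right: str) -> Junction:
    return Junction(allele, size, left, prefix, suffix, right, is_full=False)


def junctions() -> list[Junction]:
    """The 29 genome-wide deletion junctions, smallest to largest."""
    return [
        _full("h2727", 2, "TTCTTTTCATTTCTC", "ta", "TGTTTGCCTATCACT"),
        _full("h2758", 4, "TAATTTCACTGGAA", "tcat", "TGTCTTCCTTATCAC"),
        _full("h2718", 4, "ATCCAATTTTCCGC", "cgcg", "CAGTCGCCAAAAAGG"),
        _full("h2755", 5, "TAAATGACTACT", "gtaac", "GCTTGTGTCGATTTA"),
        _full("h2718", 5, "TTCTAGGCATAT", "attgc", "GAAATATCTTTATAA"),
        _full("h2718", 5, "CTTGCGTGGGACCA", "gtcgt", "GTGGTCGAAACAGAC"),
        _full("h2718", 5, "CAAATTGGAATGCTG", "ccgaa", "CTCTTGCCCATGTCT"),
        _full("h2733", 6, "TTTGGAGCTGTCGA", "cacgtt", "CCGCGCCGCACTATA"),
        _full("h2733", 7, "CATAAATCGCAAA", "ctgcgtt", "CTTCAGCAACAATAT"),
        _full("h2733", 8, "ATTTTCTGGTGAGTG", "acgcgata", "AAATCAATATTTTCT"),
        _full("h2787", 8, "ATATTCGTGAAGA", "cattgttc", "CAACGCTGCACAATT"),
        _full("h2718", 9, "GTGACCTTAAGAA", "gaacgagat", "GAGATGGAGAGTTGA"),
        _full("h2787", 10, "TCCAACACAGAGA", "tgccgtagcg", "TGCAAATTAGGCTTT"),
        _full("h2718", 13, "ACTGCATCTG", "gaattccgatatc", "GATTTCACGATCGAA"),
        _full("h2727", 22, "AAA", "accacgcaggcgacgcctacat", "ACCACGCAGGCAGCC"),
        _full("h2718", 21, "GAC", "tcctcagcttcagcagaatac", "TCCTCAGCTTCAGCAGAATATCCATG"),
        _partial("h2727", 58, "CTTTTATACGTAACC", "tttcc", "ataaa", "TGAAAAATTGCTTCC"),
        _partial("h2733", 77, "GACGACGACGAGGAA", "ccccc", "aaagc", "ACCACGTGGAGATTA"),
        _partial("h2744", 104, "TGTTTCAAAATATAC", "atctg", "ctaat", "ATAAATATCCATGCC"),
        _partial("h2717", 165, "AG", "tgccaacaacaatgtattc", "caacaatca", "TGCCAACAACAATGC"),
        _partial("h2717", 331, "GAGGAAAAGGATAAC", "acatt", "aaaaa", "TCGCAAAAAACGCAT"),
        _partial("h2727", 394, "TGGTTCGGCCAATGA", "atttt", "ctcag", "TGTTTACGGTTTATA"),
        _partial("h2733", 1_003, "ATAGAGAATATACGG", "tatgc", "gcaat", "TATCAGATTTCTTGT"),
        _partial("h2727", 2_382, "ACATTCCTTTTCCGG", "ggccg", "tcatt", "TTTACGCCTGTCAG"),
        _partial("h2755", 4_877, "CCTCATTTTGTGTGT", "taatt", "ttaat", "TCACTATAATCCAAA"),
        _partial("h2758", 4_962, "AATATCTTCAAGCCG", "tcttc", "atcac", "CATTAAATTATTAGT"),
        _partial("h2755", 13_671, "ATCCCACTTTGTAGA", "agaac", "ggagt", "TCCAAAGAGTCATGC"),
        _partial("h2787", 15_059, "GACAATTCGAGAGAA", "agaat", "ttgtg", "TTTGCGGAGTCGCAT"),
        _partial("h2717", 318_826, "CGTGAGTCGTTCCGA", "ttggc", "ttcgt", "AGATAAAACTATTA"),
    ]


#: Chromosome-I lethals partitioned against the dpy-5 / unc-13 marker pair:
#: (left of dpy-5, between, right of unc-13).
MAPPING_ZONE_COUNTS: tuple[int, int, int] = (10, 1, 10)

#: Marker map positions (map units) on chromosome I.
MARKER_POSITIONS: dict[str, float] = {"dpy-5": 0.00, "unc-13": 2.07}

#: Pooled strain-specific homozygous SNV totals per 10-strain cohort.
COHORT_SNV_TOTALS: dict[str, int] = {"mmc": 245, "spontaneous": 391, "ems": 1965}
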