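"""Sequence context of deletions: lengths, flanks, dinucleotide profiles, microhomology.

Coordinates are 1-based inclusive throughout; conversion to 0-based half-open
happens only at the BED/VCF boundary (see :mod:`mmcsig.io`).

The analyses here characterise the footprint an interstrand-crosslinking
mutagen leaves behind: an excess of 5'-CpG-3' dinucleotides inside deleted
segments relative to the genomic background, and short stretches of identical
sequence (microhomology) shared between a deletion junction's two sides — the
hallmark of repair by alternative non-homologous end joining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DINUCLEOTIDES",
    "DeletionContext",
    "DinucProfile",
    "MicrohomologyResult",
    "deletion_length",
    "extract_flanks",
    "dinucleotide_profile",
    "fold_enrichment",
    "heatmap_matrix",
    "microhomology",
    "longest_common_prefix",
    "longest_common_suffix",
]

#: The 16 ordered dinucleotides, alphabetical; column order of every profile.
DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in "ACGT" for b in "ACGT")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class DeletionContext:
    """A deleted segment with its immediately adjacent flanks.

    ``left_flank`` ends at ``start - 1`` and ``right_flank`` begins at
    ``end + 1``; there is never a gap.  Flanks may be shorter than requested
    when the deletion sits near a chromosome end.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    deleted_seq: str
    left_flank: str
    right_flank: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if len(self.deleted_seq) != self.end - self.start + 1:
            raise ValueError(
                "deleted_seq length does not match coordinates: "
                f"{len(self.deleted_seq)} vs {self.end - self.start + 1}"
            )


@dataclass
class DinucProfile:
    """Proportions of the 16 overlapping dinucleotides in a set of sequences.

    ``n_windows`` counts the length-2 windows actually tallied (windows that
    contain an N are skipped; windows never span sequence boundaries).  When
    ``n_windows`` is zero the proportions are undefined and ``defined`` is
    False.
    """

    proportions: np.ndarray  # shape (16,), ordered as DINUCLEOTIDES
    n_windows: int
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def defined(self) -> bool:
        return self.n_windows > 0

    def proportion(self, dinuc: str) -> float:
        return float(self.proportions[DINUCLEOTIDES.index(dinuc.upper())])

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(DINUCLEOTIDES))


@dataclass(frozen=True)
class MicrohomologyResult:
    """Junction microhomology measured on both alt-NHEJ-consistent alignments.

    ``five_prime_len``: longest common prefix of the deleted segment and the
    right flank.  ``three_prime_len``: longest common suffix of the deleted
    segment and the left flank.  ``mh`` is the larger of the two.
    """

    five_prime_len: int
    three_prime_len: int

    @property
    def mh(self) -> int:
        return max(self.five_prime_len, self.three_prime_len)


# ---------------------------------------------------------------------------
# lengths and flanks
# ---------------------------------------------------------------------------

def deletion_length(start: int, end: int) -> int:
    """Size in bp of a deletion given 1-based inclusive endpoints."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    return end - start + 1


def extract_flanks(genome, chrom: str, start: int, end: int, k: int = 15) -> DeletionContext:
    """Extract the deleted segment and its ``k``-nt flanks from a genome.

    Flanks are truncated (not padded) at chromosome ends.  ``genome`` is any
    mapping of chromosome name to sequence string, or an object with a
    ``sequences`` mapping attribute (e.g. :class:`mmcsig.simulate.Genome`).
    """
    seqs = genome.sequences if hasattr(genome, "sequences") else genome
    if chrom not in seqs:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = seqs[chrom]
    if k < 0:
        raise ValueError("flank length k must be >= 0")
    if start < 1 or end > len(seq) or start > end:
        raise ValueError(
            f"interval {chrom}:{start}-{end} outside chromosome of length {len(seq)}"
        )
    left = seq[max(0, start - 1 - k): start - 1]
    deleted = seq[start - 1: end]
    right = seq[end: end + k]
    return DeletionContext(chrom, start, end, deleted, left, right)


# ---------------------------------------------------------------------------
# dinucleotide tallies
# ---------------------------------------------------------------------------

def _dinuc_counts(seq: str) -> np.ndarray:
    """Counts of overlapping dinucleotide windows in one sequence.

    Windows containing a base outside ACGT (N or other ambiguity codes) are
    skipped; comparison is case-insensitive.
    """
    counts = np.zeros(16, dtype=np.int64)
    s = seq.upper()
    if len(s) < 2:
        return counts
    codes = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int8)
    for base, code in _BASE_CODE.items():
        lut[ord(base)] = code
    c = lut[codes]
    first, second = c[:-1], c[1:]
    ok = (first >= 0) & (second >= 0)
    idx = first[ok].astype(np.int64) * 4 + second[ok]
    np.add.at(counts, idx, 1)
    return counts


def dinucleotide_profile(sequences: Iterable[str] | str) -> DinucProfile:
    """Pooled overlapping-dinucleotide proportions over a set of sequences.

    Tallies are pooled across all sequences before proportions are computed,
    so every window counts equally regardless of which sequence it came from.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.zeros(16, dtype=np.int64)
    for seq in sequences:
        counts += _dinuc_counts(seq)
    n = int(counts.sum())
    props = counts / n if n > 0 else np.full(16, np.nan)
    return DinucProfile(proportions=props, n_windows=n, counts=counts)


def fold_enrichment(target: DinucProfile, background: DinucProfile, dinuc: str = "CG") -> float:
    """Ratio of a dinucleotide's proportion in target vs background.

    The canonical use is CG (the 5'-CpG-3' crosslink target) in deleted
    segments versus the whole-genome background.
    """
    if not target.defined or not background.defined:
        raise ValueError("cannot compute enrichment from an empty profile")
    bg = background.proportion(dinuc)
    if bg <= 0:
        raise ValueError(f"background proportion of {dinuc} is zero")
    return target.proportion(dinuc) / bg


def heatmap_matrix(
    deleted: Sequence[str],
    left_flanks: Sequence[str],
    right_flanks: Sequence[str],
    background: Sequence[str] | str,
) -> pd.DataFrame:
    """4x16 matrix of dinucleotide proportions for the four region classes.

    Rows: deleted segments, left flanks, right flanks, genomic background;
    columns: the 16 ordered dinucleotides.  Each row sums to 1.  This is the
    tabular form of the region-class heatmap; rendering is optional (see
    :func:`plot_heatmap`).
    """
    if len(deleted) == 0:
        raise ValueError("empty deletion set")
    rows = {
        "deleted": dinucleotide_profile(deleted),
        "left_flank": dinucleotide_profile(left_flanks),
        "right_flank": dinucleotide_profile(right_flanks),
        "background": dinucleotide_profile(background),
    }
    return pd.DataFrame(
        {name: prof.proportions for name, prof in rows.items()},
        index=list(DINUCLEOTIDES),
    ).T


def plot_heatmap(matrix: pd.DataFrame, path: str | None = None):
    """Render the region-class dinucleotide matrix (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 2.6))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdYlGn")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="proportion")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# ---------------------------------------------------------------------------
# junction microhomology
# ---------------------------------------------------------------------------

def longest_common_prefix(a: str, b: str, cap: int | None = None) -> int:
    """Length of the longest case-insensitive common prefix of two strings."""
    a, b = a.upper(), b.upper()
    limit = min(len(a), len(b))
    if cap is not None:
        limit = min(limit, cap)
    i = 0
    while i < limit and a[i] == b[i]:
        i += 1
    return i


def longest_common_suffix(a: str, b: str, cap: int | None = None) -> int:
    """Length of the longest case-insensitive common suffix of two strings."""
    a, b = a.upper(), b.upper()
    limit = min(len(a), len(b))
    if cap is not None:
        limit = min(limit, cap)
    i = 0
    while i < limit and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def microhomology(ctx: DeletionContext, cap: int = 25) -> MicrohomologyResult:
    """Junction microhomology of a deletion.

    Two alignments are consistent with end-joining across the junction: the
    deleted segment's 5' end repeated at the start of the right flank, and its
    3' end repeated at the end of the left flank.  Both are scored
    (case-insensitively) and the maximum reported, each capped at ``cap`` and
    at the lengths actually available.
    """
    if not ctx.deleted_seq:
        raise ValueError("deleted_seq is empty")
    five = longest_common_prefix(ctx.deleted_seq, ctx.right_flank, cap=cap)
    three = longest_common_suffix(ctx.deleted_seq, ctx.left_flank, cap=cap)
    return MicrohomologyResult(five_prime_len=five, three_prime_len=three)
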