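"""File formats: FASTA, minimal VCF, TSV dialects, BED, bedGraph-like tracks.

Internal coordinates are 1-based inclusive everywhere; conversion happens
only here, at the BED (0-based half-open) and VCF (left-anchored) boundaries.
FASTA goes through Biopython; VCF reading goes through pysam.  The "minimal
VCF" written here is the 8 fixed columns with DP (total depth) and VR
(variant/supporting reads) in INFO, one file per strain.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .breakpoints import DepthTrack
from .filters import DeletionRecord, SnvRecord
from .screen import BroodCount
from .simulate import Genome, TruthDeletion, TruthSet, TruthSnv

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_fasta",
    "write_fasta",
    "write_variant_vcf",
    "parse_variant_table",
    "write_snv_tsv",
    "write_deletion_tsv",
    "read_snv_tsv",
    "read_deletion_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_truth_bed",
    "write_depth_track",
    "read_depth_track",
    "write_broods",
    "read_broods",
]


class ParseError(ValueError):
    """Malformed input, annotated with the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> Genome:
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ParseError(path, 0, "no FASTA records found")
    return Genome(sequences=records)


def write_fasta(genome: Genome, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=mmcsig
##strain={strain}
{contigs}##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=VR,Number=1,Type=Integer,Description="Variant-supporting read depth">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Event type for non-SNV records">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variant_vcf(
    snvs: Sequence[SnvRecord],
    deletions: Sequence[DeletionRecord],
    path,
    genome: Genome,
    strain: str,
) -> None:
    """Write one strain's SNVs and deletions as a minimal VCF.

    Deletions use the left-anchored convention: POS is the base before the
    deleted segment, REF spans anchor + deleted sequence, ALT is the anchor.
    Records are sorted by position.
    """
    contigs = "".join(
        f"##contig=<ID={name},length={len(seq)}>\n" for name, seq in genome.sequences.items()
    )
    rows: list[tuple[str, int, str]] = []
    for r in snvs:
        info = f"DP={r.depth};VR={r.alt_reads}"
        rows.append((r.chrom, r.pos, f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}"))
    for r in deletions:
        if r.start < 2:
            raise ValueError("cannot left-anchor a deletion starting at position 1")
        anchor_pos = r.start - 1
        ref = genome.fetch(r.chrom, anchor_pos, r.end)
        alt = ref[0]
        info = f"DP={r.depth};VR={r.supporting_reads};SVTYPE=DEL"
        rows.append((r.chrom, anchor_pos, f"{r.chrom}\t{anchor_pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}"))
    rows.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(strain=strain, contigs=contigs))
        for _, _, line in rows:
            fh.write(line + "\n")


def _vcf_strain(header_text: str, path) -> str:
    for line in header_text.splitlines():
        if line.startswith("##strain="):
            return line.split("=", 1)[1]
    return Path(path).stem


def parse_variant_table(path, dialect: str = "vcf-min", strain: str | None = None):
    """Read a variant table into SNV and deletion records.

    ``dialect`` is ``"vcf-min"`` (the minimal VCF written by
    :func:`write_variant_vcf`, read through pysam) or ``"tsv"`` (the TSV
    dialects of :func:`write_snv_tsv` / :func:`write_deletion_tsv`; the file's
    columns decide which).  VCF deletion notation (REF ``ATTT``, ALT ``A``)
    maps to 1-based inclusive coordinates ``start = POS + 1``,
    ``end = POS + len(REF) - 1``.  Returns ``(snvs, deletions)``.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{path}: empty variant table", stacklevel=2)
        return [], []
    if dialect == "tsv":
        return _parse_tsv_table(path, strain)
    if dialect != "vcf-min":
        raise ValueError(f"unknown dialect {dialect!r}")

    import pysam

    snvs: list[SnvRecord] = []
    deletions: list[DeletionRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        label = strain or _vcf_strain(str(vcf.header), path)
        for rec in vcf:
            try:
                depth = int(rec.info["DP"])
                vr = int(rec.info["VR"])
                ref = rec.ref.upper()
                alt = rec.alts[0].upper()
                if len(ref) == 1 and len(alt) == 1:
                    snvs.append(SnvRecord(label, rec.chrom, rec.pos, ref, alt, depth, vr))
                elif len(ref) > 1 and len(alt) == 1 and ref[0] == alt:
                    deletions.append(
                        DeletionRecord(
                            label, rec.chrom,
                            start=rec.pos + 1,
                            end=rec.pos + len(ref) - 1,
                            depth=depth,
                            supporting_reads=vr,
                        )
                    )
                else:
                    raise ValueError(f"unsupported REF/ALT pair {ref}>{alt}")
            except (KeyError, ValueError, TypeError) as exc:
                raise ParseError(path, _vcf_line_no(path, rec), str(exc)) from exc
    return snvs, deletions


def _vcf_line_no(path, rec) -> int:
    """Best-effort line number of a pysam record (for error messages)."""
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(f"{rec.chrom}\t{rec.pos}\t"):
                return i
    return -1


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

_SNV_COLS = ["strain", "chrom", "pos", "ref", "alt", "depth", "alt_reads"]
_DEL_COLS = ["strain", "chrom", "start", "end", "depth", "supporting_reads", "zygosity_call"]


def write_snv_tsv(records: Iterable[SnvRecord], path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_SNV_COLS)
    df.to_csv(path, sep="\t", index=False)


def write_deletion_tsv(records: Iterable[DeletionRecord], path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=_DEL_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_snv_tsv(path) -> list[SnvRecord]:
    return _parse_tsv_table(path, None)[0]


def read_deletion_tsv(path) -> list[DeletionRecord]:
    return _parse_tsv_table(path, None)[1]


def _parse_tsv_table(path, strain: str | None):
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and len(df.columns) == 0:
        warnings.warn(f"{path}: empty variant table", stacklevel=3)
        return [], []
    cols = set(df.columns)
    snvs: list[SnvRecord] = []
    deletions: list[DeletionRecord] = []
    if {"pos", "ref", "alt"} <= cols:
        for i, row in df.iterrows():
            try:
                snvs.append(
                    SnvRecord(
                        strain or str(row["strain"]), str(row["chrom"]), int(row["pos"]),
                        str(row["ref"]).upper(), str(row["alt"]).upper(),
                        int(row["depth"]), int(row["alt_reads"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(path, i + 2, str(exc)) from exc  # +2: header + 1-based
    elif {"start", "end"} <= cols:
        for i, row in df.iterrows():
            try:
                deletions.append(
                    DeletionRecord(
                        strain or str(row["strain"]), str(row["chrom"]),
                        int(row["start"]), int(row["end"]),
                        int(row["depth"]), int(row["supporting_reads"]),
                        zygosity_call=str(row.get("zygosity_call", "ambiguous")),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ParseError(path, i + 2, str(exc)) from exc
    else:
        raise ParseError(path, 1, f"unrecognised variant-table columns: {sorted(cols)}")
    return snvs, deletions


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

def write_truth_tsv(truth: TruthSet, path) -> None:
    rows = []
    for t in truth.snvs:
        rows.append((t.strain, t.chrom, t.pos, t.pos, "snv", 0, "hom", f"{t.ref}>{t.alt}"))
    for t in truth.shared_snvs:
        rows.append((t.strain, t.chrom, t.pos, t.pos, "shared_snv", 0, "hom", f"{t.ref}>{t.alt}"))
    for d in truth.deletions:
        rows.append((d.strain, d.chrom, d.start, d.end, "deletion", d.engineered_mh, d.zygosity, "."))
    df = pd.DataFrame(
        rows, columns=["strain", "chrom", "start", "end", "type", "mh", "zygosity", "note"]
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> TruthSet:
    df = pd.read_csv(path, sep="\t", dtype={"strain": str, "chrom": str, "note": str})
    truth = TruthSet()
    for _, row in df.iterrows():
        kind = row["type"]
        if kind in ("snv", "shared_snv"):
            ref, alt = str(row["note"]).split(">")
            rec = TruthSnv(str(row["strain"]), str(row["chrom"]), int(row["start"]), ref, alt)
            (truth.shared_snvs if kind == "shared_snv" else truth.snvs).append(rec)
        elif kind == "deletion":
            truth.deletions.append(
                TruthDeletion(
                    str(row["strain"]), str(row["chrom"]), int(row["start"]), int(row["end"]),
                    engineered_mh=int(row["mh"]), zygosity=str(row["zygosity"]),
                )
            )
        else:
            raise ParseError(path, -1, f"unknown truth record type {kind!r}")
    return truth


def write_truth_bed(deletions: Sequence[TruthDeletion], path) -> None:
    """Truth deletions as BED (0-based half-open, converted from 1-based inclusive)."""
    with open(path, "w") as fh:
        for d in deletions:
            fh.write(f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.strain};mh={d.engineered_mh}\n")


# ---------------------------------------------------------------------------
# depth tracks and broods
# ---------------------------------------------------------------------------

def write_depth_track(track: DepthTrack, path) -> None:
    """bedGraph-like TSV: chrom, bin start (0-based), bin end, mean depth."""
    with open(path, "w") as fh:
        fh.write("chrom\tbin_start\tbin_end\tmean_depth\n")
        for i, mean in enumerate(track.means):
            fh.write(f"{track.chrom}\t{i * track.bin_width}\t{(i + 1) * track.bin_width}\t{mean:.6g}\n")


def read_depth_track(path) -> DepthTrack:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ParseError(path, 1, "empty depth track")
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ParseError(path, 1, "expected a single-chromosome track")
    widths = (df["bin_end"] - df["bin_start"]).unique()
    if len(widths) != 1:
        raise ParseError(path, 1, "bins are not fixed-width")
    df = df.sort_values("bin_start")
    return DepthTrack(chrom=str(chroms[0]), bin_width=int(widths[0]), means=df["mean_depth"].to_numpy())


def write_broods(broods: Mapping[str, BroodCount], path) -> None:
    df = pd.DataFrame(
        [(s, b.wt, b.dpy_unc, b.dpy, b.unc) for s, b in broods.items()],
        columns=["strain", "wt", "dpy_unc", "dpy", "unc"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_broods(path) -> dict[str, BroodCount]:
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    out = {}
    for i, row in df.iterrows():
        try:
            out[str(row["strain"])] = BroodCount(
                wt=int(row["wt"]), dpy_unc=int(row["dpy_unc"]),
                dpy=int(row.get("dpy", 0)), unc=int(row.get("unc", 0)),
            )
        except (ValueError, KeyError) as exc:
            raise ParseError(path, i + 2, str(exc)) from exc
    return out
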