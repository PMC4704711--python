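"""Synthetic mutagenesis cohorts with full ground truth.

Everything the analysis consumes can be generated here with known truth: a
genome of controllable dinucleotide composition, a multi-strain cohort of
homozygous strain-specific SNVs and deletions (with CpG-biased deleted
segments and engineered junction microhomology), binomial read-count evidence
at Poisson depths, a coverage track with a balancer-boundary drop, and brood
counts drawn from the mapping cross's zygote model.

The generator emulates the statistical structure of a mutagenised
balancer-screen cohort, not its molecular detail: no reads, no alignment
artifacts, no error haplotypes.  Every stochastic entry point takes an
explicit seed (or a ``numpy.random.Generator``); a cohort simulation derives
per-stage sub-streams deterministically from one seed, so a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .screen import BroodCount

__all__ = [
    "Genome",
    "SimConfig",
    "TruthSnv",
    "TruthDeletion",
    "TruthSet",
    "CohortSim",
    "SimulationError",
    "default_dinuc_freqs",
    "simulate_genome",
    "inject_deletions",
    "inject_snvs",
    "simulate_strain_tables",
    "simulate_depth_track",
    "simulate_brood",
    "simulate_cohort",
]

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(RuntimeError):
    """Raised when a requested simulation cannot be realised (e.g. no room
    left to place a deletion after bounded retries)."""


@dataclass
class Genome:
    """Named sequences with 1-based coordinates."""

    sequences: dict[str, str]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice."""
        return self.sequences[chrom][start - 1: end]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])


def default_dinuc_freqs() -> np.ndarray:
    """Default target composition: AT-rich with a depleted CpG.

    Base composition A=T=0.32, C=G=0.18 with the CG dinucleotide scaled to a
    quarter of its product expectation (CG proportion ~0.8%).  A scarce CpG
    background is what makes crosslink-driven CpG targeting identifiable in
    deleted segments at realistic deletion counts.
    """
    base = np.array([0.32, 0.18, 0.18, 0.32])
    f = np.outer(base, base)
    f[1, 2] *= 0.25  # CG
    f /= f.sum()
    return f.reshape(16)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the emulated study: a 1-Mb chromosome, 10 mutagenised
    strains each carrying ~20 strain-specific deletions and ~25 SNVs, mean
    depth 30, CpG-biased deletion placement, and junction microhomology in
    roughly two-thirds of deletions.
    """

    genome_length: int = 1_000_000
    dinuc_freqs: np.ndarray = field(default_factory=default_dinuc_freqs)
    n_strains: int = 10
    n_deletions_per_strain: int = 20
    deletion_size_dist: tuple[str, dict] = (
        "lognormal",
        {"median": 50.0, "sigma_log": 1.5, "min": 2, "max": 20_000},
    )
    cpg_bias: float = 10.0
    mh_length_dist: tuple[str, dict] = (
        "categorical",
        {"lengths": [0, 1, 2, 3, 4, 5, 6], "probs": [0.31, 0.24, 0.15, 0.10, 0.08, 0.07, 0.05]},
    )
    n_snvs_per_strain: int = 25
    mean_depth: float = 30.0
    error_rate: float = 0.01
    seed: int = 0
    # --- extensions beyond the core knobs ---
    n_het_deletions_per_strain: int = 1   # balancer-maintained lethal candidates
    n_shared_snvs: int = 20               # parental background present in every strain
    fixed_depth: bool = False             # depth exactly mean_depth (noiseless studies)
    chrom: str = "chrI"
    max_place_retries: int = 1000
    # depth-track conditions
    track_bin_width: int = 5000
    track_breakpoint: int = 650_001
    track_drop_fraction: float = 0.5
    track_sigma: float = 3.0
    # brood conditions
    brood_zygotes: int = 2000
    brood_p_range: tuple[float, float] = (0.02, 0.15)

    def __post_init__(self) -> None:
        self.dinuc_freqs = np.asarray(self.dinuc_freqs, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.dinuc_freqs.shape != (16,):
            raise ValueError("dinuc_freqs must have 16 entries")
        if (self.dinuc_freqs < 0).any() or abs(self.dinuc_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("dinuc_freqs must be non-negative and sum to 1")
        for name in (
            "genome_length", "n_strains", "n_deletions_per_strain", "n_snvs_per_strain",
            "n_het_deletions_per_strain", "n_shared_snvs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.cpg_bias < 1:
            raise ValueError("cpg_bias must be >= 1")


@dataclass(frozen=True)
class TruthSnv:
    strain: str
    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class TruthDeletion:
    strain: str
    chrom: str
    start: int
    end: int
    engineered_mh: int
    zygosity: str = "hom"  # {hom, het}

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TruthSet:
    """Ground truth for one simulated cohort."""

    snvs: list[TruthSnv] = field(default_factory=list)
    deletions: list[TruthDeletion] = field(default_factory=list)
    breakpoints: list[tuple[str, int]] = field(default_factory=list)
    shared_snvs: list[TruthSnv] = field(default_factory=list)  # parental background
    brood_p: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _balanced_joint(freqs: np.ndarray, tol: float = 1e-12, max_iter: int = 100) -> np.ndarray:
    """Project target dinucleotide frequencies onto the consistent set.

    The pair distribution realised by any single sequence has (up to end
    effects) equal row and column marginals; arbitrary 16-vectors need not.
    The target is therefore projected onto that constraint set by iterated
    least squares weighted by the squared cell values, i.e. minimising
    *relative* cell changes — so small, distinctive cells (a depleted CG)
    move very little in absolute terms and realised proportions track the
    targets that matter.  Cells that are zero in the target stay zero.
    """
    F = freqs.reshape(4, 4).astype(float)
    m = (F.sum(axis=1) + F.sum(axis=0)) / 2.0
    for x in range(4):
        if m[x] > 0 and F[x].sum() == 0:
            raise ValueError(
                "non-normalizable dinucleotide frequencies: "
                f"base {'ACGT'[x]} is entered but never left (row all zero)"
            )
    # constraints: rowsum_x - colsum_x = 0 for three bases (fourth dependent),
    # plus total mass 1
    A = np.zeros((4, 16))
    for x in range(3):
        M = np.zeros((4, 4))
        M[x, :] += 1
        M[:, x] -= 1
        A[x] = M.reshape(16)
    A[3] = 1.0
    b = np.array([0.0, 0.0, 0.0, 1.0])
    q = F.reshape(16).copy()
    for _ in range(max_iter):
        resid = b - A @ q
        if np.abs(resid).max() < tol and (q >= 0).all():
            break
        w = np.maximum(q, 1e-12) ** 2
        AW = A * w
        step, *_ = np.linalg.lstsq(AW @ A.T, resid, rcond=None)
        q = np.clip(q + w * (A.T @ step), 0.0, None)
    return (q / q.sum()).reshape(4, 4)


def simulate_genome(length: int, dinuc_freqs: Sequence[float] | None = None,
                    seed: int | np.random.Generator = 0, chrom: str = "chrI") -> Genome:
    """First-order Markov genome matching target dinucleotide proportions.

    The transition matrix is derived from the (marginal-balanced) target
    joint, so realised overlapping-dinucleotide proportions converge to the
    targets as length grows.  Alphabet is strictly ACGT.
    """
    if length < 2:
        raise ValueError("genome length must be >= 2")
    freqs = default_dinuc_freqs() if dinuc_freqs is None else np.asarray(dinuc_freqs, float)
    if freqs.shape != (16,):
        raise ValueError("dinuc_freqs must have 16 entries")
    if (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("dinuc_freqs must be non-negative and sum to 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    Q = _balanced_joint(freqs)
    m = Q.sum(axis=1)
    P = np.where(m[:, None] > 0, Q / np.maximum(m[:, None], 1e-300), 0.25)
    cum = [tuple(np.cumsum(P[x])[:3]) for x in range(4)]

    out = np.empty(length, dtype=np.int8)
    state = int(rng.choice(4, p=m / m.sum()))
    out[0] = state
    u = rng.random(length - 1)
    for i in range(1, length):
        c = cum[state]
        ui = u[i - 1]
        state = 0 if ui < c[0] else 1 if ui < c[1] else 2 if ui < c[2] else 3
        out[i] = state
    seq = _ALPHABET[out].tobytes().decode("ascii")
    return Genome(sequences={chrom: seq})


# ---------------------------------------------------------------------------
# deletions and SNVs
# ---------------------------------------------------------------------------

def _sample_size(rng: np.random.Generator, dist: tuple[str, dict]) -> int:
    name, params = dist
    if name == "fixed":
        return int(params["size"])
    if name == "uniform":
        return int(rng.integers(int(params["low"]), int(params["high"]) + 1))
    if name == "lognormal":
        size = rng.lognormal(mean=math.log(params["median"]), sigma=params["sigma_log"])
        return int(np.clip(round(size), params.get("min", 1), params.get("max", 1e9)))
    raise ValueError(f"unknown size distribution {name!r}")


def _sample_mh(rng: np.random.Generator, dist: tuple[str, dict]) -> int:
    name, params = dist
    if name == "fixed":
        return int(params["length"])
    if name == "uniform":
        return int(rng.integers(int(params["low"]), int(params["high"]) + 1))
    if name == "categorical":
        return int(rng.choice(params["lengths"], p=params["probs"]))
    raise ValueError(f"unknown microhomology distribution {name!r}")


#: Safety margin (bp) kept free around every placed deletion so flank
#: extraction (15 nt), microhomology scoring (cap 25) and engineered-flank
#: edits never interact between events.
_PLACEMENT_MARGIN = 40


def inject_deletions(
    genome: Genome,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[Genome, list[TruthDeletion]]:
    """Place strain-specific deletions with CpG bias and engineered microhomology.

    Candidate intervals containing at least one CG dinucleotide are accepted
    outright; CG-free candidates are accepted with probability
    ``1 / cpg_bias`` — i.e. relative weight ``cpg_bias`` for CpG-containing
    segments.  For an engineered microhomology of length ``k > 0`` the first
    ``k`` bases of the deleted segment are written into the start of the
    right flank, so the junction carries at least ``k`` bases of homology
    (chance sequence may extend it).  Deletions are non-overlapping across
    the whole cohort (with a margin) so truth stays unambiguous; placement
    retries are bounded and exhaustion raises :class:`SimulationError`.

    Returns the (possibly flank-edited) genome and the truth records.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    chrom = config.chrom
    seq = bytearray(genome.sequences[chrom], "ascii")
    L = len(seq)
    occupied: list[tuple[int, int]] = []
    truth: list[TruthDeletion] = []

    def overlaps(s: int, e: int) -> bool:
        return any(s <= oe and e >= os_ for os_, oe in occupied)

    for strain_idx in range(config.n_strains):
        strain = f"strain{strain_idx + 1:02d}"
        for j in range(config.n_deletions_per_strain):
            zyg = "het" if j < config.n_het_deletions_per_strain else "hom"
            size = _sample_size(rng, config.deletion_size_dist)
            k = _sample_mh(rng, config.mh_length_dist)
            if size + 2 * _PLACEMENT_MARGIN + k >= L:
                raise SimulationError(
                    f"deletion of {size} bp cannot fit a genome of {L} bp"
                )
            placed = False
            for _ in range(config.max_place_retries):
                start = int(rng.integers(_PLACEMENT_MARGIN + 1, L - size - _PLACEMENT_MARGIN - k))
                end = start + size - 1
                if overlaps(start - _PLACEMENT_MARGIN, end + _PLACEMENT_MARGIN):
                    continue
                segment = seq[start - 1: end]
                has_cpg = b"CG" in segment
                if not has_cpg and config.cpg_bias > 1 and rng.random() >= 1.0 / config.cpg_bias:
                    continue
                if k > 0:
                    seq[end: end + k] = seq[start - 1: start - 1 + k]
                occupied.append((start, end))
                truth.append(TruthDeletion(strain, chrom, start, end, engineered_mh=k, zygosity=zyg))
                placed = True
                break
            if not placed:
                raise SimulationError(
                    f"could not place a {size} bp deletion for {strain} "
                    f"after {config.max_place_retries} retries"
                )
    edited = Genome(sequences={**genome.sequences, chrom: seq.decode("ascii")})
    return edited, truth


def inject_snvs(
    genome: Genome,
    config: SimConfig,
    rng: np.random.Generator,
    forbidden: list[tuple[int, int]] | None = None,
) -> tuple[list[TruthSnv], list[TruthSnv]]:
    """Draw strain-specific and shared (parental-background) SNV truth.

    Positions are unique across the cohort and avoid ``forbidden`` intervals
    (deletions plus margins); the alternate base is drawn uniformly from the
    three non-reference bases.
    """
    chrom = config.chrom
    seq = genome.sequences[chrom]
    L = len(seq)
    forbidden = forbidden or []
    taken: set[int] = set()

    def draw_pos() -> int:
        for _ in range(config.max_place_retries):
            pos = int(rng.integers(2, L))
            if pos in taken:
                continue
            if any(s - _PLACEMENT_MARGIN <= pos <= e + _PLACEMENT_MARGIN for s, e in forbidden):
                continue
            taken.add(pos)
            return pos
        raise SimulationError("could not place an SNV (genome too crowded)")

    def draw_alt(ref: str) -> str:
        choices = [b for b in "ACGT" if b != ref]
        return choices[int(rng.integers(0, 3))]

    snvs = []
    for strain_idx in range(config.n_strains):
        strain = f"strain{strain_idx + 1:02d}"
        for _ in range(config.n_snvs_per_strain):
            pos = draw_pos()
            ref = seq[pos - 1]
            snvs.append(TruthSnv(strain, chrom, pos, ref, draw_alt(ref)))
    shared = []
    for _ in range(config.n_shared_snvs):
        pos = draw_pos()
        ref = seq[pos - 1]
        shared.append(TruthSnv("parental", chrom, pos, ref, draw_alt(ref)))
    return snvs, shared


# ---------------------------------------------------------------------------
# read-count evidence
# ---------------------------------------------------------------------------

def _depth(rng: np.random.Generator, config: SimConfig) -> int:
    if config.fixed_depth:
        return int(round(config.mean_depth))
    return int(rng.poisson(config.mean_depth))


def _alt_reads(rng: np.random.Generator, depth: int, f: float) -> int:
    if depth == 0:
        return 0
    return int(rng.binomial(depth, f))


def simulate_strain_tables(
    genome: Genome,
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
):
    """Per-strain SNV/deletion tables plus a composite-parental SNV table.

    At every cohort SNV site, every strain's table carries a row with depth
    drawn Poisson(mean_depth) and variant reads Binomial(depth, f) where f is
    ``1 - error_rate`` at sites the strain carries homozygously, 0.5 at
    heterozygous sites, and ``error_rate`` elsewhere.  Deletion tables carry
    only the strain's own called events (callers do not emit absent
    deletions); the parental table carries only the configured shared
    background variants.

    Returns ``(snv_tables, del_tables, parental_snvs)`` where the first two
    map strain name to record lists (:class:`mmcsig.filters.SnvRecord` /
    :class:`mmcsig.filters.DeletionRecord`).
    """
    from .filters import DeletionRecord, SnvRecord

    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    strains = sorted({f"strain{i + 1:02d}" for i in range(config.n_strains)})
    err = config.error_rate

    own_snv: dict[str, dict[tuple[str, int], TruthSnv]] = {s: {} for s in strains}
    for t in truth.snvs:
        own_snv[t.strain][(t.chrom, t.pos)] = t
    all_sites: list[TruthSnv] = list(truth.snvs)

    snv_tables: dict[str, list] = {s: [] for s in strains}
    for strain in strains:
        for site in all_sites:
            depth = _depth(rng, config)
            f = (1.0 - err) if (site.chrom, site.pos) in own_snv[strain] else err
            alt = _alt_reads(rng, depth, f)
            snv_tables[strain].append(
                SnvRecord(strain, site.chrom, site.pos, site.ref, site.alt, depth, alt)
            )
        for site in truth.shared_snvs:  # parental background, homozygous everywhere
            depth = _depth(rng, config)
            alt = _alt_reads(rng, depth, 1.0 - err)
            snv_tables[strain].append(
                SnvRecord(strain, site.chrom, site.pos, site.ref, site.alt, depth, alt)
            )

    parental_snvs: list = []
    for site in truth.shared_snvs:
        depth = _depth(rng, config)
        alt = _alt_reads(rng, depth, 1.0 - err)
        parental_snvs.append(
            SnvRecord("parental", site.chrom, site.pos, site.ref, site.alt, depth, alt)
        )

    del_tables: dict[str, list] = {s: [] for s in strains}
    for t in truth.deletions:
        depth = max(1, _depth(rng, config))
        f = 0.5 if t.zygosity == "het" else 1.0 - err
        support = _alt_reads(rng, depth, f)
        del_tables.setdefault(t.strain, []).append(
            DeletionRecord(t.strain, t.chrom, t.start, t.end, depth, support)
        )
    return snv_tables, del_tables, parental_snvs


# ---------------------------------------------------------------------------
# depth track and broods
# ---------------------------------------------------------------------------

def simulate_depth_track(
    chrom_length: int,
    bin_width: int,
    breakpoint: int,
    drop_fraction: float,
    mean_depth: float,
    sigma: float = 3.0,
    seed: int | np.random.Generator = 0,
    chrom: str = "chrI",
):
    """Binned coverage with a step drop at a rearrangement boundary.

    Bin means are Normal(mean_depth, sigma) before the breakpoint and
    Normal(mean_depth * drop_fraction, sigma * sqrt(drop_fraction)) from the
    bin containing it onward (noise scales roughly with the square root of
    coverage).  ``drop_fraction`` of 1 means no drop.  Returns
    ``(DepthTrack, truth_boundary_bin)``.
    """
    from .breakpoints import DepthTrack

    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if not 0 < drop_fraction <= 1:
        raise ValueError("drop_fraction must be in (0, 1]")
    if not 1 <= breakpoint <= chrom_length:
        raise ValueError("breakpoint must lie within the chromosome")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_bins = int(math.ceil(chrom_length / bin_width))
    boundary_bin = (breakpoint - 1) // bin_width
    means = np.empty(n_bins)
    means[:boundary_bin] = mean_depth + sigma * rng.standard_normal(boundary_bin)
    post_sigma = sigma * math.sqrt(drop_fraction)
    means[boundary_bin:] = mean_depth * drop_fraction + post_sigma * rng.standard_normal(n_bins - boundary_bin)
    np.clip(means, 0.0, None, out=means)
    return DepthTrack(chrom=chrom, bin_width=bin_width, means=means), int(boundary_bin)


def simulate_brood(p: float, n_zygotes: int, seed: int | np.random.Generator = 0) -> BroodCount:
    """Brood counts from the mapping cross's zygote model.

    Zygote classes: wild-type-appearing 3/4; viable Dpy-Unc recombinants
    ``p/2 - p^2/4``; dead lethal homozygotes ``((1-p)/2)^2`` (simulated, then
    discarded — only surviving animals are ever scored, which is what the
    estimator's 4/3 correction accounts for).  Single-marker Dpy and Unc
    classes are carried with zero mass: the lethal sits outside the marker
    interval in this model and the estimator ignores them regardless.
    """
    if not 0 <= p <= 0.5:
        raise ValueError("recombination fraction p must be in [0, 0.5]")
    if n_zygotes < 0:
        raise ValueError("n_zygotes must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.array([0.75, p / 2 - p * p / 4, 0.0, 0.0, ((1 - p) / 2) ** 2])
    wt, dpy_unc, dpy, unc, _dead = rng.multinomial(n_zygotes, probs)
    return BroodCount(wt=int(wt), dpy_unc=int(dpy_unc), dpy=int(dpy), unc=int(unc))


# ---------------------------------------------------------------------------
# cohort orchestration
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    """One fully simulated cohort with its ground truth."""

    config: SimConfig
    genome: Genome
    truth: TruthSet
    snv_tables: dict[str, list]
    del_tables: dict[str, list]
    parental_snvs: list
    depth_track: object
    broods: dict[str, BroodCount]


def simulate_cohort(config: SimConfig) -> CohortSim:
    """Generate genome, cohort tables, depth track and broods from one seed."""
    ss = np.random.SeedSequence(config.seed)
    r_genome, r_del, r_snv, r_tables, r_track, r_brood = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )
    genome = simulate_genome(config.genome_length, config.dinuc_freqs, r_genome, chrom=config.chrom)
    genome, deletions = inject_deletions(genome, config, r_del)
    forbidden = [(d.start, d.end) for d in deletions]
    snvs, shared = inject_snvs(genome, config, r_snv, forbidden=forbidden)

    truth = TruthSet(snvs=snvs, deletions=deletions, shared_snvs=shared)
    snv_tables, del_tables, parental_snvs = simulate_strain_tables(genome, truth, config, r_tables)

    track, boundary_bin = simulate_depth_track(
        config.genome_length,
        config.track_bin_width,
        config.track_breakpoint,
        config.track_drop_fraction,
        config.mean_depth,
        sigma=config.track_sigma,
        seed=r_track,
        chrom=config.chrom,
    )
    truth.breakpoints = [(config.chrom, config.track_breakpoint)]

    broods: dict[str, BroodCount] = {}
    lo, hi = config.brood_p_range
    for i in range(config.n_strains):
        strain = f"strain{i + 1:02d}"
        p = float(r_brood.uniform(lo, hi))
        truth.brood_p[strain] = p
        broods[strain] = simulate_brood(p, config.brood_zygotes, r_brood)

    return CohortSim(
        config=config,
        genome=genome,
        truth=truth,
        snv_tables=snv_tables,
        del_tables=del_tables,
        parental_snvs=parental_snvs,
        depth_track=track,
        broods=broods,
    )
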