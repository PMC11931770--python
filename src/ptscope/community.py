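"""Synthetic gut-community generator with planted PT systems.

Emulates the statistical structure that the downstream assays assume, so the
whole pipeline is testable without any external data:

* a mixed community in which a small fraction of genomes (default 10%, two
  of twenty) carry PT modification systems — a single-strand C*AG system and
  a bistranded G*AAC/G*TTC system, mirroring the Ssp/Dnd family division;
* PT installed at partial occupancy (default 12.5%, the middle of the
  10-15% range characteristic of Dnd/Ssp systems) of consensus occurrences;
* cleavage-derived reads whose 5' ends sit exactly one position 3' of a
  planted linkage, over a uniform background of spurious nicks;
* matched LC-MS peak tables generated from the community's expected
  dinucleotide profile (the quantity both assays should agree on);
* multi-timepoint level matrices obeying Taylor's law V = a*m^b.

Coordinate convention (0-based): a PT linkage between positions p and p+1
of a strand is recorded at p, the 5' nucleotide of the dinucleotide.
Cleavage places a read 5' end one position 3' of the linkage: forward
coordinate p+1 on the plus strand, p-1 on the minus strand.  Minus-strand
sites are stored in forward coordinates with a strand flag; their
dinucleotides and windows read from the reverse complement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from ptscope import chemistry
from ptscope.lcms import CANONICAL, CalibrationCurve, ChromPeak, PTProfile

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Edge margin that keeps every 13-nt window inside the genome.
WINDOW_FLANK = 6


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def star_label(dinucleotide: str) -> str:
    """LC-MS analyte label of a linkage dinucleotide: "CA" -> "C*A"."""
    return f"{dinucleotide[0]}*{dinucleotide[1]}"


def _iupac_regex(motif: str) -> re.Pattern:
    """Overlap-tolerant regex for an IUPAC motif."""
    expanded = []
    for ch in motif:
        vals = ambiguous_dna_values.get(ch)
        if vals is None:
            raise ValueError(f"invalid IUPAC base {ch!r} in motif {motif!r}")
        expanded.append(ch if len(vals) == 1 else f"[{vals}]")
    return re.compile("(?=" + "".join(expanded) + ")")


def find_motif_occurrences(genome: str, motif: str) -> list[int]:
    """0-based start positions of (possibly overlapping) motif matches."""
    return [m.start() for m in _iupac_regex(motif).finditer(genome)]


@dataclass(frozen=True)
class PTSystem:
    """A PT-installing modification system.

    ``linkage_index`` is the 0-based position of the PT-bearing nucleotide
    within the motif (the linkage runs to its 3' neighbor), so C*AG is
    (motif="CAG", linkage_index=0).  Bistranded systems modify both strands
    of a duplex site jointly; the partner motif is the reverse complement
    (G*AAC pairs with G*TTC).
    """

    motif: str
    linkage_index: int = 0
    strandedness: str = "single"  # "single" | "bistranded"
    occupancy: float = 0.125
    comp_linkage_index: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.linkage_index < len(self.motif) - 1):
            raise ValueError("linkage index must lie before the motif's last base")
        if self.strandedness not in ("single", "bistranded"):
            raise ValueError(f"unknown strandedness {self.strandedness!r}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")

    @property
    def comp_motif(self) -> str:
        return str(reverse_complement(self.motif))

    @property
    def comp_linkage(self) -> int:
        return self.linkage_index if self.comp_linkage_index is None else self.comp_linkage_index

    def label(self) -> str:
        m = self.motif
        i = self.linkage_index
        core = f"{m[:i + 1]}*{m[i + 1:]}"
        if self.strandedness == "bistranded":
            c = self.comp_motif
            j = self.comp_linkage
            core += f"/{c[:j + 1]}*{c[j + 1:]}"
        return core


#: Default study systems: one single-strand, one bistranded.
DEFAULT_SYSTEMS = (
    PTSystem(motif="CAG", strandedness="single", occupancy=0.125),
    PTSystem(motif="GAAC", strandedness="bistranded", occupancy=0.125),
)


@dataclass(frozen=True)
class PlantedSite:
    """One PT linkage: forward-coordinate position of the 5' base + strand."""

    position: int
    strand: str      # "+" or "-"
    dinucleotide: str


@dataclass
class Genome:
    genome_id: str
    sequence: str
    systems: list[PTSystem] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


def site_dinucleotide(genome: str, position: int, strand: str) -> str:
    """Dinucleotide spanning the linkage, read 5'->3' on the site's strand."""
    if strand == "+":
        return genome[position:position + 2]
    return (genome[position] + genome[position - 1]).translate(_COMPLEMENT)


def _valid_plus(p: int, length: int, read_length: int) -> bool:
    return p >= WINDOW_FLANK and p + 1 + read_length <= length

def _valid_minus(p: int, length: int, read_length: int) -> bool:
    return p >= read_length and p + WINDOW_FLANK + 1 <= length


def enumerate_site_units(
    genome: str, system: PTSystem, read_length: int = 150
) -> list[list[tuple[int, str]]]:
    """All modifiable units: one (pos, strand) for single-strand systems,
    the joint plus/minus pair for bistranded duplex sites.

    Units whose cleavage read or 13-nt window would run off the linear
    genome end are excluded, so every enumerated site is observable.
    """
    L = len(genome)
    m, i = system.motif, system.linkage_index
    c, j = system.comp_motif, system.comp_linkage
    units: list[list[tuple[int, str]]] = []
    if system.strandedness == "single":
        for s in find_motif_occurrences(genome, m):
            p = s + i
            if _valid_plus(p, L, read_length):
                units.append([(p, "+")])
        for s in find_motif_occurrences(genome, str(reverse_complement(m))):
            p = s + len(m) - 1 - i
            if _valid_minus(p, L, read_length):
                units.append([(p, "-")])
    else:
        # A duplex site shows the motif on one strand and the partner on the
        # other; enumerating forward hits of both covers every duplex once
        # (palindromic motifs enumerate once by construction).
        motif_pairs = [(m, i, j)]
        if c != m:
            motif_pairs.append((c, j, i))
        for fwd_motif, i_plus, i_minus in motif_pairs:
            Lm = len(fwd_motif)
            for s in find_motif_occurrences(genome, fwd_motif):
                p_plus = s + i_plus
                p_minus = s + Lm - 1 - i_minus
                if _valid_plus(p_plus, L, read_length) and _valid_minus(p_minus, L, read_length):
                    units.append([(p_plus, "+"), (p_minus, "-")])
    return units


def assign_pt_sites(
    genome: str,
    system: PTSystem,
    seed: int | np.random.Generator,
    read_length: int = 150,
) -> list[PlantedSite]:
    """Plant PT linkages: each unit modified independently with
    probability = occupancy (bistranded units jointly on both strands)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    planted: list[PlantedSite] = []
    units = enumerate_site_units(genome, system, read_length)
    coins = rng.random(len(units)) < system.occupancy
    for unit, hit in zip(units, coins):
        if not hit:
            continue
        for p, strand in unit:
            planted.append(PlantedSite(p, strand, site_dinucleotide(genome, p, strand)))
    return planted


@dataclass
class CommunityTruth:
    """Ground truth of a synthetic community."""

    genomes: list[Genome]
    abundances: np.ndarray
    planted: dict[str, list[PlantedSite]]
    seed: int
    read_length: int = 150

    def __post_init__(self) -> None:
        ab = np.asarray(self.abundances, dtype=float)
        if np.any(ab < 0) or abs(ab.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must be >= 0 and sum to 1")
        self.abundances = ab

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]

    @property
    def pt_genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes if self.planted.get(g.genome_id)]

    def abundance_of(self, genome_id: str) -> float:
        return float(self.abundances[self.genome_ids.index(genome_id)])

    def site_counts(self) -> dict[str, dict[str, int]]:
        """Planted-site counts per genome, keyed by dinucleotide."""
        out: dict[str, dict[str, int]] = {}
        for gid, sites in self.planted.items():
            counts: dict[str, int] = {}
            for s in sites:
                counts[s.dinucleotide] = counts.get(s.dinucleotide, 0) + 1
            out[gid] = counts
        return out

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {"genome": gid, "pos0": s.position, "strand": s.strand,
             "dinucleotide": s.dinucleotide}
            for gid, sites in self.planted.items()
            for s in sites
        ]
        return pd.DataFrame(rows, columns=["genome", "pos0", "strand", "dinucleotide"])

    def write_fasta(self, path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [
            SeqRecord(Seq(g.sequence), id=g.genome_id, description="")
            for g in self.genomes
        ]
        seqio_write(records, str(path), "fasta")


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=probs)
    return codes.tobytes().decode("ascii")


def build_community(
    n_genomes: int = 20,
    genome_length: int = 200_000,
    gc: float = 0.5,
    pt_genome_fraction: float = 0.10,
    systems: tuple[PTSystem, ...] = DEFAULT_SYSTEMS,
    abundance_dispersion: float = 1.0,
    seed: int = 0,
    read_length: int = 150,
) -> CommunityTruth:
    """Build a community: i.i.d. genomes, log-normal abundances, PT systems
    assigned to ``pt_genome_fraction`` of genomes (one system per carrier,
    cycling through ``systems``)."""
    if n_genomes < 1 or genome_length < 100:
        raise ValueError("need n_genomes >= 1 and genome_length >= 100")
    if not 0.0 <= pt_genome_fraction <= 1.0:
        raise ValueError("pt_genome_fraction must be in [0, 1]")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    genomes = [
        Genome(f"genome_{i:03d}", _random_sequence(rng, genome_length, gc))
        for i in range(n_genomes)
    ]
    raw = rng.lognormal(mean=0.0, sigma=abundance_dispersion, size=n_genomes)
    abundances = raw / raw.sum()

    n_pt = int(round(n_genomes * pt_genome_fraction))
    carriers = sorted(rng.choice(n_genomes, size=n_pt, replace=False)) if n_pt else []
    planted: dict[str, list[PlantedSite]] = {g.genome_id: [] for g in genomes}
    for rank, idx in enumerate(carriers):
        system = systems[rank % len(systems)]
        genomes[idx].systems.append(system)
        planted[genomes[idx].genome_id] = assign_pt_sites(
            genomes[idx].sequence, system, rng, read_length
        )
    return CommunityTruth(genomes, abundances, planted, seed=seed, read_length=read_length)


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    genome: str
    five_prime: int   # forward coordinate of the read's 5' end
    strand: str
    origin: str       # "pt_cleavage" | "background"


@dataclass
class ReadSet:
    reads: list[SimRead]
    read_length: int

    def __len__(self) -> int:
        return len(self.reads)

    def write_fastq(self, path) -> None:
        qual = "I" * self.read_length  # constant Phred-33 quality 40
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def _read_sequence(genome: str, five_prime: int, strand: str, read_length: int) -> str:
    if strand == "+":
        return genome[five_prime:five_prime + read_length]
    return revcomp(genome[five_prime - read_length + 1:five_prime + 1])


def simulate_ptseq_reads(
    community: CommunityTruth,
    n_reads: int = 200_000,
    read_length: int = 150,
    background_nick_rate: float = 0.2,
    signal_capture_prob: float = 1.0,
    seed: int = 0,
) -> ReadSet:
    """Simulate cleavage reads.

    A read is a captured cleavage fragment with probability
    ``(1 - background_nick_rate) * signal_capture_prob`` — its 5' end sits
    one position 3' of a planted linkage on that strand, and it extends 3'
    (downstream) from the break.  Otherwise it is a background nick starting
    at a uniformly random position.  Reads are allocated to genomes in
    proportion to relative abundance (signal reads among PT carriers only).
    """
    if not 0.0 <= background_nick_rate <= 1.0 or not 0.0 <= signal_capture_prob <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    if read_length < 20:
        raise ValueError("read_length must be >= 20")
    if read_length > community.read_length:
        raise ValueError(
            "read_length exceeds the community's planting margin "
            f"({community.read_length})"
        )
    if any(read_length > g.length for g in community.genomes):
        raise ValueError("read longer than a genome")

    rng = np.random.default_rng(seed)
    gids = community.genome_ids
    ab = community.abundances
    pt_ids = community.pt_genome_ids
    p_signal = (1.0 - background_nick_rate) * signal_capture_prob if pt_ids else 0.0
    is_signal = rng.random(n_reads) < p_signal

    seqs: dict[str, str] = {g.genome_id: g.sequence for g in community.genomes}
    site_pool = {gid: community.planted[gid] for gid in pt_ids}

    if pt_ids:
        ab_pt = np.array([community.abundance_of(g) for g in pt_ids])
        ab_pt = ab_pt / ab_pt.sum()

    n_sig = int(is_signal.sum())
    sig_genomes = rng.choice(len(pt_ids), size=n_sig, p=ab_pt) if n_sig else np.array([], dtype=int)
    bg_genomes = rng.choice(len(gids), size=n_reads - n_sig, p=ab)
    bg_strands = rng.random(n_reads - n_sig) < 0.5

    reads: list[SimRead] = []
    si = bi = 0
    for k in range(n_reads):
        if is_signal[k]:
            gid = pt_ids[sig_genomes[si]]
            sites = site_pool[gid]
            site = sites[rng.integers(len(sites))]
            c = site.position + 1 if site.strand == "+" else site.position - 1
            strand, origin = site.strand, "pt_cleavage"
            si += 1
        else:
            gid = gids[bg_genomes[bi]]
            L = len(seqs[gid])
            if bg_strands[bi]:
                strand = "+"
                c = int(rng.integers(0, L - read_length + 1))
            else:
                strand = "-"
                c = int(rng.integers(read_length - 1, L))
            origin = "background"
            bi += 1
        reads.append(
            SimRead(
                read_id=f"read_{k:07d}",
                sequence=_read_sequence(seqs[gid], c, strand, read_length),
                genome=gid,
                five_prime=c,
                strand=strand,
                origin=origin,
            )
        )
    return ReadSet(reads, read_length)


def expected_lcms_profile(community: CommunityTruth) -> PTProfile:
    """The dinucleotide profile both assays should report, from ground truth.

    level(d) = 1e6 * sum_g abundance_g * planted_g(d) / (2 * length_g)
    — per-strand site counts over double-stranded nucleotide content.
    """
    levels: dict[str, float] = {}
    for g in community.genomes:
        ab = community.abundance_of(g.genome_id)
        for site in community.planted.get(g.genome_id, []):
            label = star_label(site.dinucleotide)
            levels[label] = levels.get(label, 0.0) + 1e6 * ab / (2 * g.length)
    return PTProfile(levels, sample_id=f"community_seed{community.seed}")


def default_calibration(
    rf_ms: float = 2000.0, rf_uv: float = 50.0
) -> dict[tuple[str, str], CalibrationCurve]:
    """Flat calibration set: one MS curve per PT dinucleotide, one UV-260
    curve per canonical nucleoside (response factors in area per pmol)."""
    curves: dict[tuple[str, str], CalibrationCurve] = {}
    for b5 in "ACGT":
        for b3 in "ACGT":
            label = f"{b5}*{b3}"
            curves[(label, "MS")] = CalibrationCurve(label, "MS", rf_ms, 1.0, 2)
    for nuc in CANONICAL:
        curves[(nuc, "UV260")] = CalibrationCurve(nuc, "UV260", rf_uv, 1.0, 2)
    return curves


def _rt_mid() -> dict[str, float]:
    mids = {}
    for compound, (lo, hi) in chemistry.rt_windows().items():
        label = compound[2] + "*" + compound[4] if compound.startswith("d(") else compound
        mids[label] = (lo + hi) / 2
    return mids


def simulate_lcms_peaks(
    profile: PTProfile,
    calib: dict[tuple[str, str], CalibrationCurve],
    injected_nt_pmol: float = 1e6,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> list[ChromPeak]:
    """Peak table consistent with a PT profile (inverse of quantification).

    MS areas are level/1e6 * injected_nt_pmol * RF, perturbed by
    multiplicative Gaussian noise of the given CV; UV-260 areas share the
    injected canonical pool equally among dA/dC/dG/dT.  Retention times sit
    at the center of each analyte's reference window.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rt = _rt_mid()
    peaks: list[ChromPeak] = []
    for label, level in profile.levels.items():
        rf = calib[(label, "MS")].response_factor
        area = level / 1e6 * injected_nt_pmol * rf
        if noise_cv > 0:
            area *= max(0.0, 1.0 + noise_cv * rng.standard_normal())
        peaks.append(
            ChromPeak(label, rt.get(label, 0.0), area, "MS",
                      snr=1e9 if area > 0 else 0.0)
        )
    for nuc in CANONICAL:
        rf = calib[(nuc, "UV260")].response_factor
        area = injected_nt_pmol / 4 * rf
        peaks.append(ChromPeak(nuc, rt.get(nuc, 0.0), area, "UV260", snr=1e9))
    return peaks


def peaks_to_frame(peaks: list[ChromPeak], sample_id: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "analyte": [p.analyte for p in peaks],
            "channel": [p.channel for p in peaks],
            "rt_min": [p.rt_min for p in peaks],
            "area": [p.area for p in peaks],
            "snr": [p.snr for p in peaks],
        }
    )


@dataclass
class TimeSeriesMatrix:
    """Species-by-timepoint level matrix (per 10^6 nt)."""

    frame: pd.DataFrame  # rows: species, columns: timepoints

    def __post_init__(self) -> None:
        if self.frame.shape[1] < 3:
            raise ValueError("need >= 3 timepoints for variance estimation")
        if (self.frame.values < 0).any():
            raise ValueError("levels must be >= 0")

    @property
    def species(self) -> list[str]:
        return list(self.frame.index)


def simulate_timeseries(
    mean_levels: dict[str, float],
    a: float = 1.0,
    b: float = 1.4,
    n_timepoints: int = 50,
    seed: int = 0,
) -> TimeSeriesMatrix:
    """Draw per-species level time courses obeying Taylor's law V = a*m^b.

    Each species' levels are i.i.d. log-normal with distribution mean m and
    variance a*m^b (sigma^2 = ln(1 + V/m^2), mu = ln m - sigma^2/2); b = 2
    therefore implies a constant coefficient of variation sqrt(a).
    """
    if a <= 0:
        raise ValueError("a must be positive")
    if n_timepoints < 3:
        raise ValueError("need >= 3 timepoints")
    if any(m <= 0 for m in mean_levels.values()):
        raise ValueError("mean levels must be positive")
    rng = np.random.default_rng(seed)
    rows = {}
    for species, m in mean_levels.items():
        v = a * m**b
        sigma2 = np.log1p(v / m**2)
        mu = np.log(m) - sigma2 / 2
        rows[species] = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n_timepoints)
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[f"t{j}" for j in range(n_timepoints)])
    return TimeSeriesMatrix(frame)
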