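"""PT site calling from cleavage reads.

Iodine cleaves the DNA backbone at PT linkages, so the 5' ends of captured
fragments pile up one position 3' of each modified linkage.  The pipeline:

1. place each read on the genomes by exact matching, spreading multi-mapping
   reads as fractional depth 1/n over their n optimal placements;
2. summarize every genome by coverage, median depth and dispersion of depth,
   and triage genomes with a Gaussian-mixture model — the cluster with deep,
   broad coverage holds the true PT carriers;
3. call sites where the weighted 5'-end depth clears a cutoff (default 15,
   chosen by a 1-25 sensitivity/specificity sweep);
4. discover the consensus motif by anchored k-mer enrichment in the 13-nt
   windows centered on the pileup 5' ends (the linkage dinucleotide is
   pinned at window columns 5-6, so motifs are enumerated in register
   rather than by de novo alignment);
5. convert called sites to "equivalent PTs per 10^6 nt" — abundance-weighted
   site density over double-stranded genome content — directly comparable
   with the LC-MS dinucleotide levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from ptscope.community import (
    WINDOW_FLANK,
    ReadSet,
    revcomp,
    site_dinucleotide,
    star_label,
)
from ptscope.lcms import PTProfile

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 15
SWEEP_CUTOFFS = range(1, 26)
COVERAGE_FLOOR = 0.15

ALIGNMENT_COLUMNS = ["read_id", "genome", "pos0", "strand", "n_hits", "weight", "read_len"]


def _genome_dict(genomes) -> dict[str, str]:
    if isinstance(genomes, dict):
        return genomes
    if hasattr(genomes, "genomes"):  # CommunityTruth
        return {g.genome_id: g.sequence for g in genomes.genomes}
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genomes), "fasta")}


def _read_pairs(reads) -> tuple[list[tuple[str, str]], int]:
    if isinstance(reads, ReadSet):
        return [(r.read_id, r.sequence) for r in reads.reads], reads.read_length
    if isinstance(reads, (str,)) or hasattr(reads, "open"):
        from Bio import SeqIO

        pairs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(reads), "fastq")]
    else:
        pairs = list(reads)
    lengths = {len(s) for _, s in pairs}
    if len(lengths) != 1:
        raise ValueError("reads must have a single configured length")
    return pairs, lengths.pop()


def assign_reads(reads, genomes) -> pd.DataFrame:
    """Exact-placement alignment with fractional multi-mapper weights.

    Every optimal (here: exact, full-length) placement of each read on the
    genomes or their reverse complements is reported; a read with n
    placements contributes weight 1/n to each.  ``pos0`` is the forward
    coordinate of the read's 5' end (for minus-strand placements, the last
    base of the matching forward interval).  Unmappable reads are counted
    and logged, not errors.
    """
    pairs, read_len = _read_pairs(reads)
    seqs = _genome_dict(genomes)
    if not pairs or not seqs:
        raise ValueError("reads and genomes must be non-empty")

    by_seq: dict[str, list[str]] = {}
    for rid, seq in pairs:
        by_seq.setdefault(seq, []).append(rid)
    rc_of = {revcomp(seq): seq for seq in by_seq}

    placements: dict[str, list[tuple[str, int, str]]] = {seq: [] for seq in by_seq}
    for gid, genome in seqs.items():
        for i in range(len(genome) - read_len + 1):
            window = genome[i:i + read_len]
            if window in placements:
                placements[window].append((gid, i, "+"))
            target = rc_of.get(window)
            if target is not None:
                placements[target].append((gid, i + read_len - 1, "-"))

    rows = []
    n_unmapped = 0
    for seq, hits in placements.items():
        if not hits:
            n_unmapped += len(by_seq[seq])
            continue
        n = len(hits)
        w = 1.0 / n
        for rid in by_seq[seq]:
            for gid, pos, strand in hits:
                rows.append((rid, gid, pos, strand, n, w, read_len))
    if n_unmapped:
        logger.info("%d reads had no exact placement", n_unmapped)
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


@dataclass(frozen=True)
class GenomeStats:
    genome_id: str
    coverage: float          # fraction of bases with weighted depth > 0
    median_depth: float      # over covered bases
    dispersion: float        # variance-to-mean ratio of depth over covered bases
    total_weight: float      # sum of placement weights


def depth_profile(alignments: pd.DataFrame, genome_id: str, genome_length: int) -> np.ndarray:
    """Per-base weighted read depth from placement spans."""
    depth = np.zeros(genome_length + 1)
    sub = alignments[alignments["genome"] == genome_id]
    for pos, strand, w, rl in zip(sub["pos0"], sub["strand"], sub["weight"], sub["read_len"]):
        if strand == "+":
            lo, hi = pos, min(pos + rl, genome_length)
        else:
            lo, hi = max(pos - rl + 1, 0), pos + 1
        depth[lo] += w
        depth[hi] -= w
    return np.cumsum(depth[:-1])


def genome_stats(alignments: pd.DataFrame, genome_id: str, genome_length: int) -> GenomeStats:
    depth = depth_profile(alignments, genome_id, genome_length)
    covered = depth > 0
    if not covered.any():
        return GenomeStats(genome_id, 0.0, 0.0, 0.0, 0.0)
    d = depth[covered]
    mean = float(d.mean())
    disp = float(d.var(ddof=1) / mean) if len(d) > 1 and mean > 0 else 0.0
    total = float(alignments.loc[alignments["genome"] == genome_id, "weight"].sum())
    return GenomeStats(genome_id, float(covered.mean()), float(np.median(d)), disp, total)


def genome_features(stats: list[GenomeStats], eps: float = 1e-6) -> pd.DataFrame:
    """Log-scale triage features: coverage log-odds, log median depth,
    log dispersion (clipped/floored at ``eps`` for degenerate genomes)."""
    rows = {}
    for st in stats:
        cov = min(max(st.coverage, eps), 1 - eps)
        rows[st.genome_id] = {
            "logit_coverage": np.log(cov / (1 - cov)),
            "log_median_depth": np.log(max(st.median_depth, eps)),
            "log_dispersion": np.log(max(st.dispersion, eps)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def gmm_cluster(
    features: pd.DataFrame,
    k: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    n_restarts: int = 10,
) -> tuple[np.ndarray, GaussianMixture]:
    """Diagonal-covariance Gaussian mixture over genome features (EM, best
    of ``n_restarts`` by log-likelihood)."""
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(X) < k:
        raise ValueError(f"need at least k={k} genomes, got {len(X)}")
    model = GaussianMixture(
        n_components=k,
        covariance_type="diag",
        n_init=n_restarts,
        tol=tol,
        reg_covar=1e-6,
        random_state=seed,
    ).fit(X)
    return model.predict(X), model


#: Scale separation required between a candidate's depth dispersion and the
#: background cluster's typical dispersion (an order of magnitude).
DISPERSION_FOLD = 10.0


def select_candidate_genomes(
    stats: list[GenomeStats],
    labels: np.ndarray,
    coverage_floor: float = COVERAGE_FLOOR,
    dispersion_fold: float = DISPERSION_FOLD,
) -> set[str]:
    """Putative PT carriers from the genome triage.

    The bulk of a mixed community is PT-free, so the most populous GMM
    cluster calibrates the null: its median depth-dispersion is what
    abundance-driven background nicks produce (uniform nicks keep the
    variance-to-mean ratio of per-base depth near or below 1).  Capture of
    cleavage fragments instead concentrates depth at PT sites, inflating a
    carrier's dispersion by orders of magnitude regardless of its relative
    abundance — median depth alone is abundance-confounded.  A genome is
    selected when its dispersion exceeds ``dispersion_fold`` times the null
    and its coverage clears the floor (default 15%).
    """
    if len(stats) != len(labels):
        raise ValueError("one label per genome required")
    lab = np.asarray(labels)
    counts = pd.Series(lab).value_counts()
    background = counts.index[0]
    null_disp = float(
        np.median([s.dispersion for s, l in zip(stats, lab) if l == background])
    )
    threshold = dispersion_fold * max(null_disp, 1e-6)
    chosen = {
        s.genome_id
        for s in stats
        if s.dispersion > threshold and s.coverage > coverage_floor
    }
    if not chosen:
        logger.warning("no genome passed dispersion + coverage selection")
    return chosen


@dataclass(frozen=True)
class PileupSite:
    """A called PT site: linkage position p (0-based, 5' base of the
    dinucleotide on its strand), with the 5'-end depth observed at the
    cleavage point one position 3' of the linkage."""

    genome_id: str
    position: int
    strand: str
    depth: float
    dinucleotide: str
    window: str  # 13 nt centered on the cleavage point, strand-oriented


def five_prime_depths(
    alignments: pd.DataFrame, genome_id: str
) -> dict[tuple[int, str], float]:
    """Weighted 5'-end depth per (position, strand)."""
    sub = alignments[alignments["genome"] == genome_id]
    depths: dict[tuple[int, str], float] = {}
    for pos, strand, w in zip(sub["pos0"], sub["strand"], sub["weight"]):
        key = (int(pos), strand)
        depths[key] = depths.get(key, 0.0) + float(w)
    return depths


def _window_at(genome: str, c: int, strand: str) -> str | None:
    if c < WINDOW_FLANK or c + WINDOW_FLANK + 1 > len(genome):
        return None
    w = genome[c - WINDOW_FLANK:c + WINDOW_FLANK + 1]
    return w if strand == "+" else revcomp(w)


def call_pileups(
    alignments: pd.DataFrame,
    genome_id: str,
    genome: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[PileupSite]:
    """Sites whose weighted 5'-end depth reaches ``cutoff``.

    The linkage position is one position 5' of the read end on its strand
    (p = c-1 on plus, p = c+1 on minus in forward coordinates).  Sites whose
    13-nt window would cross a contig end are skipped (counted in the log).
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    sites = []
    n_edge = 0
    for (c, strand), depth in five_prime_depths(alignments, genome_id).items():
        if depth < cutoff:
            continue
        window = _window_at(genome, c, strand)
        if window is None:
            n_edge += 1
            continue
        p = c - 1 if strand == "+" else c + 1
        sites.append(
            PileupSite(genome_id, p, strand, depth,
                       site_dinucleotide(genome, p, strand), window)
        )
    if n_edge:
        logger.info("%s: %d pileups within %d nt of a contig end skipped",
                    genome_id, n_edge, WINDOW_FLANK)
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def cutoff_sweep(
    alignments: pd.DataFrame,
    genome_id: str,
    genome: str,
    target_dinucleotides: set[str],
    cutoffs=SWEEP_CUTOFFS,
) -> pd.DataFrame:
    """Site counts and target-dinucleotide specificity across depth cutoffs."""
    if not target_dinucleotides:
        raise ValueError("target dinucleotide set must be non-empty")
    depths = five_prime_depths(alignments, genome_id)
    entries = []
    for (c, strand), depth in depths.items():
        if _window_at(genome, c, strand) is None:
            continue
        p = c - 1 if strand == "+" else c + 1
        entries.append((depth, site_dinucleotide(genome, p, strand)))
    rows = []
    for cutoff in cutoffs:
        called = [d for d in entries if d[0] >= cutoff]
        n_target = sum(1 for _, dn in called if dn in target_dinucleotides)
        rows.append(
            {
                "cutoff": cutoff,
                "n_sites": len(called),
                "n_target": n_target,
                "specificity": n_target / len(called) if called else np.nan,
            }
        )
    return pd.DataFrame(rows)


def extract_windows(sites: list[PileupSite], genome: str) -> list[str]:
    """13-nt strand-oriented windows centered on each site's cleavage point;
    window columns 5-6 hold the linkage dinucleotide."""
    windows = []
    n_skipped = 0
    for s in sites:
        c = s.position + 1 if s.strand == "+" else s.position - 1
        w = _window_at(genome, c, s.strand)
        if w is None:
            n_skipped += 1
            continue
        windows.append(w)
    if n_skipped:
        logger.info("%d sites within %d nt of a contig end skipped", n_skipped, WINDOW_FLANK)
    return windows


@dataclass(frozen=True)
class MotifResult:
    consensus: str        # e.g. "C*AG" — "*" marks the linkage
    k: int
    offset: int           # window column of the k-mer's first base
    site_count: int
    n_windows: int
    fold_enrichment: float
    p_adjusted: float     # Bonferroni over all (k, offset, k-mer) hypotheses


def _background_kmer_freqs(genome: str, k: int) -> dict[str, float]:
    counts: dict[str, int] = {}
    for seq in (genome, revcomp(genome)):
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    total = 2 * (len(genome) - k + 1)
    return {kmer: n / total for kmer, n in counts.items()}


def find_anchored_motifs(
    windows: list[str],
    background_genome: str,
    k_range: tuple[int, int] = (3, 6),
    alpha: float = 0.05,
    max_motifs: int = 5,
    min_windows: int = 20,
) -> list[MotifResult]:
    """Anchored consensus-motif discovery in pileup windows.

    Because the linkage dinucleotide is pinned at window columns 5-6, every
    candidate motif is a k-mer (k in ``k_range``) at an offset covering both
    columns.  Exact k-mer counts across windows are scored against the
    genome's background k-mer frequency with a binomial test, Bonferroni-
    corrected over the full (k, offset, k-mer) hypothesis space.  Accepted
    motifs greedily explain their windows (zero-or-one occurrence per
    window) before the next round, up to ``max_motifs``.
    """
    if len(windows) < min_windows:
        raise ValueError(f"need >= {min_windows} windows, got {len(windows)}")
    wlen = len(windows[0])
    anchor = wlen // 2 - 1  # linkage 5' base column (5 for 13-nt windows)
    ks = range(k_range[0], k_range[1] + 1)
    offsets = {
        k: [o for o in range(wlen - k + 1) if o <= anchor and o + k - 1 >= anchor + 1]
        for k in ks
    }
    n_hypotheses = sum(len(offsets[k]) * 4**k for k in ks)
    background = {k: _background_kmer_freqs(background_genome, k) for k in ks}

    active = list(windows)
    results: list[MotifResult] = []
    while active and len(results) < max_motifs:
        best = None
        for k in ks:
            for off in offsets[k]:
                counts: dict[str, int] = {}
                for w in active:
                    kmer = w[off:off + k]
                    counts[kmer] = counts.get(kmer, 0) + 1
                for kmer, cnt in counts.items():
                    if cnt < 2:
                        continue
                    p0 = background[k].get(kmer, 1.0 / (4**k * len(background_genome)))
                    # log-scale Bonferroni-adjusted binomial tail; where the
                    # tail underflows past log-space, the log-pmf at the
                    # observed count preserves the ordering
                    log_tail = stats.binom.logsf(cnt - 1, len(active), p0)
                    if not np.isfinite(log_tail):
                        log_tail = stats.binom.logpmf(cnt, len(active), p0)
                    log_padj = log_tail + np.log(n_hypotheses)
                    key = (log_padj, -cnt)
                    if best is None or key < best[0]:
                        best = (key, kmer, k, off, cnt, p0)
        if best is None:
            break
        (log_padj, _), kmer, k, off, cnt, p0 = best
        p_adj = float(min(1.0, np.exp(log_padj)))
        if p_adj >= alpha:
            break
        star = anchor - off + 1
        results.append(
            MotifResult(
                consensus=kmer[:star] + "*" + kmer[star:],
                k=k,
                offset=off,
                site_count=cnt,
                n_windows=len(active),
                fold_enrichment=(cnt / len(active)) / p0,
                p_adjusted=p_adj,
            )
        )
        active = [w for w in active if w[off:off + k] != kmer]
    return results


def equivalent_pt_per_million(
    site_counts: dict[str, dict[str, int]],
    genome_lengths: dict[str, int],
    relative_abundances: dict[str, float],
) -> PTProfile:
    """Equivalent PTs per 10^6 nt from called-site counts.

    level(d) = 1e6 * sum_g abundance_g * sites_g(d) / (2 * length_g);
    the factor 2 puts per-strand site counts on the double-stranded
    nucleotide scale measured by LC-MS.
    """
    total_ab = sum(relative_abundances.values())
    if abs(total_ab - 1.0) > 1e-6:
        raise ValueError("relative abundances must sum to 1")
    levels: dict[str, float] = {}
    for gid, counts in site_counts.items():
        ab = relative_abundances[gid]
        length = genome_lengths[gid]
        for dinuc, n in counts.items():
            label = star_label(dinuc) if "*" not in dinuc else dinuc
            levels[label] = levels.get(label, 0.0) + 1e6 * ab * n / (2 * length)
    return PTProfile(levels)


def crossvalidate_lcms(
    ptseq_profile: PTProfile,
    lcms_profile: PTProfile,
    lod_table: dict[str, float],
) -> pd.DataFrame:
    """Per-dinucleotide comparison of the two assays.

    Dinucleotides seen by sequencing but absent from (or below) the LC-MS
    limit of detection are flagged ``below-LOD`` rather than discordant —
    e.g. G*C, whose LC-MS sensitivity is five-fold lower than G*A's.
    """
    labels = sorted(set(ptseq_profile.levels) | set(lcms_profile.levels))
    if not set(ptseq_profile.levels) & set(lcms_profile.levels):
        logger.warning("no dinucleotide detected by both assays")
    rows = []
    for d in labels:
        seq_level = ptseq_profile.levels.get(d, 0.0)
        ms_level = lcms_profile.levels.get(d, 0.0)
        lod = lod_table.get(d, np.inf)
        below_lod = seq_level > 0 and ms_level == 0 and seq_level < lod
        rows.append(
            {
                "dinucleotide": d,
                "ptseq_level": seq_level,
                "lcms_level": ms_level,
                "ratio": ms_level / seq_level if seq_level > 0 else np.nan,
                "abs_difference": abs(seq_level - ms_level),
                "below_lod": below_lod,
            }
        )
    return pd.DataFrame(rows)


def pileups_to_bed(sites: list[PileupSite]) -> pd.DataFrame:
    """Called sites as 6-column BED (0-based half-open; score = 100x depth)."""
    return pd.DataFrame(
        {
            "chrom": [s.genome_id for s in sites],
            "start": [s.position for s in sites],
            "end": [s.position + 2 for s in sites],
            "name": [s.dinucleotide for s in sites],
            "score": [int(round(100 * s.depth)) for s in sites],
            "strand": [s.strand for s in sites],
        }
    )
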