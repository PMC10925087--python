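"""Quality-aware windowed realignment of reads against candidate haplotypes.

Raw pileup counts are unreliable where the aligner's placement of a read is
ambiguous.  Instead, for every (read, candidate site) pair we compute
read-haplotype likelihoods P(R|H) with a banded pair-HMM forward algorithm
over short reference windows in which either the reference or the alternate
allele has been substituted.  The difference ``logp_alt - logp_ref`` is the
realignment evidence that the read carries the alternate allele, and feeds
the genotyper, the haplotagger and the somatic classifier.

The HMM has match/insert/delete states with affine gap transitions
(``gap_open``, ``gap_extend``); match emissions come from the base quality
(correct base: 1 - 10^(-q/10), each other base: 10^(-q/10)/3, quality capped),
insertions emit uniformly over the four bases.  The forward sum is restricted
to a diagonal band.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from numba import njit

_NEG_INF = -np.inf
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


class BandOverflowError(ValueError):
    """The diagonal band cannot connect the alignment start and end corners."""


@dataclasses.dataclass(frozen=True)
class HmmParams:
    """Pair-HMM parameters.

    Defaults (gap open 1e-3, gap extend 0.1, band 20) are stand-ins tuned for
    modern long reads and are deliberately configurable; base qualities are
    capped at ``max_quality`` to keep match emissions away from 1.
    """

    gap_open: float = 1e-3
    gap_extend: float = 0.1
    band_width: int = 20
    min_emission: float = 1e-8
    max_quality: int = 40

    def __post_init__(self) -> None:
        for name in ("gap_open", "gap_extend"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")


@dataclasses.dataclass(frozen=True)
class WindowedHaplotype:
    """A short reference window with zero or more candidate alleles substituted."""

    window: Tuple[int, int]  # 0-based half-open reference interval
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError("haplotype window sequence is empty")


@dataclasses.dataclass
class ReadAlleleLikelihoods:
    """Realignment likelihoods of one read against both alleles of one site."""

    read_id: str
    site_index: int
    logp_ref: float
    logp_alt: float
    strand: str  # '+' or '-'
    passes_qc: bool = True
    #: mismatch rate of the read against the reference window it was scored
    #: in; reads crossing structural-variant breakpoints show high values
    window_mismatch: float = 0.0


@njit(cache=True)
def _forward_banded(read, quals, hap, log_go, log_ge, log_m, log_back,
                    band, min_emission):  # pragma: no cover - exercised via wrapper
    n = read.shape[0]
    m = hap.shape[0]
    M = np.full((n + 1, m + 1), _NEG_INF)
    I = np.full((n + 1, m + 1), _NEG_INF)
    D = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    log_insert = np.log(0.25)
    for j in range(1, min(m, band) + 1):
        # leading deletions along the top row
        prev_m = M[0, j - 1] + log_go
        prev_d = D[0, j - 1] + log_ge
        D[0, j] = np.logaddexp(prev_m, prev_d)
    for i in range(1, n + 1):
        lo = max(1, i - band)
        hi = min(m, i + band)
        if i <= band:
            # leading insertions along the first column
            I[i, 0] = log_insert + np.logaddexp(
                M[i - 1, 0] + log_go, I[i - 1, 0] + log_ge
            )
        for j in range(lo, hi + 1):
            e = 10.0 ** (-quals[i - 1] / 10.0)
            if read[i - 1] == hap[j - 1]:
                emit = 1.0 - e
            else:
                emit = e / 3.0
            if emit < min_emission:
                emit = min_emission
            stay = np.logaddexp(M[i - 1, j - 1] + log_m,
                                np.logaddexp(I[i - 1, j - 1] + log_back,
                                             D[i - 1, j - 1] + log_back))
            M[i, j] = np.log(emit) + stay
            I[i, j] = log_insert + np.logaddexp(M[i - 1, j] + log_go,
                                                I[i - 1, j] + log_ge)
            D[i, j] = np.logaddexp(M[i, j - 1] + log_go, D[i, j - 1] + log_ge)
    # close every path with its exit-to-match transition; this makes path
    # weights invariant under joint reversal of read and haplotype
    return np.logaddexp(
        M[n, m] + log_m, np.logaddexp(I[n, m] + log_back, D[n, m] + log_back)
    )


def _encode_bases(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, b in enumerate(seq.upper()):
        out[i] = _BASE_INDEX.get(b, 4)  # non-ACGT never matches
    return out


def realign_likelihood(
    read_bases: str,
    base_qualities: Sequence[int],
    haplotype: WindowedHaplotype | str,
    params: Optional[HmmParams] = None,
) -> float:
    """log P(read | haplotype) by the banded pair-HMM forward algorithm."""
    if params is None:
        params = HmmParams()
    hap_seq = haplotype.sequence if isinstance(haplotype, WindowedHaplotype) else haplotype
    if len(read_bases) == 0:
        raise ValueError("read segment is empty")
    if len(hap_seq) == 0:
        raise ValueError("haplotype window is empty")
    if len(read_bases) != len(base_qualities):
        raise ValueError("read bases and qualities differ in length")
    if abs(len(read_bases) - len(hap_seq)) > params.band_width:
        raise BandOverflowError(
            f"band width {params.band_width} cannot align lengths "
            f"{len(read_bases)} and {len(hap_seq)}"
        )
    read = _encode_bases(read_bases)
    hap = _encode_bases(hap_seq)
    quals = np.minimum(
        np.asarray(base_qualities, dtype=np.float64), float(params.max_quality)
    )
    go, ge = params.gap_open, params.gap_extend
    return float(
        _forward_banded(
            read,
            quals,
            hap,
            np.log(go),
            np.log(ge),
            np.log(1.0 - 2.0 * go),
            np.log(1.0 - ge),
            params.band_width,
            params.min_emission,
        )
    )


# ---------------------------------------------------------------------------
# fragment extraction from BAM
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class Site:
    """A biallelic candidate SNV site (0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos + 1}: ref equals alt")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.chrom}:{self.pos + 1}: SNVs only")


@dataclasses.dataclass(frozen=True)
class ExtractConfig:
    flank: int = 20
    min_mapq: int = 20
    max_cluster: int = 4  # combination haplotypes for up to 2^k nearby sites


def _read_passes_qc(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return not (
        read.is_unmapped
        or read.is_secondary
        or read.is_supplementary
        or read.is_duplicate
        or read.mapping_quality < min_mapq
    )


def _cluster_sites(sites: Sequence[Site], flank: int) -> List[List[int]]:
    """Group site indices whose positions are closer than ``flank`` bases."""
    clusters: List[List[int]] = []
    for idx in range(len(sites)):
        if clusters and sites[idx].pos - sites[clusters[-1][-1]].pos < flank:
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    return clusters


def _segment_in_window(
    ref_pos: np.ndarray, query_pos: np.ndarray, start: int, end: int
) -> Optional[Tuple[int, int]]:
    """Query-coordinate span of the read bases aligned within [start, end)."""
    lo = int(np.searchsorted(ref_pos, start, side="left"))
    hi = int(np.searchsorted(ref_pos, end, side="left"))
    if hi <= lo:
        return None
    return int(query_pos[lo]), int(query_pos[hi - 1]) + 1


def extract_fragments(
    bam: str | pysam.AlignmentFile,
    sites: Sequence[Site],
    reference: str | pysam.FastaFile,
    region: Optional[Tuple[str, int, int]] = None,
    config: Optional[ExtractConfig] = None,
    hmm: Optional[HmmParams] = None,
) -> Dict[int, List[ReadAlleleLikelihoods]]:
    """Realignment likelihoods for every QC-passing (read, site) pair.

    ``sites`` must be sorted by position on a single contig.  Sites closer
    than the window flank are evaluated jointly: all allele combinations of
    the cluster (up to ``2^max_cluster``) are substituted into the shared
    window and the per-allele likelihood is the average over the combination
    haplotypes carrying that allele.  Larger clusters fall back to
    substituting each site alone.

    Returns a mapping from site index (into ``sites``) to the per-read
    likelihood records.
    """
    config = config or ExtractConfig()
    hmm = hmm or HmmParams()
    own_bam = isinstance(bam, str)
    bam_f = pysam.AlignmentFile(bam) if own_bam else bam
    own_ref = isinstance(reference, str)
    ref_f = pysam.FastaFile(reference) if own_ref else reference
    try:
        return _extract(bam_f, sites, ref_f, region, config, hmm)
    finally:
        if own_bam:
            bam_f.close()
        if own_ref:
            ref_f.close()


def _extract(bam, sites, ref, region, config, hmm):
    if not sites:
        return {}
    chroms = {s.chrom for s in sites}
    if len(chroms) > 1:
        raise ValueError("sites must lie on a single contig")
    chrom = sites[0].chrom
    positions = [s.pos for s in sites]
    if any(b > a for a, b in zip(positions[1:], positions)):
        raise ValueError("sites must be sorted by position")
    contig_len = ref.get_reference_length(chrom)
    for s in sites:
        base = ref.fetch(chrom, s.pos, s.pos + 1).upper()
        if base != s.ref:
            raise ValueError(
                f"{chrom}:{s.pos + 1}: site ref {s.ref} does not match reference {base}"
            )

    clusters = _cluster_sites(sites, config.flank)
    windows = []  # (start, end, [site indices], [haplotype variants])
    for cluster in clusters:
        start = max(0, sites[cluster[0]].pos - config.flank)
        end = min(contig_len, sites[cluster[-1]].pos + config.flank + 1)
        window_ref = ref.fetch(chrom, start, end).upper()
        windows.append((start, end, cluster, window_ref))

    out: Dict[int, List[ReadAlleleLikelihoods]] = {i: [] for i in range(len(sites))}
    win_starts = np.array([w[0] for w in windows])
    max_window = max(w[1] - w[0] for w in windows)

    if region is None:
        fetch_args = (chrom, max(0, windows[0][0]), windows[-1][1])
    else:
        fetch_args = region
    for read in bam.fetch(*fetch_args):
        if not _read_passes_qc(read, config.min_mapq):
            continue
        if read.query_sequence is None or read.query_qualities is None:
            continue
        pairs = read.get_aligned_pairs(matches_only=True)
        if not pairs:
            continue
        q_pos = np.array([p[0] for p in pairs])
        r_pos = np.array([p[1] for p in pairs])
        strand = "-" if read.is_reverse else "+"
        seq = read.query_sequence.upper()
        seq_bytes = np.frombuffer(seq.encode(), dtype=np.uint8)
        quals = read.query_qualities
        first = int(
            np.searchsorted(win_starts, read.reference_start - max_window, "left")
        )
        for w in range(first, len(windows)):
            start, end, cluster, window_ref = windows[w]
            if start >= read.reference_end:
                break
            if end <= read.reference_start:
                continue
            # the read must cover every site of the cluster it is scored on
            span = _segment_in_window(r_pos, q_pos, start, end)
            if span is None:
                continue
            covered = [
                i
                for i in cluster
                if np.searchsorted(r_pos, sites[i].pos) < len(r_pos)
                and r_pos[np.searchsorted(r_pos, sites[i].pos)] == sites[i].pos
            ]
            if not covered:
                continue
            # clip the window to the read's aligned extent
            lo = int(np.searchsorted(r_pos, start, "left"))
            hi = int(np.searchsorted(r_pos, end, "left"))
            w_start = int(r_pos[lo])
            w_end = int(r_pos[hi - 1]) + 1
            seg = seq[span[0]: span[1]]
            seg_quals = quals[span[0]: span[1]]
            local = window_ref[w_start - start: w_end - start]
            wr_bytes = np.frombuffer(local.encode(), dtype=np.uint8)
            mismatch = float(
                np.mean(
                    seq_bytes[q_pos[lo:hi]] != wr_bytes[r_pos[lo:hi] - w_start]
                )
            )
            offsets = [sites[i].pos - w_start for i in covered]
            k = len(covered)
            if k <= config.max_cluster:
                combo_logs = np.empty(2 ** k)
                for mask in range(2 ** k):
                    hseq = list(local)
                    for bit, (i, off) in enumerate(zip(covered, offsets)):
                        hseq[off] = sites[i].alt if (mask >> bit) & 1 else sites[i].ref
                    try:
                        combo_logs[mask] = realign_likelihood(
                            seg, seg_quals, "".join(hseq), hmm
                        )
                    except BandOverflowError:
                        combo_logs[mask] = _NEG_INF
                if not np.any(np.isfinite(combo_logs)):
                    continue
                for bit, i in enumerate(covered):
                    alt_mask = [(m >> bit) & 1 == 1 for m in range(2 ** k)]
                    l_alt = _log_mean(combo_logs[np.array(alt_mask)])
                    l_ref = _log_mean(combo_logs[~np.array(alt_mask)])
                    _append(out, i, read, l_ref, l_alt, strand, mismatch)
            else:
                for i, off in zip(covered, offsets):
                    logs = {}
                    for allele in (sites[i].ref, sites[i].alt):
                        hseq = list(local)
                        hseq[off] = allele
                        try:
                            logs[allele] = realign_likelihood(
                                seg, seg_quals, "".join(hseq), hmm
                            )
                        except BandOverflowError:
                            logs[allele] = _NEG_INF
                    if np.isfinite(logs[sites[i].ref]) or np.isfinite(logs[sites[i].alt]):
                        _append(
                            out, i, read,
                            logs[sites[i].ref], logs[sites[i].alt], strand, mismatch,
                        )
    return out


def _log_mean(logs: np.ndarray) -> float:
    finite = logs[np.isfinite(logs)]
    if finite.size == 0:
        return _NEG_INF
    m = finite.max()
    return float(m + np.log(np.sum(np.exp(finite - m)) / logs.size))


def _append(out, i, read, l_ref, l_alt, strand, mismatch=0.0):
    out[i].append(
        ReadAlleleLikelihoods(
            read_id=read.query_name,
            site_index=i,
            logp_ref=l_ref,
            logp_alt=l_alt,
            strand=strand,
            passes_qc=True,
            window_mismatch=mismatch,
        )
    )
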