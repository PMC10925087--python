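"""Tumour-only somatic mutation calling over phased long reads.

The caller works in genome windows: reads are haplotagged from a phased
heterozygous-SNP VCF, per-haplotype depths define the *callable* footprint
(both haplotypes >= 10x, total <= 400x), permissive per-haplotype candidate
discovery picks up any modal non-reference base seen at least 3 times and in
more than 10% of the haplotype's reads, and each candidate is classified on
its haplotype of origin into {somatic, het SNP, reference} using realignment
likelihoods.  The somatic class models the mutant-read fraction as
``alpha * phi`` where ``phi`` is the unknown cancer cell fraction, drawn
from a clonal point mass at 1 (weight ``rho``) plus a Beta(a, b) subclonal
component that is integrated numerically.  Calls then pass through six
independent filters before VCF/BED emission.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist, fisher_exact

from .haplotagger import HaplotagConfig, HaplotypeAssignment, PhasedHaplotypes, tag_reads
from .realign import (
    ExtractConfig,
    HmmParams,
    ReadAlleleLikelihoods,
    Site,
    _read_passes_qc,
    extract_fragments,
)

FILTER_NAMES = (
    "MaxOtherHaplotypeObservations",
    "MinObsPerStrand",
    "PossibleAlignmentArtifact",
    "LowQual",
    "MinHaplotypeDepth",
    "StrandBias",
)

_BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class CCFPrior:
    """Cancer-cell-fraction prior: point mass ``rho`` at 1 plus Beta(a, b)."""

    rho: float = 0.95
    a: float = 2.0
    b: float = 2.0
    n_bins: int = 100

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shape parameters must be > 0")
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")

    def grid(self) -> Tuple[np.ndarray, np.ndarray]:
        """Midpoint bins over (0, 1) and their Beta-weighted masses (sum 1-rho)."""
        edges = np.linspace(0.0, 1.0, self.n_bins + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        mass = np.diff(beta_dist.cdf(edges, self.a, self.b))
        return mids, (1.0 - self.rho) * mass


@dataclasses.dataclass(frozen=True)
class CallerConfig:
    alpha: float = 0.5  # tumour purity; the method needs normal contamination
    window_size: int = 10_000_000
    min_hap_depth: int = 10
    max_total_depth: int = 400
    candidate_min_fraction: float = 0.10
    candidate_min_obs: int = 3
    qual_threshold: float = 20.0
    qual_cap: float = 60.0
    mu_prior: float = 1e-5
    pi_prior: float = 1e-3
    ccf: CCFPrior = dataclasses.field(default_factory=CCFPrior)
    max_other_hap_obs: int = 2
    max_other_hap_frac: float = 0.20
    artifact_mismatch_rate: float = 0.15
    artifact_read_fraction: float = 0.5
    strand_bias_p: float = 1e-3
    haplotag: HaplotagConfig = dataclasses.field(default_factory=HaplotagConfig)
    extract: ExtractConfig = dataclasses.field(default_factory=ExtractConfig)
    hmm: HmmParams = dataclasses.field(default_factory=HmmParams)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(
                "alpha must be in (0, 1): a purely tumour sample carries no "
                "evidence of the inherited allele"
            )
        if self.min_hap_depth < 1 or self.max_total_depth < 1:
            raise ValueError("depth bounds must be positive")
        if not (0.0 < self.mu_prior and 0.0 < self.pi_prior
                and self.mu_prior + self.pi_prior < 1.0):
            raise ValueError("class priors must be positive and sum below 1")


@dataclasses.dataclass(frozen=True)
class CandidateSite:
    chrom: str
    pos: int
    ref: str
    alt: str
    haplotype: int  # haplotype on which the candidate was discovered
    hap_alt_count: int
    hap_depth: int


@dataclasses.dataclass
class MutationCall:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    haplotype: int
    qual: float
    p_somatic: float
    p_het: float
    p_reference: float
    hap_depths: Tuple[int, int]
    other_hap_alt: int
    other_hap_depth: int
    alt_strand_counts: Tuple[int, int]  # forward, reverse among alt reads
    ref_strand_counts: Tuple[int, int]
    artifact_read_fraction: float
    filters: frozenset = frozenset()

    @property
    def is_pass(self) -> bool:
        return len(self.filters) == 0


# ---------------------------------------------------------------------------
# callable regions
# ---------------------------------------------------------------------------


def haplotype_coverage(
    bam: pysam.AlignmentFile,
    assignments: Dict[str, HaplotypeAssignment],
    region: Tuple[str, int, int],
    min_mapq: int = 20,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-position ACGT counts for each haplotype, shape (2, 4, length).

    Counts only QC-passing, haplotype-assigned reads.
    """
    chrom, start, end = region

    def callback(hap):
        def cb(read):
            asg = assignments.get(read.query_name)
            return (
                asg is not None
                and asg.haplotype == hap
                and _read_passes_qc(read, min_mapq)
            )
        return cb

    cov = []
    for hap in (0, 1):
        counts = bam.count_coverage(
            chrom, start, end, quality_threshold=0, read_callback=callback(hap)
        )
        cov.append(np.array(counts, dtype=np.int64))
    return cov[0], cov[1]


def find_callable(
    cov0: np.ndarray,
    cov1: np.ndarray,
    region_start: int,
    config: Optional[CallerConfig] = None,
) -> Tuple[List[Tuple[int, int]], np.ndarray, np.ndarray]:
    """Maximal merged intervals where both haplotypes are adequately covered.

    A position is callable when both haplotype depths are at least
    ``min_hap_depth`` and their sum does not exceed ``max_total_depth``.
    Returns 0-based half-open intervals plus the two depth vectors.
    """
    config = config or CallerConfig()
    d0 = cov0.sum(axis=0)
    d1 = cov1.sum(axis=0)
    mask = (
        (d0 >= config.min_hap_depth)
        & (d1 >= config.min_hap_depth)
        & (d0 + d1 <= config.max_total_depth)
    )
    intervals = mask_to_intervals(mask, region_start)
    return intervals, d0, d1


def mask_to_intervals(mask: np.ndarray, offset: int = 0) -> List[Tuple[int, int]]:
    """Merge a boolean per-position mask into 0-based half-open intervals."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [(int(s) + offset, int(e) + offset) for s, e in zip(starts, ends)]


# ---------------------------------------------------------------------------
# candidate discovery
# ---------------------------------------------------------------------------


def discover_candidates(
    cov0: np.ndarray,
    cov1: np.ndarray,
    reference_window: str,
    region_start: int,
    callable_mask: np.ndarray,
    config: Optional[CallerConfig] = None,
) -> List[CandidateSite]:
    """Permissive per-haplotype candidate discovery over callable positions.

    On each haplotype the modal non-reference base becomes a candidate when
    it is observed at least ``candidate_min_obs`` times and in more than
    ``candidate_min_fraction`` of the haplotype's reads.
    """
    config = config or CallerConfig()
    cov0 = np.asarray(cov0, dtype=np.int64)
    cov1 = np.asarray(cov1, dtype=np.int64)
    ref_idx = np.frombuffer(reference_window.upper().encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        code[ord(b)] = i
    ref_code = code[ref_idx]
    n = len(reference_window)
    out: List[CandidateSite] = []
    cols = np.arange(n)
    for hap, cov in ((0, cov0), (1, cov1)):
        counts = cov.copy()
        valid = ref_code >= 0
        counts[ref_code[valid], cols[valid]] = -1  # exclude the reference base
        modal = counts.argmax(axis=0)
        modal_n = counts[modal, cols]
        depth = cov.sum(axis=0)
        sel = (
            valid
            & callable_mask
            & (modal_n >= config.candidate_min_obs)
            & (modal_n > config.candidate_min_fraction * depth)
        )
        for i in np.flatnonzero(sel):
            out.append(
                CandidateSite(
                    chrom="",
                    pos=region_start + int(i),
                    ref=_BASES[ref_code[i]],
                    alt=_BASES[int(modal[i])],
                    haplotype=hap,
                    hap_alt_count=int(modal_n[i]),
                    hap_depth=int(depth[i]),
                )
            )
    out.sort(key=lambda c: (c.pos, c.haplotype))
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def somatic_log_likelihood(
    logp_ref: np.ndarray,
    logp_alt: np.ndarray,
    alpha: float,
    ccf: CCFPrior,
) -> float:
    """log P(reads | somatic): per-read CCF mixture, integrated numerically.

    Each read's likelihood is ``(1 - alpha*phi) P(R|ref) + alpha*phi P(R|alt)``
    marginalized over the CCF prior (clonal point mass handled analytically,
    Beta component by midpoint bins), then multiplied across reads.
    """
    phi, w = ccf.grid()
    lpr = np.asarray(logp_ref)[:, None]
    lpa = np.asarray(logp_alt)[:, None]
    with np.errstate(divide="ignore"):
        log_mix = np.logaddexp(
            lpr + np.log1p(-alpha * phi)[None, :],
            lpa + np.log(alpha * phi)[None, :],
        )
        sub = logsumexp(log_mix, axis=1, b=w[None, :]) if ccf.rho < 1.0 else None
        clonal = np.logaddexp(
            np.asarray(logp_ref) + np.log1p(-alpha),
            np.asarray(logp_alt) + np.log(alpha),
        ) + np.log(ccf.rho) if ccf.rho > 0.0 else None
    if sub is None:
        per_read = clonal
    elif clonal is None:
        per_read = sub
    else:
        per_read = np.logaddexp(clonal, sub)
    return float(per_read.sum())


def classify_candidate(
    reads: Sequence[ReadAlleleLikelihoods],
    config: Optional[CallerConfig] = None,
) -> Tuple[np.ndarray, float]:
    """Class posteriors (somatic, het, reference) and PHRED QUAL for a candidate.

    ``reads`` must be the realignment records restricted to the candidate's
    haplotype.  The reference class expects every read to match the reference
    allele, the het class every read to match the alternate, and the somatic
    class the purity-scaled CCF mixture.
    """
    config = config or CallerConfig()
    if not reads:
        raise ValueError("no reads on candidate haplotype")
    lpr = np.array([r.logp_ref for r in reads])
    lpa = np.array([r.logp_alt for r in reads])
    loglik = np.array(
        [
            somatic_log_likelihood(lpr, lpa, config.alpha, config.ccf),
            lpa.sum(),
            lpr.sum(),
        ]
    )
    log_prior = np.log(
        np.array(
            [config.mu_prior, config.pi_prior, 1.0 - config.mu_prior - config.pi_prior]
        )
    )
    logpost = loglik + log_prior
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    p_not_som = max(1.0 - post[0], 10.0 ** (-config.qual_cap / 10.0))
    qual = min(config.qual_cap, -10.0 * np.log10(p_not_som))
    return post, float(qual)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def apply_filters(
    call: MutationCall, config: Optional[CallerConfig] = None
) -> MutationCall:
    """Evaluate the six hard filters independently and record all that fire."""
    config = config or CallerConfig()
    fired = set()
    if call.other_hap_alt > config.max_other_hap_obs or (
        call.other_hap_depth > 0
        and call.other_hap_alt / call.other_hap_depth > config.max_other_hap_frac
    ):
        fired.add("MaxOtherHaplotypeObservations")
    if min(call.alt_strand_counts) == 0:
        fired.add("MinObsPerStrand")
    if call.artifact_read_fraction > config.artifact_read_fraction:
        fired.add("PossibleAlignmentArtifact")
    if call.qual < config.qual_threshold:
        fired.add("LowQual")
    if min(call.hap_depths) < config.min_hap_depth:
        fired.add("MinHaplotypeDepth")
    table = np.array([list(call.ref_strand_counts), list(call.alt_strand_counts)])
    if table[1].sum() > 0 and table[0].sum() > 0:
        if fisher_exact(table)[1] < config.strand_bias_p:
            fired.add("StrandBias")
    return dataclasses.replace(call, filters=frozenset(fired))


# ---------------------------------------------------------------------------
# window orchestration
# ---------------------------------------------------------------------------


def call_window(
    bam: str,
    phased_vcf: str | PhasedHaplotypes,
    reference: str,
    region: Tuple[str, int, int],
    config: Optional[CallerConfig] = None,
) -> Tuple[List[MutationCall], List[Tuple[int, int]], Dict[str, HaplotypeAssignment]]:
    """Run the full calling pipeline on one genome window.

    Steps: haplotag reads, compute per-haplotype coverage, derive callable
    intervals, discover per-haplotype candidates, realign reads against both
    candidate alleles, classify each candidate on its haplotype with the CCF
    mixture model, and filter.  Returns (calls, callable intervals,
    read assignments); calls are sorted and deterministic given the inputs.
    """
    config = config or CallerConfig()
    chrom, start, end = region
    cfg_tag = dataclasses.replace(
        config.haplotag, extract=config.extract, hmm=config.hmm
    )
    if isinstance(phased_vcf, PhasedHaplotypes):
        haps = phased_vcf
    else:
        try:
            haps = PhasedHaplotypes.from_vcf(phased_vcf, region)
        except ValueError as exc:
            if "no phased heterozygous" in str(exc):
                # nothing can be haplotagged here: empty output, not an error
                return [], [], {}
            raise ValueError(f"window {chrom}:{start}-{end}: {exc}") from exc
    with pysam.AlignmentFile(bam) as bam_f, pysam.FastaFile(reference) as ref_f:
        if chrom not in bam_f.references:
            raise ValueError(f"window {chrom}:{start}-{end}: contig missing from BAM")
        try:
            assignments = tag_reads(
                bam_f, haps, ref_f, region=region, config=cfg_tag
            )
        except ValueError as exc:
            raise ValueError(f"window {chrom}:{start}-{end}: {exc}") from exc
        cov0, cov1 = haplotype_coverage(
            bam_f, assignments, region, config.extract.min_mapq
        )
        callable_intervals, d0, d1 = find_callable(cov0, cov1, start, config)
        callable_mask = np.zeros(end - start, dtype=bool)
        for s, e in callable_intervals:
            callable_mask[s - start : e - start] = True
        window_ref = ref_f.fetch(chrom, start, end)
        candidates = discover_candidates(
            cov0, cov1, window_ref, start, callable_mask, config
        )
        for i, cand in enumerate(candidates):
            candidates[i] = dataclasses.replace(cand, chrom=chrom)
        calls = _classify_and_filter(
            bam_f, ref_f, candidates, assignments, d0, d1, start, region, config
        )
    # same-site candidates on both haplotypes: keep the higher-QUAL call
    best: Dict[int, MutationCall] = {}
    for call in calls:
        prev = best.get(call.pos)
        if prev is None or call.qual > prev.qual:
            best[call.pos] = call
    out = sorted(best.values(), key=lambda c: c.pos)
    return out, callable_intervals, assignments


def _classify_and_filter(
    bam_f, ref_f, candidates, assignments, d0, d1, start, region, config
) -> List[MutationCall]:
    if not candidates:
        return []
    # unique positions; both-haplotype candidates share one realignment site
    site_map: Dict[Tuple[int, str], int] = {}
    sites: List[Site] = []
    for cand in candidates:
        key = (cand.pos, cand.alt)
        if key not in site_map:
            site_map[key] = len(sites)
            sites.append(Site(cand.chrom, cand.pos, cand.ref, cand.alt))
    order = np.argsort([s.pos for s in sites], kind="stable")
    sites = [sites[i] for i in order]
    site_map = {(s.pos, s.alt): i for i, s in enumerate(sites)}
    frags = extract_fragments(
        bam_f, sites, ref_f, region=region, config=config.extract, hmm=config.hmm
    )
    calls = []
    for cand in candidates:
        records = frags.get(site_map[(cand.pos, cand.alt)], [])
        by_hap: Dict[Optional[int], List[ReadAlleleLikelihoods]] = {0: [], 1: [], None: []}
        for rec in records:
            asg = assignments.get(rec.read_id)
            by_hap[asg.haplotype if asg is not None else None].append(rec)
        own = by_hap[cand.haplotype]
        other = by_hap[1 - cand.haplotype]
        if not own:
            continue
        post, qual = classify_candidate(own, config)
        alt_fwd = sum(1 for r in own if r.logp_alt > r.logp_ref and r.strand == "+")
        alt_rev = sum(1 for r in own if r.logp_alt > r.logp_ref and r.strand == "-")
        ref_fwd = sum(1 for r in own if r.logp_alt <= r.logp_ref and r.strand == "+")
        ref_rev = sum(1 for r in own if r.logp_alt <= r.logp_ref and r.strand == "-")
        other_alt = sum(1 for r in other if r.logp_alt > r.logp_ref)
        alt_reads = [r for r in own if r.logp_alt > r.logp_ref]
        noisy = sum(
            1 for r in alt_reads if r.window_mismatch > config.artifact_mismatch_rate
        )
        artifact_frac = noisy / len(alt_reads) if alt_reads else 0.0
        i = cand.pos - start
        call = MutationCall(
            chrom=cand.chrom,
            pos=cand.pos,
            ref=cand.ref,
            alt=cand.alt,
            haplotype=cand.haplotype,
            qual=qual,
            p_somatic=float(post[0]),
            p_het=float(post[1]),
            p_reference=float(post[2]),
            hap_depths=(int(d0[i]), int(d1[i])),
            other_hap_alt=other_alt,
            other_hap_depth=len(other),
            alt_strand_counts=(alt_fwd, alt_rev),
            ref_strand_counts=(ref_fwd, ref_rev),
            artifact_read_fraction=artifact_frac,
        )
        call = apply_filters(call, config)
        if np.argmax(post) == 0:
            calls.append(call)
    return calls


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_calls_vcf(
    calls: Sequence[MutationCall], path: str, contigs: Sequence[Tuple[str, int]]
) -> None:
    """Write calls as VCF 4.2 with the six filter names and INFO annotations."""
    header = pysam.VariantHeader()
    for name, length in contigs:
        header.add_line(f"##contig=<ID={name},length={length}>")
    descriptions = {
        "MaxOtherHaplotypeObservations": "Alternate allele observed on the non-called haplotype",
        "MinObsPerStrand": "Alternate allele not observed on both sequencing strands",
        "PossibleAlignmentArtifact": "Alt reads dominated by high-mismatch realignment windows",
        "LowQual": "QUAL below the calling threshold",
        "MinHaplotypeDepth": "Haplotype depth below the calling threshold",
        "StrandBias": "Significant allele-by-strand association",
    }
    for name in FILTER_NAMES:
        header.add_line(f'##FILTER=<ID={name},Description="{descriptions[name]}">')
    header.add_line('##INFO=<ID=HAP,Number=1,Type=Integer,Description="Haplotype of origin">')
    header.add_line('##INFO=<ID=PSOM,Number=1,Type=Float,Description="Posterior somatic probability">')
    header.add_line('##INFO=<ID=PHET,Number=1,Type=Float,Description="Posterior het probability">')
    header.add_line('##INFO=<ID=PREF,Number=1,Type=Float,Description="Posterior reference probability">')
    header.add_line('##INFO=<ID=HDP,Number=2,Type=Integer,Description="Haplotype depths">')
    header.add_line('##INFO=<ID=OHA,Number=1,Type=Integer,Description="Other-haplotype alt observations">')
    header.add_line('##INFO=<ID=OHD,Number=1,Type=Integer,Description="Other-haplotype depth">')
    header.add_line('##INFO=<ID=ALTSC,Number=2,Type=Integer,Description="Alt strand counts fwd,rev">')
    header.add_line('##INFO=<ID=REFSC,Number=2,Type=Integer,Description="Ref strand counts fwd,rev">')
    header.add_line('##INFO=<ID=ARTF,Number=1,Type=Float,Description="Fraction of alt reads with noisy windows">')
    # native VCF floats are 32-bit; FP64 carries the exact values for round-trips
    header.add_line('##INFO=<ID=FP64,Number=5,Type=String,Description="Full-precision QUAL,PSOM,PHET,PREF,ARTF">')
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos,
                stop=call.pos + 1,
                alleles=(call.ref, call.alt),
                qual=round(call.qual, 2),
            )
            if call.filters:
                for name in sorted(call.filters):
                    rec.filter.add(name)
            else:
                rec.filter.add("PASS")
            rec.info["HAP"] = call.haplotype
            rec.info["PSOM"] = call.p_somatic
            rec.info["PHET"] = call.p_het
            rec.info["PREF"] = call.p_reference
            rec.info["HDP"] = list(call.hap_depths)
            rec.info["OHA"] = call.other_hap_alt
            rec.info["OHD"] = call.other_hap_depth
            rec.info["ALTSC"] = list(call.alt_strand_counts)
            rec.info["REFSC"] = list(call.ref_strand_counts)
            rec.info["ARTF"] = call.artifact_read_fraction
            rec.info["FP64"] = tuple(
                repr(v)
                for v in (
                    call.qual,
                    call.p_somatic,
                    call.p_het,
                    call.p_reference,
                    call.artifact_read_fraction,
                )
            )
            out.write(rec)


def read_calls_vcf(path: str) -> List[MutationCall]:
    calls = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            filters = frozenset(f for f in rec.filter.keys() if f != "PASS")
            qual, psom, phet, pref, artf = (float(x) for x in rec.info["FP64"])
            calls.append(
                MutationCall(
                    chrom=rec.chrom,
                    pos=rec.start,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    haplotype=int(rec.info["HAP"]),
                    qual=qual,
                    p_somatic=psom,
                    p_het=phet,
                    p_reference=pref,
                    hap_depths=tuple(rec.info["HDP"]),
                    other_hap_alt=int(rec.info["OHA"]),
                    other_hap_depth=int(rec.info["OHD"]),
                    alt_strand_counts=tuple(rec.info["ALTSC"]),
                    ref_strand_counts=tuple(rec.info["REFSC"]),
                    artifact_read_fraction=artf,
                    filters=filters,
                )
            )
    return calls


def write_bed(intervals: Sequence[Tuple[int, int]], chrom: str, path: str) -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")
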