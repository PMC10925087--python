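"""Assignment of reads to phased haplotypes (haplotagging).

Given a phased heterozygous-SNP VCF, each phase set defines two allele
strings B0/B1 over its het sites.  A read's posterior over the two
haplotypes is the product, over the phased het sites it covers, of its
realignment likelihood for the allele that haplotype carries.  Reads are
left unassigned when the evidence is weak (PHRED assignment quality < 20)
or contradictory (the read's supported alleles mismatch more than 10% of
its assigned haplotype), which also discards reads spanning phase-block
boundaries.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .realign import ExtractConfig, HmmParams, Site, extract_fragments


@dataclasses.dataclass(frozen=True)
class HaplotagConfig:
    min_quality: float = 20.0  # PHRED mis-assignment quality threshold
    max_mismatch: float = 0.10
    prior: Tuple[float, float] = (0.5, 0.5)
    extract: ExtractConfig = dataclasses.field(default_factory=ExtractConfig)
    hmm: HmmParams = dataclasses.field(default_factory=HmmParams)


@dataclasses.dataclass(frozen=True)
class PhasedHaplotypes:
    """Allele strings of the two haplotypes over phased het sites.

    ``b0[i]`` is 0 if haplotype 0 carries the reference allele at site ``i``
    (haplotype 1 then carries the alternate), else 1.  ``phase_set[i]``
    identifies the phase block; relative phase is only defined within one.
    """

    sites: Tuple[Site, ...]
    b0: np.ndarray
    phase_set: np.ndarray

    def __post_init__(self) -> None:
        pos = [s.pos for s in self.sites]
        if any(b <= a for a, b in zip(pos, pos[1:])) and len(set(s.chrom for s in self.sites)) == 1:
            raise ValueError("phased sites must be strictly sorted")

    @classmethod
    def from_vcf(
        cls, path: str, region: Optional[Tuple[str, int, int]] = None
    ) -> "PhasedHaplotypes":
        sites: List[Site] = []
        b0: List[int] = []
        ps: List[int] = []
        with pysam.VariantFile(path) as vcf:
            if not vcf.header.samples:
                raise ValueError("phased VCF has no sample column")
            sample = vcf.header.samples[0]
            it = vcf.fetch(*region) if region else vcf.fetch()
            for rec in it:
                if rec.alts is None or len(rec.alts) != 1:
                    continue
                if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                    continue
                data = rec.samples[sample]
                gt = data["GT"]
                if gt is None or None in gt or gt[0] == gt[1]:
                    continue
                if not data.phased:
                    continue
                if "PS" not in data or data["PS"] is None:
                    raise ValueError(
                        f"{rec.chrom}:{rec.pos}: phased het record lacks a PS tag"
                    )
                sites.append(Site(rec.chrom, rec.start, rec.ref.upper(), rec.alts[0].upper()))
                b0.append(int(gt[0]))  # 1 => haplotype 0 carries ALT
                ps.append(int(data["PS"]))
        if not sites:
            raise ValueError("no phased heterozygous SNVs found")
        return cls(tuple(sites), np.array(b0, dtype=np.int8), np.array(ps))


@dataclasses.dataclass
class HaplotypeAssignment:
    read_id: str
    haplotype: Optional[int]  # 0, 1 or None (unassigned)
    quality: float  # PHRED-scaled probability of mis-assignment
    n_sites: int
    mismatch_fraction: float


def assign_read(
    read_id: str,
    site_indices: Sequence[int],
    logp_ref: Sequence[float],
    logp_alt: Sequence[float],
    haplotypes: PhasedHaplotypes,
    config: Optional[HaplotagConfig] = None,
) -> HaplotypeAssignment:
    """Assign one read given its likelihoods over the phased het sites it covers.

    When the read spans several phase sets, only the phase set contributing
    the most sites is used.  The assignment quality is the PHRED scaling of
    the non-assigned haplotype's posterior.
    """
    config = config or HaplotagConfig()
    if len(site_indices) == 0:
        return HaplotypeAssignment(read_id, None, 0.0, 0, 0.0)
    idx = np.asarray(site_indices)
    lpr = np.asarray(logp_ref, dtype=float)
    lpa = np.asarray(logp_alt, dtype=float)

    ps = haplotypes.phase_set[idx]
    blocks, counts = np.unique(ps, return_counts=True)
    keep = ps == blocks[np.argmax(counts)]
    idx, lpr, lpa = idx[keep], lpr[keep], lpa[keep]

    b0 = haplotypes.b0[idx]  # 1 where hap0 carries ALT
    lik0 = np.where(b0 == 1, lpa, lpr).sum()
    lik1 = np.where(b0 == 1, lpr, lpa).sum()
    logpost = np.array(
        [lik0 + np.log(config.prior[0]), lik1 + np.log(config.prior[1])]
    )
    logpost -= np.logaddexp(logpost[0], logpost[1])
    hap = int(np.argmax(logpost))
    p_other = float(np.exp(logpost[1 - hap]))
    quality = -10.0 * np.log10(max(p_other, 1e-300))

    supported_alt = lpa > lpr  # allele each site's evidence favours
    hap_alt = (b0 == 1) if hap == 0 else (b0 == 0)
    mismatch = float(np.mean(supported_alt != hap_alt))

    assigned: Optional[int] = hap
    if quality < config.min_quality or mismatch > config.max_mismatch:
        assigned = None
    return HaplotypeAssignment(read_id, assigned, quality, int(idx.size), mismatch)


def tag_reads(
    bam: str | pysam.AlignmentFile,
    phased_vcf: str | PhasedHaplotypes,
    reference: str | pysam.FastaFile,
    region: Optional[Tuple[str, int, int]] = None,
    config: Optional[HaplotagConfig] = None,
    tagged_bam: Optional[str] = None,
) -> Dict[str, HaplotypeAssignment]:
    """Assign every QC-passing read in ``region`` to a haplotype.

    Assignments are produced in memory (keyed by read name); ``tagged_bam``
    optionally writes a BAM copy with HP (1/2) and PS tags for inspection.
    """
    config = config or HaplotagConfig()
    haps = (
        phased_vcf
        if isinstance(phased_vcf, PhasedHaplotypes)
        else PhasedHaplotypes.from_vcf(phased_vcf, region)
    )
    frags = extract_fragments(
        bam, list(haps.sites), reference, region=region,
        config=config.extract, hmm=config.hmm,
    )
    per_read: Dict[str, List[Tuple[int, float, float]]] = defaultdict(list)
    for site_idx, records in frags.items():
        for rec in records:
            per_read[rec.read_id].append((site_idx, rec.logp_ref, rec.logp_alt))
    assignments: Dict[str, HaplotypeAssignment] = {}
    for read_id, entries in per_read.items():
        entries.sort()
        idx = [e[0] for e in entries]
        assignments[read_id] = assign_read(
            read_id, idx, [e[1] for e in entries], [e[2] for e in entries], haps, config
        )
    if tagged_bam is not None:
        _write_tagged_bam(bam, tagged_bam, assignments, haps, region)
    return assignments


def _write_tagged_bam(bam, out_path, assignments, haps, region) -> None:
    own = isinstance(bam, str)
    bam_f = pysam.AlignmentFile(bam) if own else bam
    try:
        with pysam.AlignmentFile(out_path, "wb", template=bam_f) as out:
            it = bam_f.fetch(*region) if region else bam_f.fetch()
            for read in it:
                asg = assignments.get(read.query_name)
                if asg is not None and asg.haplotype is not None:
                    read.set_tag("HP", asg.haplotype + 1, "i")
                    read.set_tag("PS", int(haps.phase_set[0]), "i")
                out.write(read)
    finally:
        if own:
            bam_f.close()
    pysam.index(out_path)
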