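"""Genotyping of known population SNP sites under unbalanced copy number.

Tumour genomes violate the usual assumption that each parental haplotype is
sampled by half of the reads: copy-number imbalance, and loss of
heterozygosity in the extreme, can push the minor-haplotype read fraction far
below 1/2.  The heterozygous genotype likelihood therefore draws each read
from a mixture in which the higher-copy haplotype is sampled with probability
``f`` (default 0.25, i.e. the *minor* haplotype contributes 25% of reads in
one orientation), averaged over the two assignments of alleles to the
major/minor haplotypes.  The caller is deliberately conservative — false
negative het SNPs merely shrink the phasable genome, while false positives
corrupt read haplotagging — so only confident 0/1 calls are emitted.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pysam
from scipy.special import logsumexp
from scipy.stats import fisher_exact

from .realign import ExtractConfig, HmmParams, ReadAlleleLikelihoods, Site, extract_fragments

GENOTYPES = ("0/0", "0/1", "1/1")


@dataclasses.dataclass(frozen=True)
class GenotyperConfig:
    """``f`` is the probability a read derives from the higher-copy haplotype."""

    f: float = 0.25
    prior_variant: float = 1e-3
    prior_het_given_variant: float = 2.0 / 3.0
    strand_bias_p: float = 1e-4
    min_depth: int = 8  # minimum informative reads for any call
    extract: ExtractConfig = dataclasses.field(default_factory=ExtractConfig)
    hmm: HmmParams = dataclasses.field(default_factory=HmmParams)

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"f must be in (0, 1), got {self.f}")
        for name in ("prior_variant", "prior_het_given_variant"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @property
    def log_priors(self) -> np.ndarray:
        pv, ph = self.prior_variant, self.prior_het_given_variant
        return np.log(np.array([1.0 - pv, pv * ph, pv * (1.0 - ph)]))


@dataclasses.dataclass
class GenotypeCall:
    site: Site
    genotype: str  # one of GENOTYPES or './.' when uncalled
    posteriors: Optional[np.ndarray]  # (p00, p01, p11) or None when uncalled
    depth: int
    allele_depths: Tuple[int, int]  # reads favouring ref, alt
    strand_table: Optional[np.ndarray] = None  # 2x2 allele x strand
    uncalled_reason: Optional[str] = None


def _strand_table(reads: Sequence[ReadAlleleLikelihoods]) -> np.ndarray:
    table = np.zeros((2, 2), dtype=int)
    for rec in reads:
        allele = 1 if rec.logp_alt > rec.logp_ref else 0
        strand = 0 if rec.strand == "+" else 1
        table[allele, strand] += 1
    return table


def genotype_site(
    reads: Sequence[ReadAlleleLikelihoods],
    config: Optional[GenotyperConfig] = None,
) -> GenotypeCall:
    """Posterior genotype at one site from per-read allele likelihoods.

    Hom-ref/hom-alt likelihoods are plain products of the per-read allele
    likelihoods; the het likelihood averages the two copy-number orientations
    of the ``f`` / ``1-f`` read-draw mixture.  Strand-biased sites are left
    uncalled.
    """
    config = config or GenotyperConfig()
    if not reads:
        raise ValueError("genotype_site requires at least one read")
    lpr = np.array([r.logp_ref for r in reads])
    lpa = np.array([r.logp_alt for r in reads])
    table = _strand_table(reads)
    ad = (int(table[0].sum()), int(table[1].sum()))
    site_obj = None

    if len(reads) < config.min_depth:
        return GenotypeCall(
            site_obj, "./.", None, len(reads), ad, table, "insufficient depth"
        )

    f = config.f
    log_f, log_1mf = np.log(f), np.log(1.0 - f)
    orient_a = np.logaddexp(lpr + log_f, lpa + log_1mf).sum()
    orient_b = np.logaddexp(lpa + log_f, lpr + log_1mf).sum()
    log_het = np.log(0.5) + np.logaddexp(orient_a, orient_b)
    loglik = np.array([lpr.sum(), log_het, lpa.sum()])
    logpost = loglik + config.log_priors
    logpost -= logsumexp(logpost)
    post = np.exp(logpost)
    genotype = GENOTYPES[int(np.argmax(post))]

    if min(ad) > 0:
        p = fisher_exact(table)[1]
        if p < config.strand_bias_p:
            return GenotypeCall(
                site_obj, "./.", post, len(reads), ad, table, "strand bias"
            )
    return GenotypeCall(site_obj, genotype, post, len(reads), ad, table, None)


def read_sites_vcf(path: str, region: Optional[Tuple[str, int, int]] = None) -> List[Site]:
    """Biallelic SNV sites from a (bgzipped, indexed) VCF."""
    sites: List[Site] = []
    with pysam.VariantFile(path) as vcf:
        it = vcf.fetch(*region) if region else vcf.fetch()
        for rec in it:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            sites.append(Site(rec.chrom, rec.start, rec.ref.upper(), rec.alts[0].upper()))
    return sites


def genotype_sites(
    bam: str,
    sites_vcf: str,
    reference: str,
    output_vcf: str,
    region: Optional[Tuple[str, int, int]] = None,
    config: Optional[GenotyperConfig] = None,
) -> List[GenotypeCall]:
    """Genotype every site in ``sites_vcf`` and write confident 0/1 calls.

    Only heterozygous calls are written (false-negative hets are preferred
    over false positives, which would corrupt phasing).  The output VCF is
    unphased; phasing is delegated to an external tool.
    """
    config = config or GenotyperConfig()
    sites = read_sites_vcf(sites_vcf, region)
    calls: List[GenotypeCall] = []
    with pysam.FastaFile(reference) as ref_f, pysam.AlignmentFile(bam) as bam_f:
        vcf_chroms = {s.chrom for s in sites}
        for chrom in vcf_chroms:
            if chrom not in bam_f.references or chrom not in ref_f.references:
                raise ValueError(f"contig {chrom} missing from BAM or reference")
        frags = extract_fragments(
            bam_f, sites, ref_f, region=region, config=config.extract, hmm=config.hmm
        )
    for idx, site in enumerate(sites):
        reads = frags.get(idx, [])
        if not reads:
            continue
        call = genotype_site(reads, config)
        call.site = site
        calls.append(call)
    _write_het_vcf(output_vcf, calls, reference)
    return calls


def _write_het_vcf(path: str, calls: List[GenotypeCall], reference: str) -> None:
    header = pysam.VariantHeader()
    with pysam.FastaFile(reference) as ref_f:
        for name, length in zip(ref_f.references, ref_f.lengths):
            header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Informative read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Reads favouring each allele">')
    header.add_sample("sample")
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in calls:
            if call.genotype != "0/1":
                continue
            rec = out.new_record(
                contig=call.site.chrom,
                start=call.site.pos,
                stop=call.site.pos + 1,
                alleles=(call.site.ref, call.site.alt),
            )
            rec.samples["sample"]["GT"] = (0, 1)
            rec.samples["sample"].phased = False
            rec.samples["sample"]["DP"] = call.depth
            rec.samples["sample"]["AD"] = list(call.allele_depths)
            out.write(rec)
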