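"""Synthetic, truth-annotated pipeline inputs for the somatic caller.

Generates a random diploid region with heterozygous SNPs, somatic mutations
on a single haplotype with clonal/subclonal cancer-cell fractions, and
pre-aligned long reads sampled from a tumour/normal mixture, written as
FASTA + sorted/indexed BAM + truth VCFs.  Reads are emitted with perfect
coordinates (full-match CIGAR), sidestepping an aligner dependency; an
optional FASTQ export supports full-stack runs through a real aligner.

Everything is driven by one seed: the same :class:`FixtureSpec` reproduces
byte-identical truth files.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic tumour-only sequencing experiment.

    ``depth`` is the merged (tumour + normal) mean coverage; a fraction
    ``alpha`` of reads derive from tumour cells.  ``n_somatic`` places an
    exact number of somatic SNVs instead of the per-base rate ``mu``.
    Base qualities are constant at the PHRED equivalent of ``epsilon``
    (capped at 40) so emission probabilities agree with the error process.
    """

    region_length: int = 1_000_000
    chrom: str = "synth1"
    pi: float = 1e-3
    mu: float = 5e-5
    n_somatic: Optional[int] = None
    rho: float = 0.95
    ccf_a: float = 2.0
    ccf_b: float = 2.0
    alpha: float = 0.5
    depth: float = 80.0
    read_length: int = 20_000
    epsilon: float = 0.005
    decoy_rate: float = 1e-3
    #: probability a read derives from haplotype 0; values away from 0.5
    #: emulate copy-number imbalance / loss of heterozygosity
    hap0_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi", "mu", "rho", "alpha", "epsilon", "decoy_rate", "hap0_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_length < 100:
            raise ValueError("read_length must be >= 100")
        if self.read_length > self.region_length:
            raise ValueError("read_length exceeds region_length")
        if self.ccf_a <= 0 or self.ccf_b <= 0:
            raise ValueError("Beta shape parameters must be > 0")

    @property
    def base_quality(self) -> int:
        if self.epsilon <= 0:
            return 40
        return min(40, int(round(-10 * np.log10(self.epsilon))))


@dataclasses.dataclass
class GermlineTruth:
    positions: np.ndarray  # 0-based
    alt_codes: np.ndarray  # base code of the alternate allele
    alt_hap: np.ndarray  # haplotype (0/1) carrying the alternate


@dataclasses.dataclass
class SomaticTruth:
    positions: np.ndarray
    alt_codes: np.ndarray
    hap: np.ndarray  # haplotype of origin
    ccf: np.ndarray  # cancer cell fraction, 1.0 for clonal


@dataclasses.dataclass
class Fixture:
    """Paths of a generated fixture plus in-memory truth."""

    reference_fasta: str
    bam: str
    germline_vcf: str  # phased, bgzipped + tabix indexed
    somatic_vcf: str
    sites_vcf: str  # population-SNP style site list (het truth + hom-ref decoys)
    read_table: str  # TSV: read id, germline haplotype, tumour origin
    chrom: str
    region_length: int
    germline: GermlineTruth
    somatic: SomaticTruth


def _draw_truth(spec: FixtureSpec, rng: np.random.Generator):
    L = spec.region_length
    ref = rng.integers(0, 4, size=L, dtype=np.uint8)

    het_mask = rng.random(L) < spec.pi
    het_pos = np.flatnonzero(het_mask)
    het_alt = (ref[het_pos] + rng.integers(1, 4, size=het_pos.size)) % 4
    het_hap = rng.integers(0, 2, size=het_pos.size)

    if spec.n_somatic is not None:
        free = np.setdiff1d(np.arange(L), het_pos, assume_unique=True)
        som_pos = np.sort(rng.choice(free, size=spec.n_somatic, replace=False))
    else:
        som_mask = rng.random(L) < spec.mu
        som_mask[het_pos] = False  # somatic and germline SNVs kept disjoint
        som_pos = np.flatnonzero(som_mask)
    som_alt = (ref[som_pos] + rng.integers(1, 4, size=som_pos.size)) % 4
    som_hap = rng.integers(0, 2, size=som_pos.size)
    clonal = rng.random(som_pos.size) < spec.rho
    ccf = np.where(
        clonal, 1.0, rng.beta(spec.ccf_a, spec.ccf_b, size=som_pos.size)
    )

    decoy_mask = rng.random(L) < spec.decoy_rate
    decoy_mask[het_pos] = False
    decoy_mask[som_pos] = False
    decoy_pos = np.flatnonzero(decoy_mask)
    decoy_alt = (ref[decoy_pos] + rng.integers(1, 4, size=decoy_pos.size)) % 4

    germline = GermlineTruth(het_pos, het_alt.astype(np.uint8), het_hap)
    somatic = SomaticTruth(som_pos, som_alt.astype(np.uint8), som_hap, ccf)
    return ref, germline, somatic, (decoy_pos, decoy_alt.astype(np.uint8))


def _haplotype_sequences(ref, germline) -> Tuple[np.ndarray, np.ndarray]:
    h0 = ref.copy()
    h1 = ref.copy()
    on0 = germline.alt_hap == 0
    h0[germline.positions[on0]] = germline.alt_codes[on0]
    h1[germline.positions[~on0]] = germline.alt_codes[~on0]
    return h0, h1


def _simulate_reads(
    spec: FixtureSpec,
    ref: np.ndarray,
    germline: GermlineTruth,
    somatic: SomaticTruth,
    alpha: float,
    depth: float,
    rng: np.random.Generator,
):
    """Yield (name, start, hap, is_tumour, reverse, seq_codes) per read."""
    L = spec.region_length
    rl = spec.read_length
    n_reads = int(round(depth * L / rl))
    haps = _haplotype_sequences(ref, germline)
    som_by_hap = {
        j: (somatic.positions[somatic.hap == j], somatic.alt_codes[somatic.hap == j],
            somatic.ccf[somatic.hap == j])
        for j in (0, 1)
    }
    starts = rng.integers(0, L - rl + 1, size=n_reads)
    hap_of = (rng.random(n_reads) >= spec.hap0_fraction).astype(int)
    tumour = rng.random(n_reads) < alpha
    reverse = rng.random(n_reads) < 0.5
    order = np.argsort(starts, kind="stable")
    for rank, idx in enumerate(order):
        start = int(starts[idx])
        j = int(hap_of[idx])
        seq = haps[j][start : start + rl].copy()
        if tumour[idx]:
            pos, alt, ccf = som_by_hap[j]
            lo, hi = np.searchsorted(pos, (start, start + rl))
            if hi > lo:
                carried = rng.random(hi - lo) < ccf[lo:hi]
                seq[pos[lo:hi][carried] - start] = alt[lo:hi][carried]
        err = np.flatnonzero(rng.random(rl) < spec.epsilon)
        if err.size:
            seq[err] = (seq[err] + rng.integers(1, 4, size=err.size)) % 4
        yield (
            f"read{rank:06d}",
            start,
            j,
            bool(tumour[idx]),
            bool(reverse[idx]),
            seq,
        )


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def _write_fasta(path: str, chrom: str, ref: np.ndarray) -> None:
    seq = _codes_to_str(ref)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(path)


def _vcf_header(chrom: str, length: int, with_sample: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={length}>")
    if with_sample:
        header.add_line(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
        )
        header.add_line(
            '##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">'
        )
        header.add_sample("sample")
    return header


def _index_vcf(path: str) -> str:
    gz = path + ".gz"
    pysam.tabix_compress(path, gz, force=True)
    pysam.tabix_index(gz, preset="vcf", force=True)
    os.unlink(path)
    return gz


def _write_phased_germline_vcf(path, chrom, length, ref, germline) -> str:
    header = _vcf_header(chrom, length, with_sample=True)
    header.add_line(
        '##INFO=<ID=HAP,Number=1,Type=Integer,Description="Haplotype carrying ALT">'
    )
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for pos, alt, hap in zip(
            germline.positions, germline.alt_codes, germline.alt_hap
        ):
            rec = vcf.new_record(
                contig=chrom,
                start=int(pos),
                stop=int(pos) + 1,
                alleles=(_codes_to_str(ref[pos : pos + 1]), _BASES[alt : alt + 1].tobytes().decode()),
            )
            rec.info["HAP"] = int(hap)
            rec.samples["sample"]["GT"] = (1, 0) if hap == 0 else (0, 1)
            rec.samples["sample"].phased = True
            rec.samples["sample"]["PS"] = 1
            vcf.write(rec)
    return _index_vcf(path)


def _write_somatic_vcf(path, chrom, length, ref, somatic) -> str:
    header = _vcf_header(chrom, length, with_sample=False)
    header.add_line(
        '##INFO=<ID=HAP,Number=1,Type=Integer,Description="Haplotype of origin">'
    )
    header.add_line(
        '##INFO=<ID=CCF,Number=1,Type=Float,Description="Cancer cell fraction">'
    )
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for pos, alt, hap, ccf in zip(
            somatic.positions, somatic.alt_codes, somatic.hap, somatic.ccf
        ):
            rec = vcf.new_record(
                contig=chrom,
                start=int(pos),
                stop=int(pos) + 1,
                alleles=(
                    _codes_to_str(ref[pos : pos + 1]),
                    _BASES[alt : alt + 1].tobytes().decode(),
                ),
            )
            rec.info["HAP"] = int(hap)
            rec.info["CCF"] = float(ccf)
            vcf.write(rec)
    return _index_vcf(path)


def _write_sites_vcf(path, chrom, length, ref, germline, decoys) -> str:
    """Population-SNP style site list: the true het SNPs plus hom-ref decoys."""
    header = _vcf_header(chrom, length, with_sample=False)
    pos = np.concatenate([germline.positions, decoys[0]])
    alt = np.concatenate([germline.alt_codes, decoys[1]])
    order = np.argsort(pos)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for p, a in zip(pos[order], alt[order]):
            rec = vcf.new_record(
                contig=chrom,
                start=int(p),
                stop=int(p) + 1,
                alleles=(
                    _codes_to_str(ref[p : p + 1]),
                    _BASES[a : a + 1].tobytes().decode(),
                ),
            )
            vcf.write(rec)
    return _index_vcf(path)


def make_fixture(
    spec: FixtureSpec, outdir: str, fastq: bool = False, read_seed: Optional[int] = None
) -> Fixture:
    """Generate the full synthetic input set under ``outdir``.

    ``read_seed`` (default derived from ``spec.seed``) controls only the read
    mixture; the truth variants depend solely on ``spec.seed``, so fixtures
    sharing a spec seed share their variant positions.
    """
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    ref, germline, somatic, decoys = _draw_truth(spec, rng)
    chrom, L = spec.chrom, spec.region_length

    fasta = os.path.join(outdir, "reference.fa")
    _write_fasta(fasta, chrom, ref)

    bam_path = os.path.join(outdir, "reads.bam")
    read_table = os.path.join(outdir, "reads_truth.tsv")
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": L}],
    }
    qual = spec.base_quality
    fastq_path = os.path.join(outdir, "reads.fastq") if fastq else None
    fq = open(fastq_path, "w") if fastq else None
    read_rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 1 if read_seed is None else read_seed])
    )
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam, open(
        read_table, "w"
    ) as table:
        table.write("read_id\thaplotype\tis_tumour\tstrand\n")
        for name, start, hap, is_tumour, reverse, seq in _simulate_reads(
            spec, ref, germline, somatic, spec.alpha, spec.depth, read_rng
        ):
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = _codes_to_str(seq)
            a.flag = 16 if reverse else 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [(0, len(seq))]
            a.query_qualities = pysam.qualitystring_to_array(chr(qual + 33) * len(seq))
            bam.write(a)
            table.write(
                f"{name}\t{hap}\t{int(is_tumour)}\t{'-' if reverse else '+'}\n"
            )
            if fq is not None:
                fq.write(f"@{name}\n{a.query_sequence}\n+\n{chr(qual + 33) * len(seq)}\n")
    if fq is not None:
        fq.close()
    pysam.index(bam_path)

    germline_vcf = _write_phased_germline_vcf(
        os.path.join(outdir, "germline.vcf"), chrom, L, ref, germline
    )
    somatic_vcf = _write_somatic_vcf(
        os.path.join(outdir, "somatic_truth.vcf"), chrom, L, ref, somatic
    )
    sites_vcf = _write_sites_vcf(
        os.path.join(outdir, "sites.vcf"), chrom, L, ref, germline, decoys
    )
    return Fixture(
        reference_fasta=fasta,
        bam=bam_path,
        germline_vcf=germline_vcf,
        somatic_vcf=somatic_vcf,
        sites_vcf=sites_vcf,
        read_table=read_table,
        chrom=chrom,
        region_length=L,
        germline=germline,
        somatic=somatic,
    )


def make_mixture_series(
    spec: FixtureSpec,
    purities: Sequence[float],
    depths: Sequence[float],
    outdir: str,
) -> Dict[Tuple[float, float], Fixture]:
    """One fixture per (purity, depth) cell sharing the same truth variants.

    The truth (reference, germline, somatic) is drawn once from ``spec.seed``;
    only the read mixture differs between cells.
    """
    if not purities or not depths:
        raise ValueError("purity and depth grids must be non-empty")
    out: Dict[Tuple[float, float], Fixture] = {}
    for i, purity in enumerate(purities):
        for k, depth in enumerate(depths):
            cell_spec = dataclasses.replace(spec, alpha=purity, depth=depth)
            cell_dir = os.path.join(outdir, f"purity{purity:g}_depth{depth:g}")
            # same truth: same spec.seed; different reads: per-cell read seed
            fx = make_fixture(
                cell_spec, cell_dir, read_seed=1000 + i * len(depths) + k
            )
            out[(purity, depth)] = fx
    return out


# ---------------------------------------------------------------------------
# mutation-spectrum sampling helper
# ---------------------------------------------------------------------------


def sample_spectrum_calls(
    reference: str,
    probabilities: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> List[Tuple[int, str, str]]:
    """Draw ``n`` SNVs from a 96-context mutation spectrum on ``reference``.

    Contexts are pyrimidine-centred; each draw picks a context according to
    ``probabilities`` (COSMIC-style order, see :mod:`hapsomatic.burden`) and a
    genome position with a matching trinucleotide (on either strand).
    Returns 0-based ``(position, ref_base, alt_base)`` tuples.
    """
    from . import burden

    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.shape != (96,):
        raise ValueError("spectrum must have 96 entries")
    probabilities = probabilities / probabilities.sum()

    # index interior positions by their pyrimidine-centred trinucleotide
    by_context: Dict[str, List[Tuple[int, bool]]] = {}
    comp = str.maketrans("ACGT", "TGCA")
    for i in range(1, len(reference) - 1):
        tri = reference[i - 1 : i + 2].upper()
        if any(b not in "ACGT" for b in tri):
            continue
        if tri[1] in "CT":
            by_context.setdefault(tri, []).append((i, False))
        else:
            rc = tri.translate(comp)[::-1]
            by_context.setdefault(rc, []).append((i, True))

    calls: List[Tuple[int, str, str]] = []
    ctx_idx = rng.choice(96, size=n, p=probabilities)
    for idx in ctx_idx:
        label = burden.CONTEXT_LABELS[idx]  # e.g. "A[C>T]G"
        five, central, alt, three = label[0], label[2], label[4], label[6]
        tri = five + central + three
        pool = by_context.get(tri)
        if not pool:
            continue
        pos, flipped = pool[rng.integers(len(pool))]
        if flipped:
            ref_base = tri[1].translate(comp)
            alt_base = alt.translate(comp)
        else:
            ref_base, alt_base = tri[1], alt
        calls.append((pos, ref_base, alt_base))
    return calls
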