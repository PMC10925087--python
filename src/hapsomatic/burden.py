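"""Tumour mutation burden and the 96-context mutation spectrum.

TMB (mutations per megabase) is an immunotherapy-response biomarker; the
96-context spectrum (six pyrimidine-centred substitution types times the 16
flanking-base combinations) is the standard input representation for
mutational-signature analysis.  Both are genome-wide quantities, so they can
be estimated from the subset of the genome that was phased and called —
here, the callable BED emitted alongside the calls.
"""

from __future__ import annotations

import dataclasses
from typing import List, Sequence, Tuple

import numpy as np
import pysam

SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: COSMIC-style ordering: substitution-type blocks, then 5' base, then 3' base
CONTEXT_LABELS: Tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in "ACGT"
    for three in "ACGT"
)
_CONTEXT_INDEX = {label: i for i, label in enumerate(CONTEXT_LABELS)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class UndefinedTMBError(ValueError):
    """TMB is undefined over an empty callable footprint."""


@dataclasses.dataclass
class SpectrumVector:
    """Counts over the 96 pyrimidine-centred trinucleotide contexts."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 entries")
        if np.any(self.counts < 0):
            raise ValueError("spectrum counts must be non-negative")

    @property
    def labels(self) -> Tuple[str, ...]:
        return CONTEXT_LABELS

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.copy()

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("context\tcount\tfrequency\n")
            freqs = self.frequencies
            for label, c, f in zip(CONTEXT_LABELS, self.counts, freqs):
                fh.write(f"{label}\t{c:g}\t{f:.6g}\n")


def context_label(five: str, ref: str, alt: str, three: str) -> str:
    """Canonical pyrimidine-centred context of one SNV.

    Purine-reference substitutions are reverse-complemented (an involution:
    applying it twice returns the original strand's representation).
    """
    five, ref, alt, three = (b.upper() for b in (five, ref, alt, three))
    if ref in "AG":
        five, three = three.translate(_COMPLEMENT), five.translate(_COMPLEMENT)
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return f"{five}[{ref}>{alt}]{three}"


def _iter_called_snvs(calls_vcf: str, qual_threshold: float):
    with pysam.VariantFile(calls_vcf) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            if rec.qual is None or rec.qual < qual_threshold:
                continue
            if set(rec.filter.keys()) - {"PASS"}:
                continue
            yield rec.chrom, rec.start, rec.ref.upper(), rec.alts[0].upper()


def read_bed(path: str) -> List[Tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e = line.split()[:3]
            out.append((chrom, int(s), int(e)))
    return out


def estimate_tmb(
    calls_vcf: str, callable_bed: str, qual_threshold: float = 20.0
) -> float:
    """Mutations per megabase: QC-PASS calls with QUAL >= threshold over the
    callable footprint."""
    intervals = read_bed(callable_bed)
    footprint = sum(e - s for _, s, e in intervals)
    if footprint == 0:
        raise UndefinedTMBError("callable BED is empty")
    n = sum(1 for _ in _iter_called_snvs(calls_vcf, qual_threshold))
    return n / (footprint / 1e6)


def mutation_spectrum(
    calls_vcf: str | Sequence[Tuple[str, int, str, str]],
    reference: str | pysam.FastaFile,
    qual_threshold: float = 20.0,
) -> SpectrumVector:
    """96-context spectrum of the called SNVs (same call set as TMB).

    ``calls_vcf`` may also be an iterable of ``(chrom, pos0, ref, alt)``
    tuples.  Mutations whose flanking bases fall outside the contig or are
    ambiguous are skipped.
    """
    own_ref = isinstance(reference, str)
    ref_f = pysam.FastaFile(reference) if own_ref else reference
    counts = np.zeros(96)
    try:
        if isinstance(calls_vcf, str):
            snvs = _iter_called_snvs(calls_vcf, qual_threshold)
        else:
            snvs = iter(calls_vcf)
        for chrom, pos, ref, alt in snvs:
            if pos < 1 or pos + 2 > ref_f.get_reference_length(chrom):
                continue
            tri = ref_f.fetch(chrom, pos - 1, pos + 2).upper()
            if any(b not in "ACGT" for b in tri) or tri[1] != ref:
                continue
            label = context_label(tri[0], ref, alt, tri[2])
            counts[_CONTEXT_INDEX[label]] += 1
    finally:
        if own_ref:
            ref_f.close()
    return SpectrumVector(counts)


def cosine_similarity(u, v) -> float:
    """Cosine of two 96-context spectra (or any equal-length count vectors)."""
    u = u.counts if isinstance(u, SpectrumVector) else np.asarray(u, dtype=float)
    v = v.counts if isinstance(v, SpectrumVector) else np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))
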