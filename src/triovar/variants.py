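"""Variants, genotypes, and VCF input/output.

Coordinates are 1-based and inclusive throughout, following the VCF
convention. A :class:`Variant` is the usual anchored VCF representation
(``pos``, ``ref``, ``alt``); indel spellings inside repeat runs are made
unique by :func:`normalize_variant`, which by default right-aligns
(3'-shifts) indels so that an insertion in a homopolymer is anchored at the
run's last base — the convention used when an insertion is reported "after"
a mononucleotide repeat (e.g. a cytosine inserted into a C7 run named after
its 3'-most cytosine). Left alignment (the VCF norm) is available via
``align="left"``.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .errors import (
    ConsistencyError,
    IntervalError,
    PloidyError,
    ReferenceMismatchError,
    VcfFormatError,
)

_DNA = frozenset("ACGT")

#: Dosage code for a missing genotype call.
MISSING = -1


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise IntervalError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise IntervalError(
                f"end ({self.end}) < start ({self.start}) on {self.contig}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def interval_length(iv: GenomicInterval) -> int:
    """Length of a 1-based inclusive interval: ``end - start + 1``.

    The seven-cytosine run at Chr6:55,146,550-55,146,556 has length 7 under
    this convention.
    """
    return len(iv)


@dataclass(frozen=True, order=True)
class Variant:
    """An anchored genomic change (SNV or indel) in VCF representation."""

    contig: str
    pos: int
    ref: str
    alt: str
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if set(self.ref) - _DNA or set(self.alt) - _DNA:
            raise ValueError(f"alleles must be A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def vclass(self) -> str:
        return "SNV" if len(self.ref) == len(self.alt) else "INDEL"

    def __str__(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class GenotypeCall:
    """A diploid genotype for one sample, as an alt-allele dosage.

    ``dosage`` is 0, 1 or 2 alt alleles, or :data:`MISSING` (-1) when any
    allele is uncalled — a call with one missing allele is treated as wholly
    missing (conservative for segregation filtering).
    """

    sample: str
    dosage: int

    def __post_init__(self) -> None:
        if self.dosage not in (MISSING, 0, 1, 2):
            raise ValueError(f"dosage must be -1/0/1/2, got {self.dosage}")

    @property
    def is_missing(self) -> bool:
        return self.dosage == MISSING

    @property
    def is_hom_alt(self) -> bool:
        return self.dosage == 2

    @property
    def is_het(self) -> bool:
        return self.dosage == 1

    @property
    def is_hom_ref(self) -> bool:
        return self.dosage == 0


class GenotypeMatrix:
    """Rectangular diploid genotype calls over variants x samples.

    ``calls[i, j]`` holds the alt-allele dosage of sample ``j`` at variant
    ``i`` (0/1/2, or -1 for missing). ``info[i]`` carries per-variant
    annotations (e.g. ``gene``, ``exonic``, ``nonsynonymous``) and
    ``formats[i]`` optional per-sample FORMAT extras preserved from VCF.
    """

    def __init__(
        self,
        variants: Sequence[Variant],
        samples: Sequence[str],
        calls: np.ndarray,
        info: Sequence[dict] | None = None,
        formats: Sequence[dict] | None = None,
        format_decls: dict[str, tuple] | None = None,
    ) -> None:
        self.variants = list(variants)
        self.samples = list(samples)
        self.calls = np.asarray(calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.samples)):
            raise ConsistencyError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        self.info = list(info) if info is not None else [{} for _ in self.variants]
        self.formats = (
            list(formats) if formats is not None else [{} for _ in self.variants]
        )
        if len(self.info) != len(self.variants) or len(self.formats) != len(
            self.variants
        ):
            raise ConsistencyError("info/formats length != number of variants")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ConsistencyError("duplicate (contig, pos, ref, alt) in matrix")
        self._sample_index = {s: j for j, s in enumerate(self.samples)}
        self._variant_index = {k: i for i, k in enumerate(keys)}

    # -- accessors ---------------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def index_of(self, variant: Variant) -> int | None:
        return self._variant_index.get(variant.key)

    def call(self, i: int, sample: str) -> GenotypeCall:
        return GenotypeCall(sample, int(self.calls[i, self.sample_index(sample)]))

    def subset(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            [self.variants[i] for i in idx],
            self.samples,
            self.calls[idx, :] if idx else np.zeros((0, self.n_samples), np.int8),
            [self.info[i] for i in idx],
            [self.formats[i] for i in idx],
        )

    def sorted(self) -> "GenotypeMatrix":
        order = sorted(range(self.n_variants), key=lambda i: self.variants[i].key)
        return self.subset(order)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.samples == other.samples
            and np.array_equal(self.calls, other.calls)
            and self.info == other.info
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_variants} variants x {self.n_samples} samples)"


# -- FASTA ----------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into ``{contig: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# -- VCF parsing ----------------------------------------------------------

_INFO_BOOL = {"EXONIC": "exonic", "NONSYN": "nonsynonymous"}
_INFO_STR = {"GENE": "gene"}


def _dosage(gt: tuple, alt_index: int) -> int:
    """Recode a pysam GT tuple against one alt allele of a (possibly
    multiallelic) record. Any missing allele makes the call missing; alleles
    for a *different* alt are recoded as ref for this row."""
    if gt is None or len(gt) == 0 or all(a is None for a in gt):
        return MISSING
    if any(a is None for a in gt):
        return MISSING
    if len(gt) != 2:
        raise PloidyError(f"expected diploid GT, got ploidy {len(gt)}")
    return sum(1 for a in gt if a == alt_index)


def parse_vcf(source) -> GenotypeMatrix:
    """Parse a multi-sample VCF into a :class:`GenotypeMatrix`.

    ``source`` may be a path or an open text stream. Multiallelic records
    are split into one biallelic row per alt allele, with genotypes recoded
    against that alt (other-alt alleles count as ref). Phased and unphased
    separators are treated identically. Records must carry a GT field.
    """
    tmp_path = None
    if hasattr(source, "read"):
        fd, tmp_path = tempfile.mkstemp(suffix=".vcf")
        with os.fdopen(fd, "w") as fh:
            fh.write(source.read())
        path = tmp_path
    else:
        path = str(source)
    try:
        return _parse_vcf_path(path)
    finally:
        if tmp_path is not None:
            os.unlink(tmp_path)


def _format_decls(header: pysam.VariantHeader) -> dict[str, tuple]:
    decls = {}
    for name, rec in header.formats.items():
        decls[name] = (rec.number, rec.type, rec.description or name)
    return decls


def _parse_vcf_path(path: str) -> GenotypeMatrix:
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vf:
        samples = list(vf.header.samples)
        decls = _format_decls(vf.header)
        declared_flags = {k for k in _INFO_BOOL if k in vf.header.info}
        variants: list[Variant] = []
        calls: list[list[int]] = []
        infos: list[dict] = []
        formats: list[dict] = []
        for rec in vf:
            if "GT" not in rec.format:
                raise VcfFormatError(
                    f"record {rec.contig}:{rec.pos} has no GT FORMAT field"
                )
            alts = rec.alts or ()
            info: dict = {}
            for key, name in _INFO_BOOL.items():
                if key in rec.info:
                    info[name] = bool(rec.info[key])
                elif key in declared_flags:
                    info[name] = False  # declared flag absent on the record
            for key, name in _INFO_STR.items():
                if key in rec.info:
                    info[name] = str(rec.info[key])
            multi = len(alts) > 1
            for ai, alt in enumerate(alts, start=1):
                if alt is None or set(alt) - _DNA:
                    continue  # symbolic / spanning-deletion alts unsupported
                row = []
                fmt: dict = {}
                for s in samples:
                    sd = rec.samples[s]
                    row.append(_dosage(sd.get("GT"), ai))
                    if not multi:
                        extras = {
                            k: sd[k]
                            for k in rec.format.keys()
                            if k != "GT" and sd.get(k) is not None
                        }
                        if extras:
                            fmt[s] = extras
                variants.append(
                    Variant(rec.contig, rec.pos, rec.ref.upper(), alt.upper(), rec.id)
                )
                calls.append(row)
                infos.append(dict(info))
                formats.append(fmt)
    arr = (
        np.array(calls, dtype=np.int8)
        if calls
        else np.zeros((0, len(samples)), np.int8)
    )
    return GenotypeMatrix(variants, samples, arr, infos, formats, decls)


def write_vcf(
    gm: GenotypeMatrix,
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a :class:`GenotypeMatrix` as VCF v4.2 (GT plus any preserved
    FORMAT extras; annotations re-emitted as INFO flags)."""
    header = pysam.VariantHeader()
    lengths: dict[str, int] = dict(contig_lengths or {})
    for v in gm.variants:
        need = v.pos + len(v.ref) + 1000
        lengths[v.contig] = max(lengths.get(v.contig, 0), need)
    for contig, length in lengths.items():
        header.contigs.add(contig, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    extra_fmts = sorted(
        {k for fmt in gm.formats for extras in fmt.values() for k in extras}
    )
    for name in extra_fmts:
        header.formats.add(name, ".", "String", name)
    used = {k for info in gm.info for k in info}
    if "gene" in used:
        header.info.add("GENE", 1, "String", "Gene symbol")
    if "exonic" in used:
        header.info.add("EXONIC", 0, "Flag", "Variant overlaps an exon")
    if "nonsynonymous" in used:
        header.info.add("NONSYN", 0, "Flag", "Nonsynonymous coding change")
    for s in gm.samples:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    with out:
        for i, v in enumerate(gm.variants):
            rec = out.new_record(
                contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt), id=v.id
            )
            info = gm.info[i]
            if info.get("gene"):
                rec.info["GENE"] = info["gene"]
            if info.get("exonic"):
                rec.info["EXONIC"] = True
            if info.get("nonsynonymous"):
                rec.info["NONSYN"] = True
            for j, s in enumerate(gm.samples):
                d = int(gm.calls[i, j])
                rec.samples[s]["GT"] = {
                    0: (0, 0),
                    1: (0, 1),
                    2: (1, 1),
                    MISSING: (None, None),
                }[d]
                for k, val in gm.formats[i].get(s, {}).items():
                    if isinstance(val, tuple):
                        val = ",".join(str(x) for x in val)
                    rec.samples[s][k] = str(val)
            out.write(rec)


# -- indel normalization --------------------------------------------------


def _check_ref(v: Variant, seq: str) -> None:
    observed = seq[v.pos - 1 : v.pos - 1 + len(v.ref)]
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"{v}: reference sequence has {observed!r} at {v.pos}, variant claims "
            f"{v.ref!r}"
        )


def minimal_edit(ref: str, alt: str, pos: int) -> tuple[int, str, str]:
    """Reduce an anchored (ref, alt) pair at 1-based ``pos`` to its minimal
    unanchored edit ``(start, deleted_seq, inserted_seq)``: the bases
    ``start .. start+len(deleted)-1`` are replaced by ``inserted``; for a
    pure insertion (empty ``deleted``) the sequence goes in *before*
    ``start``."""
    i = 0
    while i < len(ref) and i < len(alt) and ref[i] == alt[i]:
        i += 1
    j = 0
    while (
        j < len(ref) - i and j < len(alt) - i and ref[len(ref) - 1 - j] == alt[len(alt) - 1 - j]
    ):
        j += 1
    return pos + i, ref[i : len(ref) - j], alt[i : len(alt) - j]


def _anchored_insertion(contig, k, s, ref_seq, vid) -> Variant:
    """Insertion of ``s`` before 0-based index ``k``, re-anchored VCF-style."""
    if k >= 1:
        anchor = ref_seq[k - 1]
        return Variant(contig, k, anchor, anchor + s, vid)
    anchor = ref_seq[0]  # contig start: anchor on the following base
    return Variant(contig, 1, anchor, s + anchor, vid)


def normalize_variant(v: Variant, ref_seq: str, align: str = "right") -> Variant:
    """Canonicalize a variant against its contig sequence.

    SNVs and length-preserving substitutions are returned in minimal form
    (after a reference check). Pure insertions and deletions are trimmed to
    their minimal anchored form and shifted through repeat runs:
    ``align="right"`` (default) 3'-shifts to the most downstream equivalent
    spelling, the dialect in which an insertion into a homopolymer is
    anchored at the run's last base; ``align="left"`` gives the VCF
    left-aligned spelling. Idempotent; every equivalent spelling of an
    indel inside a repeat maps to the same canonical variant.
    """
    if align not in ("right", "left"):
        raise ValueError("align must be 'right' or 'left'")
    _check_ref(v, ref_seq)
    start, dseq, iseq = minimal_edit(v.ref, v.alt, v.pos)
    if dseq and iseq:
        # substitution (SNV/MNV) or complex indel: minimal form, no shifting
        return Variant(v.contig, start, dseq, iseq, v.id)
    if iseq:  # pure insertion of iseq before 1-based `start`
        s, k = iseq, start - 1  # k: 0-based index of the base after the gap
        if align == "right":
            while k < len(ref_seq) and ref_seq[k] == s[0]:
                s = s[1:] + s[0]
                k += 1
        else:
            while k >= 1 and ref_seq[k - 1] == s[-1]:
                s = s[-1] + s[:-1]
                k -= 1
        return _anchored_insertion(v.contig, k, s, ref_seq, v.id)
    # pure deletion of d bases starting at 0-based index `start - 1`
    d = len(dseq)
    j = start - 1
    if align == "right":
        while j + d < len(ref_seq) and ref_seq[j] == ref_seq[j + d]:
            j += 1
    else:
        while j >= 1 and ref_seq[j - 1] == ref_seq[j + d - 1]:
            j -= 1
    if j >= 1:
        anchor = ref_seq[j - 1]
        return Variant(v.contig, j, anchor + ref_seq[j : j + d], anchor, v.id)
    anchor = ref_seq[d]  # deletion at contig start: anchor on following base
    return Variant(v.contig, 1, ref_seq[: d + 1], anchor, v.id)
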