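"""Transcript models and protein-level consequence prediction.

A :class:`TranscriptModel` maps genomic positions to coding (CDS)
positions; :func:`project_to_cds` turns a genomic :class:`~triovar.variants.Variant`
into a :class:`CodingVariant` with an HGVS-style ``c.`` name, and
:func:`call_consequence` applies the edit to the CDS, translates both
alleles with the standard nuclear genetic code, and classifies the effect.

Protein names for frameshifts are emitted, by default, in the
absolute-stop dialect ``p.<WT><pos><MUT>fs*<stop codon index>`` — i.e. the
number after ``*`` is the codon index of the new termination codon in the
mutant protein counted from the initiator methionine (so a frameshift at
residue 1393 terminating at codon 1395 is ``p.F1393Lfs*1395``). Standard
HGVS instead counts the stop from the first changed residue
(``p.F1393Lfs*3``); pass ``dialect="hgvs"`` for that form. Stop codons are
never counted in protein lengths.
"""

from __future__ import annotations

import csv
import os
import warnings
from dataclasses import dataclass, field
from typing import Mapping

from Bio.Seq import Seq

from .errors import TranscriptModelError
from .variants import GenomicInterval, Variant, minimal_edit

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``cds_start`` and ``cds_end`` are the genomic positions of the first
    and last base of the coding sequence *in transcript orientation*: on
    the minus strand ``cds_start > cds_end`` numerically. The CDS includes
    the stop codon.
    """

    gene: str
    transcript_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise TranscriptModelError(f"strand must be '+' or '-', got {self.strand}")
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise TranscriptModelError(
                    f"{self.transcript_id}: overlapping exons {a} / {b}"
                )
        object.__setattr__(self, "exons", tuple(exons))

    # -- coordinate arithmetic --------------------------------------------

    @property
    def cds_segments(self) -> tuple[GenomicInterval, ...]:
        """CDS-overlapping exon pieces, in *transcript* order."""
        lo, hi = sorted((self.cds_start, self.cds_end))
        segs = [
            GenomicInterval(self.contig, max(e.start, lo), min(e.end, hi))
            for e in self.exons
            if e.end >= lo and e.start <= hi
        ]
        return tuple(segs if self.strand == "+" else segs[::-1])

    @property
    def cds_length(self) -> int:
        return sum(len(s) for s in self.cds_segments)

    def genomic_to_cds(self, pos: int) -> int | None:
        """1-based CDS coordinate of a genomic position, or None if the
        position is intronic, UTR, or outside the transcript."""
        offset = 0
        for seg in self.cds_segments:
            if seg.contains(pos):
                if self.strand == "+":
                    return offset + (pos - seg.start) + 1
                return offset + (seg.end - pos) + 1
            offset += len(seg)
        return None

    def cds_to_genomic(self, cpos: int) -> int:
        if not 1 <= cpos <= self.cds_length:
            raise ValueError(f"c.{cpos} outside CDS of length {self.cds_length}")
        offset = 0
        for seg in self.cds_segments:
            if cpos <= offset + len(seg):
                k = cpos - offset - 1
                return seg.start + k if self.strand == "+" else seg.end - k
            offset += len(seg)
        raise AssertionError("unreachable")


def extract_cds(tm: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Concatenated, strand-corrected CDS (including the stop codon)."""
    try:
        contig_seq = genome[tm.contig]
    except KeyError:
        raise TranscriptModelError(f"contig {tm.contig!r} not in genome") from None
    parts = []
    for seg in sorted(tm.cds_segments, key=lambda s: s.start):
        piece = contig_seq[seg.start - 1 : seg.end]
        if len(piece) != len(seg):
            raise TranscriptModelError(f"exon {seg} extends beyond contig")
        parts.append(piece)
    cds = "".join(parts)  # genomic order; reverse-complement flips segment order too
    if tm.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    if len(cds) % 3 != 0:
        raise TranscriptModelError(
            f"{tm.transcript_id}: CDS length {len(cds)} not divisible by 3"
        )
    protein = str(Seq(cds).translate())
    if "*" in protein[:-1]:
        warnings.warn(
            f"{tm.transcript_id}: internal stop codon in reference frame",
            stacklevel=2,
        )
    return cds


def translate_cds(cds: str) -> str:
    """Translate a CDS to its protein, stopping at (and excluding) the
    first stop codon."""
    protein = str(Seq(cds[: len(cds) // 3 * 3]).translate())
    stop = protein.find("*")
    return protein if stop < 0 else protein[:stop]


# -- transcript table I/O -------------------------------------------------

_COLUMNS = [
    "gene",
    "transcript",
    "contig",
    "strand",
    "exon_start",
    "exon_end",
    "cds_start",
    "cds_end",
]


def read_transcripts(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from a tab-delimited exon table.

    One row per exon with columns ``gene, transcript, contig, strand,
    exon_start, exon_end, cds_start, cds_end`` (the CDS columns repeat on
    every row of a transcript).
    """
    groups: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise TranscriptModelError(f"missing columns: {sorted(missing)}")
        for row in reader:
            g = groups.setdefault(
                row["transcript"],
                {
                    "gene": row["gene"],
                    "contig": row["contig"],
                    "strand": row["strand"],
                    "cds_start": int(row["cds_start"]),
                    "cds_end": int(row["cds_end"]),
                    "exons": [],
                },
            )
            g["exons"].append(
                GenomicInterval(
                    row["contig"], int(row["exon_start"]), int(row["exon_end"])
                )
            )
    return [
        TranscriptModel(
            gene=g["gene"],
            transcript_id=tid,
            contig=g["contig"],
            strand=g["strand"],
            exons=tuple(g["exons"]),
            cds_start=g["cds_start"],
            cds_end=g["cds_end"],
        )
        for tid, g in groups.items()
    ]


def write_transcripts(models: list[TranscriptModel], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_COLUMNS)
        for tm in models:
            for e in sorted(tm.exons, key=lambda e: e.start):
                writer.writerow(
                    [
                        tm.gene,
                        tm.transcript_id,
                        tm.contig,
                        tm.strand,
                        e.start,
                        e.end,
                        tm.cds_start,
                        tm.cds_end,
                    ]
                )


# -- projection to coding coordinates -------------------------------------


@dataclass(frozen=True)
class CodingVariant:
    """A variant projected into CDS space.

    ``c_pos`` is the coordinate used in ``c_name`` (for insertions, the
    3'-most base after which the sequence is inserted). ``cds_start_index``,
    ``cds_ref`` and ``cds_alt`` describe the edit in CDS orientation:
    ``cds_ref`` (possibly empty) is replaced by ``cds_alt`` starting at
    1-based CDS position ``cds_start_index``; for a pure insertion the
    sequence goes in *after* position ``cds_start_index``.
    """

    variant: Variant
    c_pos: int
    c_name: str
    cds_start_index: int
    cds_ref: str
    cds_alt: str
    transcript_id: str = field(default="", compare=False)


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement()) if s else ""


def project_to_cds(
    v: Variant, tm: TranscriptModel, genome: Mapping[str, str]
) -> CodingVariant | None:
    """Project a genomic variant onto a transcript's CDS.

    Returns ``None`` (the non-coding signal) for variants that do not lie
    fully within the CDS exons of the transcript. Insertions are 3'-shifted
    within the CDS so that the name anchors at the downstream-most base of
    a repeat run (``c.4176insC`` for a cytosine inserted anywhere in the
    c.4170-4176 C7 run); SNVs are named ``c.<pos><ref>><alt>``.
    """
    if v.contig != tm.contig:
        return None
    cds = extract_cds(tm, genome)
    start, dseq, iseq = minimal_edit(v.ref, v.alt, v.pos)

    if dseq and iseq and len(dseq) == len(iseq):  # SNV / MNV substitution
        cpos = [tm.genomic_to_cds(start + k) for k in range(len(dseq))]
        if any(c is None for c in cpos):
            return None
        if tm.strand == "+":
            c0, cref, calt = cpos[0], dseq, iseq
        else:
            c0, cref, calt = cpos[-1], _revcomp(dseq), _revcomp(iseq)
        if cds[c0 - 1 : c0 - 1 + len(cref)] != cref:
            return None  # split by an intron: not a contiguous CDS edit
        if len(cref) == 1:
            name = f"c.{c0}{cref}>{calt}"
        else:
            name = f"c.{c0}_{c0 + len(cref) - 1}delins{calt}"
        return CodingVariant(v, c0, name, c0, cref, calt, tm.transcript_id)

    if iseq and not dseq:  # pure insertion before genomic position `start`
        left, right = tm.genomic_to_cds(start - 1), tm.genomic_to_cds(start)
        if left is None or right is None or abs(left - right) != 1:
            return None  # at a CDS edge or across an intron
        s = iseq if tm.strand == "+" else _revcomp(iseq)
        i = min(left, right)  # insertion after CDS position i (0-based gap i)
        while i < len(cds) and cds[i] == s[0]:
            s = s[1:] + s[0]
            i += 1
        name = f"c.{i}ins{s}"
        return CodingVariant(v, i, name, i, "", s, tm.transcript_id)

    if dseq and not iseq:  # pure deletion of genomic span start..start+d-1
        d = len(dseq)
        cpos = [tm.genomic_to_cds(start + k) for k in range(d)]
        if any(c is None for c in cpos):
            return None
        j = min(cpos) - 1  # 0-based start of deleted run in CDS orientation
        if max(cpos) - min(cpos) != d - 1:
            return None  # interrupted by an intron
        while j + d < len(cds) and cds[j] == cds[j + d]:
            j += 1
        a, b = j + 1, j + d
        name = f"c.{a}del" if d == 1 else f"c.{a}_{b}del"
        return CodingVariant(v, a, name, a, cds[j : j + d], "", tm.transcript_id)

    # complex (unequal-length substitution)
    cpos = [tm.genomic_to_cds(start + k) for k in range(len(dseq))]
    if any(c is None for c in cpos) or max(cpos) - min(cpos) != len(dseq) - 1:
        return None
    if tm.strand == "+":
        c0, cref, calt = cpos[0], dseq, iseq
    else:
        c0, cref, calt = cpos[-1], _revcomp(dseq), _revcomp(iseq)
    name = f"c.{c0}_{c0 + len(cref) - 1}delins{calt}"
    return CodingVariant(v, c0, name, c0, cref, calt, tm.transcript_id)


# -- consequence calling --------------------------------------------------


@dataclass(frozen=True)
class ProteinConsequence:
    """Classified protein-level effect of a coding variant.

    ``mut_length`` and ``wt_length`` count residues excluding the stop
    codon; ``stop_position`` is the absolute codon index of a *new* stop
    (``mut_length + 1`` for a premature termination), ``None`` when the
    stop is unchanged; ``residues_lost = wt_length - mut_length``.
    """

    kind: str
    p_name: str
    wt_length: int
    mut_length: int
    stop_position: int | None
    residues_lost: int
    first_changed_residue: int | None = None
    c_name: str = ""


def _apply_cds_edit(cds: str, cv: CodingVariant) -> str:
    i = cv.cds_start_index
    if cv.cds_ref == "":  # insertion after position i
        return cds[:i] + cv.cds_alt + cds[i:]
    if cds[i - 1 : i - 1 + len(cv.cds_ref)] != cv.cds_ref:
        raise TranscriptModelError(
            f"CDS edit ref mismatch at c.{i}: expected {cv.cds_ref!r}"
        )
    return cds[: i - 1] + cv.cds_alt + cds[i - 1 + len(cv.cds_ref) :]


def call_consequence(
    cv: CodingVariant,
    tm: TranscriptModel,
    genome: Mapping[str, str],
    dialect: str = "absolute",
) -> ProteinConsequence:
    """Apply a CDS edit, translate both alleles, and classify the effect.

    ``dialect="absolute"`` (default) writes frameshift names with the
    absolute codon index of the new stop (``p.F1393Lfs*1395``);
    ``dialect="hgvs"`` counts the stop from the first changed residue
    (``p.F1393Lfs*3``).
    """
    if dialect not in ("absolute", "hgvs"):
        raise ValueError("dialect must be 'absolute' or 'hgvs'")
    cds = extract_cds(tm, genome)
    mut_cds = _apply_cds_edit(cds, cv)
    wt = translate_cds(cds)
    mut = translate_cds(mut_cds)
    wt_len, mut_len = len(wt), len(mut)
    delta = len(cv.cds_alt) - len(cv.cds_ref)

    # index (1-based) of the first residue where mutant differs from wild type
    first_changed: int | None = None
    for i in range(min(wt_len, mut_len)):
        if wt[i] != mut[i]:
            first_changed = i + 1
            break
    if first_changed is None and wt_len != mut_len:
        first_changed = min(wt_len, mut_len) + 1

    mut_has_stop = "*" in str(Seq(mut_cds[: len(mut_cds) // 3 * 3]).translate())

    # start-codon loss dominates every other classification
    if mut_cds[:3] != cds[:3] and cds[:3] == "ATG" and mut_cds[:3] != "ATG":
        return ProteinConsequence(
            "start_lost", "p.M1?", wt_len, mut_len, None, wt_len - mut_len,
            1, cv.c_name,
        )

    if delta % 3 != 0:
        if first_changed is None:  # degenerate: shift after the last codon
            first_changed = wt_len + 1
        stop_position = mut_len + 1 if mut_has_stop else None
        wt_aa = wt[first_changed - 1] if first_changed <= wt_len else "*"
        mut_aa = mut[first_changed - 1] if first_changed <= mut_len else "*"
        if mut_aa == "*":  # immediate nonsense at the first shifted codon
            p_name = f"p.{wt_aa}{first_changed}*"
        elif not mut_has_stop:
            p_name = f"p.{wt_aa}{first_changed}{mut_aa}fs*?"
        elif dialect == "absolute":
            p_name = f"p.{wt_aa}{first_changed}{mut_aa}fs*{mut_len + 1}"
        else:
            p_name = f"p.{wt_aa}{first_changed}{mut_aa}fs*{mut_len + 1 - first_changed + 1}"
        return ProteinConsequence(
            "frameshift", p_name, wt_len, mut_len, stop_position,
            wt_len - mut_len, first_changed, cv.c_name,
        )

    if delta != 0:  # in-frame insertion or deletion
        if first_changed is None:
            first_changed = min(wt_len, mut_len) + 1
        expected_len = wt_len + delta // 3
        if mut_len < expected_len:  # the indel junction created a stop
            return ProteinConsequence(
                "stop_gained",
                f"p.{wt[first_changed - 1] if first_changed <= wt_len else '*'}"
                f"{first_changed}*",
                wt_len, mut_len, mut_len + 1, wt_len - mut_len,
                first_changed, cv.c_name,
            )
        if mut_len > expected_len:  # the reference stop codon was removed
            return ProteinConsequence(
                "stop_lost", f"p.*{wt_len + 1}ext*?", wt_len, mut_len,
                None, wt_len - mut_len, first_changed, cv.c_name,
            )
        p_name = f"p.{first_changed}{'ins' if delta > 0 else 'del'}{abs(delta) // 3}aa"
        return ProteinConsequence(
            "inframe_indel", p_name, wt_len, mut_len, None,
            wt_len - mut_len, first_changed, cv.c_name,
        )

    # length-preserving substitution
    if mut_len < wt_len:  # a codon became a stop
        pos = mut_len + 1
        return ProteinConsequence(
            "stop_gained", f"p.{wt[pos - 1]}{pos}*", wt_len, mut_len,
            pos, wt_len - mut_len, pos, cv.c_name,
        )
    if mut_len > wt_len:  # reference stop codon destroyed
        aa = mut[wt_len]
        return ProteinConsequence(
            "stop_lost", f"p.*{wt_len + 1}{aa}ext*?", wt_len, mut_len,
            None, wt_len - mut_len, wt_len + 1, cv.c_name,
        )
    if first_changed is None:
        pos = (cv.cds_start_index + 2) // 3
        aa = wt[pos - 1] if pos <= wt_len else "*"
        return ProteinConsequence(
            "synonymous", f"p.{aa}{pos}=", wt_len, mut_len, None, 0, None, cv.c_name,
        )
    return ProteinConsequence(
        "missense",
        f"p.{wt[first_changed - 1]}{first_changed}{mut[first_changed - 1]}",
        wt_len, mut_len, None, 0, first_changed, cv.c_name,
    )
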