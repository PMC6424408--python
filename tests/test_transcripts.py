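"""CDS extraction, coordinate projection, and consequence calling.

The consequence caller is checked against an independent brute-force
oracle that re-translates the edited CDS codon by codon with its own
codon table.
"""

import numpy as np
import pytest

from triovar.errors import TranscriptModelError
from triovar.transcripts import (
    CodingVariant,
    GenomicInterval,
    TranscriptModel,
    call_consequence,
    extract_cds,
    project_to_cds,
    read_transcripts,
    translate_cds,
    write_transcripts,
)
from triovar.variants import Variant

# independent standard-code table for the oracle (built from first
# principles: base ordering TCAG per classical codon wheel)
_T = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _T[16 * i + 4 * j + k]
    for i, a in enumerate("TCAG")
    for j, b in enumerate("TCAG")
    for k, c in enumerate("TCAG")
}


def oracle_translate(cds: str) -> str:
    protein = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TABLE[cds[i : i + 3]]
        if aa == "*":
            return "".join(protein)
        protein.append(aa)
    return "".join(protein)


def oracle_consequence(cds: str, mut_cds: str):
    """(kind, mut_length, stop_position) by naive re-translation."""
    wt, mut = oracle_translate(cds), oracle_translate(mut_cds)
    delta = len(mut_cds) - len(cds)
    has_stop = "*" in [
        CODON_TABLE[mut_cds[i : i + 3]]
        for i in range(0, len(mut_cds) - len(mut_cds) % 3, 3)
    ]
    if delta % 3 != 0:
        kind = "frameshift"
        stop = len(mut) + 1 if has_stop else None
    elif delta != 0:
        expected = len(wt) + delta // 3
        if len(mut) < expected:
            kind, stop = "stop_gained", len(mut) + 1
        elif len(mut) > expected:
            kind, stop = "stop_lost", None
        else:
            kind, stop = "inframe_indel", None
    else:
        if len(mut) < len(wt):
            kind, stop = "stop_gained", len(mut) + 1
        elif len(mut) > len(wt):
            kind, stop = "stop_lost", None
        elif mut == wt:
            kind, stop = "synonymous", None
        else:
            kind, stop = "missense", None
    return kind, len(mut), stop


def single_exon_transcript(cds: str, offset: int = 101, contig: str = "ctg"):
    genome = {contig: "A" * (offset - 1) + cds + "A" * 50}
    tm = TranscriptModel(
        gene="TOY",
        transcript_id="TOY-1",
        contig=contig,
        strand="+",
        exons=(GenomicInterval(contig, offset, offset + len(cds) - 1),),
        cds_start=offset,
        cds_end=offset + len(cds) - 1,
    )
    return genome, tm


def random_cds(rng, n_codons: int) -> str:
    nonstop = [c for c in CODON_TABLE if CODON_TABLE[c] != "*" and "U" not in c]
    nonstop = [c.replace("T", "T") for c in sorted(nonstop)]
    codons = list(rng.choice(sorted(nonstop), size=n_codons))
    codons[0] = "ATG"
    return "".join(codons) + "TAA"


class TestExtractCds:
    def test_single_exon_plus_strand(self):
        genome, tm = single_exon_transcript("ATGGCCTAA")
        assert extract_cds(tm, genome) == "ATGGCCTAA"

    def test_two_exon_minus_strand_hand_computed(self):
        # genomic:  1..4 = TTAC (exon2), 8..15 = GGCATCAT (exon1, 3' half)
        # minus-strand CDS = revcomp(TTACGGCATCAT) = ATGATGCCGTAA
        genome = {"m": "TTACNNNGGCATCAT"}
        tm = TranscriptModel(
            gene="M", transcript_id="M-1", contig="m", strand="-",
            exons=(GenomicInterval("m", 1, 4), GenomicInterval("m", 8, 15)),
            cds_start=15, cds_end=1,
        )
        assert extract_cds(tm, genome) == "ATGATGCCGTAA"

    def test_construct_cds_dimensions(self, construct):
        cds = extract_cds(construct.transcript, construct.genome)
        assert len(cds) == 6807  # 2,268 codons + stop
        assert len(translate_cds(cds)) == 2268

    def test_length_not_multiple_of_three_rejected(self):
        genome = {"c": "ATGGCCTAAA"}
        tm = TranscriptModel(
            gene="X", transcript_id="X-1", contig="c", strand="+",
            exons=(GenomicInterval("c", 1, 10),), cds_start=1, cds_end=10,
        )
        with pytest.raises(TranscriptModelError):
            extract_cds(tm, genome)

    def test_internal_stop_warns(self):
        genome, tm = single_exon_transcript("ATGTAAGGCTAA")
        with pytest.warns(UserWarning, match="internal stop"):
            extract_cds(tm, genome)


class TestTranscriptTableRoundTrip:
    def test_write_read_round_trip(self, tmp_path, construct):
        path = tmp_path / "tx.tsv"
        write_transcripts([construct.transcript], path)
        (again,) = read_transcripts(path)
        assert again == construct.transcript


class TestProjection:
    def test_causal_insertion_named_c4176insC(self, construct):
        cv = project_to_cds(construct.causal, construct.transcript, construct.genome)
        assert cv.c_name == "c.4176insC"
        assert cv.c_pos == 4176

    def test_snv_at_cds_position_7244(self):
        # second toy transcript, large enough to hold c.7244
        rng = np.random.default_rng(42)
        cds = list(random_cds(rng, 2500))
        cds[7243] = "C"
        if CODON_TABLE["".join(cds[7242:7245])] == "*":
            cds[7242] = "A"
        genome, tm = single_exon_transcript("".join(cds))
        v = Variant("ctg", 101 + 7243, "C", "T")
        cv = project_to_cds(v, tm, genome)
        assert cv.c_name == "c.7244C>T"

    def test_intronic_variant_is_non_coding(self, construct):
        tm = construct.transcript
        gap_pos = tm.exons[0].end + 1  # first intron base
        base = construct.genome[tm.contig][gap_pos - 1]
        alt = "A" if base != "A" else "G"
        assert project_to_cds(Variant(tm.contig, gap_pos, base, alt), tm, construct.genome) is None


class TestConsequence:
    def test_causal_insertion_full_consequence(self, construct):
        cv = project_to_cds(construct.causal, construct.transcript, construct.genome)
        pc = call_consequence(cv, construct.transcript, construct.genome)
        assert pc.kind == "frameshift"
        assert pc.p_name == "p.F1393Lfs*1395"
        assert pc.stop_position == 1395
        assert pc.mut_length == 1394
        assert pc.wt_length == 2268
        assert pc.residues_lost == 874

    def test_standard_hgvs_dialect(self, construct):
        cv = project_to_cds(construct.causal, construct.transcript, construct.genome)
        pc = call_consequence(cv, construct.transcript, construct.genome, dialect="hgvs")
        assert pc.p_name == "p.F1393Lfs*3"

    def test_synonymous_wobble(self):
        genome, tm = single_exon_transcript("ATGCTGGCCTAA")
        v = Variant("ctg", 106, "G", "A")  # CTG -> CTA, both leucine
        pc = call_consequence(project_to_cds(v, tm, genome), tm, genome)
        assert pc.kind == "synonymous"
        assert pc.mut_length == pc.wt_length == 3
        assert pc.residues_lost == 0

    def test_missense(self):
        genome, tm = single_exon_transcript("ATGCTGGCCTAA")
        v = Variant("ctg", 104, "C", "A")  # CTG -> ATG: L2M
        pc = call_consequence(project_to_cds(v, tm, genome), tm, genome)
        assert pc.kind == "missense" and pc.p_name == "p.L2M"

    def test_stop_gained_snv(self):
        genome, tm = single_exon_transcript("ATGTACGCCTAA")
        v = Variant("ctg", 106, "C", "A")  # TAC -> TAA
        pc = call_consequence(project_to_cds(v, tm, genome), tm, genome)
        assert pc.kind == "stop_gained" and pc.stop_position == 2
        assert pc.mut_length == 1

    def test_start_lost(self):
        genome, tm = single_exon_transcript("ATGTACGCCTAA")
        v = Variant("ctg", 101, "A", "C")
        pc = call_consequence(project_to_cds(v, tm, genome), tm, genome)
        assert pc.kind == "start_lost" and pc.p_name == "p.M1?"

    def test_inframe_deletion_preserves_downstream(self):
        rng = np.random.default_rng(5)
        cds = random_cds(rng, 40)
        genome, tm = single_exon_transcript(cds)
        # delete codon 10 exactly (an in-frame deletion)
        pos = 101 + 26  # anchor = last base of codon 9
        ref = genome["ctg"][pos - 1 : pos + 3]
        v = Variant("ctg", pos, ref, ref[0])
        pc = call_consequence(project_to_cds(v, tm, genome), tm, genome)
        assert pc.kind == "inframe_indel"
        assert pc.mut_length == pc.wt_length - 1
        # residues after the edited span match the wild type, shifted by one
        wt = translate_cds(cds)
        mut_cds = cds[: pos - 101 + 1] + cds[pos - 101 + 5 - 1 + 0 :]
        assert translate_cds(mut_cds)[10:] == wt[11:]

    def test_oracle_equivalence_on_random_edits(self):
        """200+ random CDS/edit pairs agree with brute-force re-translation."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 220:
            cds = random_cds(rng, int(rng.integers(20, 80)))
            genome, tm = single_exon_transcript(cds)
            kind = rng.choice(["snv", "ins", "del"])
            pos = int(rng.integers(101, 101 + len(cds) - 2))
            seq = genome["ctg"]
            if kind == "snv":
                ref = seq[pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                v = Variant("ctg", pos, ref, alt)
                mut_cds = (
                    cds[: pos - 101] + alt + cds[pos - 101 + 1 :]
                )
            elif kind == "ins":
                ins = str(rng.choice(list("ACGT")))
                v = Variant("ctg", pos, seq[pos - 1], seq[pos - 1] + ins)
                mut_cds = cds[: pos - 101 + 1] + ins + cds[pos - 101 + 1 :]
            else:
                if pos - 101 + 2 > len(cds):
                    continue
                v = Variant("ctg", pos, seq[pos - 1 : pos + 1], seq[pos - 1])
                mut_cds = cds[: pos - 101 + 1] + cds[pos - 101 + 2 :]
            cv = project_to_cds(v, tm, genome)
            if cv is None:
                continue
            pc = call_consequence(cv, tm, genome)
            exp_kind, exp_len, exp_stop = oracle_consequence(cds, mut_cds)
            if pc.kind in ("start_lost",):
                checked += 1
                continue  # oracle does not model start-codon semantics
            assert (pc.kind, pc.mut_length, pc.stop_position) == (
                exp_kind, exp_len, exp_stop,
            ), f"{v} on CDS len {len(cds)}"
            checked += 1

    def test_strand_symmetry(self):
        """A variant and its reverse-complement twin on the mirrored
        minus-strand transcript give identical consequences."""
        from Bio.Seq import Seq

        rng = np.random.default_rng(99)
        cds = random_cds(rng, 30)
        genome_fwd, tm_fwd = single_exon_transcript(cds, offset=101)
        L = len(genome_fwd["ctg"])
        genome_rev = {"ctg": str(Seq(genome_fwd["ctg"]).reverse_complement())}
        start = L - (101 + len(cds) - 1) + 1
        tm_rev = TranscriptModel(
            gene="TOY", transcript_id="TOY-1R", contig="ctg", strand="-",
            exons=(GenomicInterval("ctg", start, start + len(cds) - 1),),
            cds_start=start + len(cds) - 1, cds_end=start,
        )
        assert extract_cds(tm_rev, genome_rev) == cds
        for pos in (105, 110, 123, 140):
            ref = genome_fwd["ctg"][pos - 1]
            alt = "C" if ref != "C" else "G"
            v_fwd = Variant("ctg", pos, ref, alt)
            mirror_pos = L - pos + 1
            v_rev = Variant(
                "ctg", mirror_pos,
                str(Seq(ref).reverse_complement()),
                str(Seq(alt).reverse_complement()),
            )
            pc_f = call_consequence(
                project_to_cds(v_fwd, tm_fwd, genome_fwd), tm_fwd, genome_fwd
            )
            pc_r = call_consequence(
                project_to_cds(v_rev, tm_rev, genome_rev), tm_rev, genome_rev
            )
            assert (pc_f.kind, pc_f.p_name, pc_f.mut_length) == (
                pc_r.kind, pc_r.p_name, pc_r.mut_length,
            )

    def test_p_name_deterministic(self, construct):
        cv1 = project_to_cds(construct.causal, construct.transcript, construct.genome)
        cv2 = project_to_cds(construct.causal, construct.transcript, construct.genome)
        a = call_consequence(cv1, construct.transcript, construct.genome)
        b = call_consequence(cv2, construct.transcript, construct.genome)
        assert a == b
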