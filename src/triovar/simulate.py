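"""Seeded synthetic-data generation for the whole pipeline.

Everything the discovery pipeline consumes can be generated from a single
integer seed: a toy reference contig carrying an ABCA4-like transcript
construct, a family-quartet VCF with a planted causal insertion and
labelled nuisance variants, a panel of additional genomes, a validation
cohort, effect-score and disease-gene tables, and phenotype-quantification
fixtures (qPCR Ct, nuclei counts, autofluorescence).

The construct reproduces the *published dimensions* of the canine ABCA4
coding sequence — 2,268 codons plus stop, a seven-cytosine run at
c.4170-4176, phenylalanine (TTC) at codon 1393, and a +1-frame stop
engineered so that inserting a cytosine after c.4176 truncates translation
at absolute codon 1395 — without claiming sequence fidelity to the real
gene; every other codon is a random non-stop codon.

Determinism: one master seed drives named substreams
(``np.random.default_rng([seed, k])``), so each output is byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError
from .segregation import Pedigree, PedigreeSample, Trio, write_pedigree
from .transcripts import STOP_CODONS, TranscriptModel, translate_cds, write_transcripts
from .variants import (
    GenomicInterval,
    GenotypeMatrix,
    Variant,
    write_fasta,
    write_vcf,
)

_BASES = np.array(list("ACGT"))
_NONSTOP = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOP_CODONS
)

#: Cascade-condition labels a nuisance variant can violate.
NUISANCE_LABELS = ("fails_trio1", "fails_trio2", "panel_hom", "not_exonic", "synonymous")

#: The stage of the discovery cascade at which each nuisance class must fall.
NUISANCE_STAGE = {
    "fails_trio1": "ar_trio1",
    "fails_trio2": "ar_trio2",
    "panel_hom": "private",
    "not_exonic": "exonic",
    "synonymous": "candidates",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic generators.

    Defaults encode the emulated study: a 2,268-codon CDS with the C7 run
    at c.4170-4176 and a frameshift stop at absolute codon 1395, a family
    quartet (two carrier parents, two affected offspring), a 23-genome
    comparison panel, and a validation cohort of 8 affected plus 14
    unaffected individuals.
    """

    seed: int = 0
    # construct geometry (coding coordinates)
    cds_codons: int = 2268
    repeat_run_start: int = 4170
    repeat_run_end: int = 4176
    first_changed_codon: int = 1393  # phenylalanine (TTC) in the wild type
    frameshift_stop_codon: int = 1395
    n_exons: int = 50
    genome_length: int = 100_000
    contig: str = "chr6"
    gene: str = "ABCA4"
    transcript_id: str = "ABCA4-tx1"
    tx_offset: int = 5001
    # quartet / panel / cohort
    n_panel: int = 23
    n_affected: int = 8
    n_unaffected: int = 14
    nuisance_per_class: int = 3
    panel_af_max: float = 0.3
    causal_panel_af: float = 0.1
    # phenotype-quant planted effects
    ct_noise_sd: float = 0.2
    fold_het: float = 0.6
    fold_affected: float = 0.25
    onl_wt: int = 100
    inl_wt: int = 40
    cones_wt: int = 10
    onl_reduction: float = 0.46
    count_noise_cv: float = 0.10
    fluor_background: float = 10.0
    fluor_signal_wt: float = 5.0
    fluor_contrast: float = 7.0
    fluor_noise_sd: float = 0.5
    n_images_per_group: int = 6

    def __post_init__(self) -> None:
        if self.repeat_run_end >= self.cds_codons * 3:
            raise GenerationError("repeat run must lie inside the CDS")
        if self.frameshift_stop_codon <= self.first_changed_codon:
            raise GenerationError("frameshift stop must lie beyond the first changed codon")
        if min(self.n_panel, self.n_affected, self.n_unaffected, self.cds_codons) <= 0:
            raise GenerationError("counts must be positive")


@dataclass
class Construct:
    """A generated reference contig plus its transcript model."""

    genome: dict[str, str]
    transcript: TranscriptModel
    cds: str  # including the stop codon
    causal: Variant  # canonical right-aligned single-C insertion
    repeat_run: GenomicInterval


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# -- construct ------------------------------------------------------------


def build_construct(cfg: SimulationConfig = SimulationConfig()) -> Construct:
    """Build the toy genome and ABCA4-like transcript.

    The wild-type frame contains no internal stop; the +1 frame entered by
    a single-base insertion after the repeat run hits its first stop at
    exactly ``cfg.frameshift_stop_codon``. Violated constraints raise
    :class:`~triovar.errors.GenerationError` after bounded retries.
    """
    rng = _rng(cfg, 1)
    fc, fs = cfg.first_changed_codon, cfg.frameshift_stop_codon
    if cfg.repeat_run_end != (fc - 1) * 3:
        raise GenerationError(
            "repeat run must end on the codon boundary preceding the first changed codon"
        )
    for _ in range(100):
        codons = list(rng.choice(_NONSTOP, size=cfg.cds_codons))
        codons[0] = "ATG"
        # plant the cytosine run (all run bases C; boundary bases non-C)
        for p in range(cfg.repeat_run_start, cfg.repeat_run_end + 1):
            ci, off = (p - 1) // 3, (p - 1) % 3
            c = list(codons[ci])
            c[off] = "C"
            codons[ci] = "".join(c)
        for boundary in (cfg.repeat_run_start - 1, cfg.repeat_run_end + 1):
            ci, off = (boundary - 1) // 3, (boundary - 1) % 3
            if codons[ci][off] == "C":
                c = list(codons[ci])
                c[off] = str(rng.choice([b for b in "AGT"]))
                codons[ci] = "".join(c)
        codons[fc - 1] = "TTC"  # phenylalanine at the first shifted codon
        # The +1 frame reads [codon k-1 base 3, codon k bases 1-2]; its stop
        # codons all start with T, so codon fs-1 must end in T and codon fs
        # must begin with one of AA/AG/GA to shift into a stop.
        end_t = [c for c in _NONSTOP if c.endswith("T")]
        codons[fs - 2] = str(rng.choice(end_t))
        start_ok = [c for c in _NONSTOP if c[:2] in ("AA", "AG", "GA")]
        codons[fs - 1] = str(rng.choice(start_ok))
        ok = all(
            (codons[k - 2][2] + codons[k - 1][:2]) not in STOP_CODONS
            for k in range(fc + 1, fs)
        )
        if not any(c in STOP_CODONS for c in codons) and ok:
            break
    else:
        raise GenerationError("could not satisfy construct constraints")
    cds = "".join(codons) + "TAA"

    # sanity scan: wild-type clean, first +1-frame stop exactly at `fs`
    if "*" in translate_cds(cds[:-3]) or len(translate_cds(cds)) != cfg.cds_codons:
        raise GenerationError("wild-type frame contains an internal stop")
    shifted = cds[: cfg.repeat_run_end] + "C" + cds[cfg.repeat_run_end :]
    mut_len = len(translate_cds(shifted))
    if mut_len != fs - 1:
        raise GenerationError(
            f"+1-frame stop lands at codon {mut_len + 1}, expected {fs}"
        )

    genome, tm = _embed(cfg, cds, rng)
    g_run_end = tm.cds_to_genomic(cfg.repeat_run_end)
    causal = Variant(cfg.contig, g_run_end, "C", "CC", id="causal")
    run = GenomicInterval(
        cfg.contig, tm.cds_to_genomic(cfg.repeat_run_start), g_run_end
    )
    return Construct({cfg.contig: genome}, tm, cds, causal, run)


def _embed(
    cfg: SimulationConfig, cds: str, rng: np.random.Generator
) -> tuple[str, TranscriptModel]:
    """Split the CDS into exons on a random background contig (+ strand)."""
    length = len(cds)
    n = cfg.n_exons
    min_exon = 30
    if n * min_exon > length:
        raise GenerationError(f"cannot split {length} nt into {n} exons")
    forbidden = range(cfg.repeat_run_start - 3, cfg.repeat_run_end + 4)
    for _ in range(100):
        extra = rng.multinomial(length - n * min_exon, [1.0 / n] * n)
        sizes = (min_exon + extra).astype(int)
        cuts = np.cumsum(sizes)[:-1]
        if not any(int(c) in forbidden for c in cuts):
            break
    else:
        raise GenerationError("could not place exon boundaries")
    introns = rng.integers(200, 1501, size=n - 1)
    span = length + int(introns.sum())
    if cfg.tx_offset + span > cfg.genome_length - 100:
        raise GenerationError("transcript does not fit in the toy genome")
    background = "".join(rng.choice(_BASES, size=cfg.genome_length))
    seq = list(background)
    exons = []
    g = cfg.tx_offset
    c = 0
    for i, size in enumerate(int(s) for s in sizes):
        exons.append(GenomicInterval(cfg.contig, g, g + size - 1))
        seq[g - 1 : g - 1 + size] = list(cds[c : c + size])
        c += size
        g += size + (int(introns[i]) if i < n - 1 else 0)
    tm = TranscriptModel(
        gene=cfg.gene,
        transcript_id=cfg.transcript_id,
        contig=cfg.contig,
        strand="+",
        exons=tuple(exons),
        cds_start=exons[0].start,
        cds_end=exons[-1].end,
    )
    return "".join(seq), tm


# -- quartet + panel ------------------------------------------------------

QUARTET = ("LAB1", "LAB2", "LAB3", "LAB4")  # sire, dam, affected offspring x2


@dataclass
class QuartetPanel:
    quartet: GenotypeMatrix
    panel: list[GenotypeMatrix]
    pedigree: Pedigree
    trios: list[Trio]
    nuisance_labels: dict[str, str]  # variant id -> violated condition
    causal: Variant


def _hwe_dosage(rng: np.random.Generator, af: float, n: int) -> np.ndarray:
    return (rng.random(n) < af).astype(int) + (rng.random(n) < af).astype(int)


def simulate_quartet_and_panel(
    cfg: SimulationConfig, construct: Construct
) -> QuartetPanel:
    """Plant the causal insertion plus labelled nuisance variants.

    The causal variant segregates recessively (parents het, both affected
    offspring hom-alt) and is never homozygous in the panel. Each nuisance
    variant violates exactly one cascade condition (see
    :data:`NUISANCE_LABELS`) and satisfies all others, so the full cascade
    must recover exactly the causal variant.
    """
    rng = _rng(cfg, 2)
    genome = construct.genome[cfg.contig]
    causal = construct.causal

    spec: list[str] = [
        label for label in NUISANCE_LABELS for _ in range(cfg.nuisance_per_class)
    ]
    used = {causal.pos}
    entries = []  # (Variant, info, quartet dosages, label)
    for i, label in enumerate(spec):
        while True:
            pos = int(rng.integers(1000, cfg.genome_length - 1000))
            if all(abs(pos - u) > 1 for u in used):
                break
        used.add(pos)
        ref = genome[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        v = Variant(cfg.contig, pos, ref, alt, id=f"nuis{i + 1:03d}")
        info = {
            "gene": f"GENE{i + 1:03d}",
            "exonic": label != "not_exonic",
            "nonsynonymous": label != "synonymous",
        }
        if label == "fails_trio1":
            dosages = [1, 1, 1, 2]
        elif label == "fails_trio2":
            dosages = [1, 1, 2, 1]
        else:
            dosages = [1, 1, 2, 2]
        entries.append((v, info, dosages, label))
    causal_info = {"gene": cfg.gene, "exonic": True, "nonsynonymous": True}
    entries.append((causal, causal_info, [1, 1, 2, 2], "causal"))
    entries.sort(key=lambda e: e[0].key)

    variants = [e[0] for e in entries]
    infos = [e[1] for e in entries]
    calls = np.array([e[2] for e in entries], dtype=np.int8)
    quartet = GenotypeMatrix(variants, list(QUARTET), calls, infos)
    labels = {e[0].id: e[3] for e in entries if e[3] != "causal"}

    # panel genotypes: per-variant allele frequencies, homozygosity forced
    # in (only) the panel_hom class and forbidden elsewhere
    n = cfg.n_panel
    panel_calls = np.zeros((len(entries), n), dtype=np.int8)
    for r, (v, _info, _d, label) in enumerate(entries):
        if label == "causal":
            p_het = 2 * cfg.causal_panel_af * (1 - cfg.causal_panel_af)
            panel_calls[r] = (rng.random(n) < p_het).astype(np.int8)
        else:
            af = float(rng.uniform(0.02, cfg.panel_af_max))
            dos = _hwe_dosage(rng, af, n)
            if label == "panel_hom":
                if not (dos == 2).any():
                    dos[int(rng.integers(n))] = 2
            else:
                dos[dos == 2] = 1
            panel_calls[r] = dos
    panel = [
        GenotypeMatrix(
            variants, [f"PANEL{j + 1:02d}"], panel_calls[:, [j]], [dict(x) for x in infos]
        )
        for j in range(n)
    ]

    pedigree = Pedigree(
        [
            PedigreeSample("LAB1", None, None, "male", "unaffected", "sire"),
            PedigreeSample("LAB2", None, None, "female", "unaffected", "dam"),
            PedigreeSample("LAB3", "LAB1", "LAB2", "female", "affected", "offspring"),
            PedigreeSample("LAB4", "LAB1", "LAB2", "male", "affected", "offspring"),
        ]
    )
    trios = [Trio("LAB1", "LAB2", "LAB3"), Trio("LAB1", "LAB2", "LAB4")]
    return QuartetPanel(quartet, panel, pedigree, trios, labels, causal)


# -- cohort ---------------------------------------------------------------


def simulate_cohort(
    cfg: SimulationConfig, inject_discordant: int = 0
) -> pd.DataFrame:
    """Validation cohort: affected individuals hom-alt, unaffected ones
    het or hom-ref (seeded); ``inject_discordant`` appends that many
    affected heterozygotes for negative testing."""
    rng = _rng(cfg, 3)
    rows = []
    for i in range(cfg.n_affected):
        rows.append((f"VAL{i + 1:02d}", "affected", "1/1"))
    for i in range(cfg.n_unaffected):
        gt = "0/1" if rng.random() < 0.5 else "0/0"
        rows.append((f"VAL{cfg.n_affected + i + 1:02d}", "unaffected", gt))
    for i in range(inject_discordant):
        rows.append((f"DISC{i + 1:02d}", "affected", "0/1"))
    return pd.DataFrame(rows, columns=["dog_id", "phenotype", "genotype"])


# -- phenotype tables -----------------------------------------------------

GROUPS = ("wild_type", "het", "affected")


def simulate_phenotype_tables(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Ct, nuclei-count and fluorescence tables with planted group effects.

    Planted truths: expression folds (wild_type 1.0, het ``fold_het``,
    affected ``fold_affected``), an ``onl_reduction`` fraction of ONL
    nuclei in the affected group with cones absent there, and a
    ``fluor_contrast``-fold background-corrected autofluorescence in the
    affected group. Setting the noise parameters to zero recovers the
    planted values exactly.
    """
    rng = _rng(cfg, 4)
    folds = {"wild_type": 1.0, "het": cfg.fold_het, "affected": cfg.fold_affected}
    base_ref, base_dct = 18.0, 6.0
    ct_rows = []
    for group in GROUPS:
        sample = f"S_{group.upper()}"
        for amplicon in ("ex2-3", "ex27-28", "ex47-48"):
            for rep in range(1, 4):
                noise = rng.normal(0, cfg.ct_noise_sd) if cfg.ct_noise_sd else 0.0
                ct_rows.append(
                    (sample, group, "target", amplicon, rep,
                     base_ref + base_dct - np.log2(folds[group]) + noise)
                )
        for rep in range(1, 4):
            noise = rng.normal(0, cfg.ct_noise_sd) if cfg.ct_noise_sd else 0.0
            ct_rows.append((sample, group, "reference", "GAPDH", rep, base_ref + noise))
    ct = pd.DataFrame(
        ct_rows, columns=["sample", "group", "gene", "amplicon", "replicate", "ct"]
    )

    count_rows = []
    onl_means = {
        "wild_type": cfg.onl_wt,
        "het": cfg.onl_wt,
        "affected": round(cfg.onl_wt * (1 - cfg.onl_reduction)),
    }
    cone_means = {"wild_type": cfg.cones_wt, "het": cfg.cones_wt, "affected": 0}
    for group in GROUPS:
        for i in range(cfg.n_images_per_group):

            def jitter(mean: float) -> int:
                if cfg.count_noise_cv == 0:
                    return int(round(mean))
                return max(0, int(round(mean * np.exp(rng.normal(0, cfg.count_noise_cv)))))

            onl = jitter(onl_means[group])
            cones = min(jitter(cone_means[group]), onl)
            count_rows.append(
                (f"{group}_img{i + 1}", group, onl, jitter(cfg.inl_wt), cones)
            )
    counts = pd.DataFrame(
        count_rows,
        columns=["image_id", "group", "onl_nuclei", "inl_nuclei", "cone_count"],
    )

    fluor_rows = []
    signal = {
        "wild_type": cfg.fluor_signal_wt,
        "het": cfg.fluor_signal_wt,
        "affected": cfg.fluor_signal_wt * cfg.fluor_contrast,
    }
    for group in GROUPS:
        for i in range(cfg.n_images_per_group):
            bnoise = rng.normal(0, cfg.fluor_noise_sd) if cfg.fluor_noise_sd else 0.0
            rnoise = rng.normal(0, cfg.fluor_noise_sd) if cfg.fluor_noise_sd else 0.0
            bg = cfg.fluor_background + bnoise
            fluor_rows.append(
                (f"{group}_img{i + 1}", group, bg + signal[group] + rnoise, bg)
            )
    fluor = pd.DataFrame(
        fluor_rows, columns=["image_id", "group", "region_mean", "background_mean"]
    )
    return ct, counts, fluor


# -- bundle ---------------------------------------------------------------

DISEASE_GENES = [
    "ABCA4", "USH2A", "KIAA1549", "RPE65", "PRCD", "RHO", "CNGB1",
    "CRX", "PDE6B", "RPGR", "BEST1", "NPHP4",
]


def write_bundle(
    cfg: SimulationConfig, outdir: str | os.PathLike, force: bool = False
) -> dict:
    """Write the complete synthetic input bundle plus a ground-truth
    manifest; returns the manifest. Refuses to write into a non-empty
    directory unless ``force``."""
    out = Path(outdir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    (out / "panel").mkdir(parents=True, exist_ok=True)

    construct = build_construct(cfg)
    qp = simulate_quartet_and_panel(cfg, construct)
    cohort = simulate_cohort(cfg)
    ct, counts, fluor = simulate_phenotype_tables(cfg)

    contig_lengths = {cfg.contig: cfg.genome_length}
    write_fasta(construct.genome, out / "reference.fa")
    write_transcripts([construct.transcript], out / "transcripts.tsv")
    write_vcf(qp.quartet, out / "quartet.vcf", contig_lengths)
    panel_paths = []
    for j, pm in enumerate(qp.panel):
        p = out / "panel" / f"panel_{j + 1:02d}.vcf"
        write_vcf(pm, p, contig_lengths)
        panel_paths.append(str(p.relative_to(out)))
    write_pedigree(qp.pedigree, out / "pedigree.tsv")
    cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    ct.to_csv(out / "ct.tsv", sep="\t", index=False)
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    fluor.to_csv(out / "fluor.tsv", sep="\t", index=False)
    with open(out / "disease_genes.txt", "w") as fh:
        fh.write("\n".join(DISEASE_GENES) + "\n")

    rng = _rng(cfg, 5)
    with open(out / "scores.tsv", "w") as fh:
        fh.write("variant_id\tgene\tkind\tpolyphen2\tprovean\n")
        fh.write(f"causal\t{cfg.gene}\tframeshift\tNA\tNA\n")
        for vid in sorted(qp.nuisance_labels):
            pp2 = round(float(rng.uniform(0, 1)), 3)
            pv = round(float(rng.uniform(-6, 1)), 3)
            fh.write(f"{vid}\tGENE\tmissense\t{pp2}\t{pv}\n")

    manifest = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "causal": {
            "contig": qp.causal.contig,
            "pos": qp.causal.pos,
            "ref": qp.causal.ref,
            "alt": qp.causal.alt,
            "id": qp.causal.id,
            "gene": cfg.gene,
            "expected_c_name": f"c.{cfg.repeat_run_end}insC",
            "expected_stop_codon": cfg.frameshift_stop_codon,
            "expected_mut_length": cfg.frameshift_stop_codon - 1,
            "expected_wt_length": cfg.cds_codons,
        },
        "nuisance": [
            {"id": vid, "violates": label, "eliminated_at": NUISANCE_STAGE[label]}
            for vid, label in sorted(qp.nuisance_labels.items())
        ],
        "planted_effects": {
            "fold_het": cfg.fold_het,
            "fold_affected": cfg.fold_affected,
            "onl_reduction_percent": 100 * cfg.onl_reduction,
            "fluor_contrast": cfg.fluor_contrast,
        },
        "files": {
            "reference": "reference.fa",
            "transcripts": "transcripts.tsv",
            "quartet_vcf": "quartet.vcf",
            "panel_vcfs": panel_paths,
            "pedigree": "pedigree.tsv",
            "cohort": "cohort.tsv",
            "scores": "scores.tsv",
            "disease_genes": "disease_genes.txt",
            "ct": "ct.tsv",
            "counts": "counts.tsv",
            "fluorescence": "fluor.tsv",
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
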