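"""Candidate prioritization: effect-score classification, disease-gene
intersection, and genotype-phenotype concordance.

PolyPhen-2 and PROVEAN scores are *inputs* (computed upstream by those
tools); this module only bands them. The default bands are the published
tool conventions: PolyPhen-2 HumDiv calls >= 0.908 "probably damaging" and
< 0.446 "benign"; PROVEAN's default deleteriousness cutoff is -2.5 (more
negative = more damaging). Frameshift and stop-gain variants are damaging
by rule regardless of scores (the predictors do not score them).

The concordance test applies a full-penetrance autosomal-recessive model:
an affected individual must be homozygous for the candidate allele; an
unaffected individual must be heterozygous or homozygous reference.
"""

from __future__ import annotations

import csv
import os
import warnings
from dataclasses import dataclass

import pandas as pd

#: Default score bands (configurable in every entry point).
PROVEAN_CUTOFF = -2.5
PP2_DAMAGING = 0.908
PP2_BENIGN = 0.446

_GT_CLASS = {
    "0/0": "hom_ref", "0|0": "hom_ref", "ref/ref": "hom_ref", "hom_ref": "hom_ref",
    "0/1": "het", "1/0": "het", "0|1": "het", "1|0": "het",
    "ref/alt": "het", "het": "het",
    "1/1": "hom_alt", "1|1": "hom_alt", "alt/alt": "hom_alt", "hom_alt": "hom_alt",
    "./.": "missing", ".|.": "missing", ".": "missing", "missing": "missing",
}


@dataclass(frozen=True)
class EffectScores:
    """Per-variant predictor scores; either may be absent (e.g. for
    frameshifts, which the missense predictors do not score)."""

    variant_id: str
    polyphen2: float | None = None
    provean: float | None = None
    kind: str | None = None  # consequence kind, if known (frameshift, ...)

    def __post_init__(self) -> None:
        if self.polyphen2 is not None and not 0.0 <= self.polyphen2 <= 1.0:
            raise ValueError(f"polyphen2 must be in [0, 1], got {self.polyphen2}")


def classify_effect(
    s: EffectScores,
    provean_cutoff: float = PROVEAN_CUTOFF,
    pp2_damaging: float = PP2_DAMAGING,
    pp2_benign: float = PP2_BENIGN,
) -> str:
    """Band a variant as ``damaging``, ``neutral`` or ``indeterminate``.

    With both scores present: damaging iff PROVEAN <= cutoff AND
    PolyPhen-2 >= the probably-damaging band; neutral iff PROVEAN > cutoff
    AND PolyPhen-2 < the benign band; anything else is indeterminate. With
    one score present that tool's own call applies. Frameshift/stop-gain
    variants are damaging by rule.
    """
    if s.kind in ("frameshift", "stop_gained", "start_lost"):
        return "damaging"
    pp, pv = s.polyphen2, s.provean
    if pp is None and pv is None:
        warnings.warn(
            f"{s.variant_id}: no effect scores available; indeterminate",
            stacklevel=2,
        )
        return "indeterminate"
    if pp is not None and pv is not None:
        if pv <= provean_cutoff and pp >= pp2_damaging:
            return "damaging"
        if pv > provean_cutoff and pp < pp2_benign:
            return "neutral"
        return "indeterminate"
    if pv is not None:
        return "damaging" if pv <= provean_cutoff else "neutral"
    if pp >= pp2_damaging:
        return "damaging"
    if pp < pp2_benign:
        return "neutral"
    return "indeterminate"


def read_scores(path: str | os.PathLike) -> dict[str, EffectScores]:
    """Read a tab-delimited score table with columns
    ``variant_id  gene  kind  polyphen2  provean`` ('NA'/'.' = absent)."""

    def _num(x: str) -> float | None:
        return None if x in ("", "NA", "na", ".", "None") else float(x)

    scores = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            scores[row["variant_id"]] = EffectScores(
                row["variant_id"],
                _num(row.get("polyphen2", "NA")),
                _num(row.get("provean", "NA")),
                row.get("kind") or None,
            )
    return scores


# -- disease-gene intersection --------------------------------------------


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [
            line.strip().upper()
            for line in fh
            if line.strip() and not line.startswith("#")
        ]


def intersect_disease_genes(
    candidates: list[str], disease_genes: list[str]
) -> list[str]:
    """Candidates present in the disease list, input order preserved,
    case-insensitive, duplicates collapsed to first occurrence."""
    listed = {g.upper() for g in disease_genes}
    out, seen = [], set()
    for g in candidates:
        gu = g.upper()
        if gu in listed and gu not in seen:
            out.append(g)
            seen.add(gu)
    return out


# -- concordance ----------------------------------------------------------


@dataclass(frozen=True)
class DogRecord:
    id: str
    phenotype: str
    genotype: str  # hom_ref / het / hom_alt / missing
    concordant: bool | None  # None = excluded (missing data)


@dataclass
class ConcordanceResult:
    """Per-individual concordance under the full-penetrance recessive
    model, with totals. ``concordant + discordant`` equals the number of
    individuals with a called genotype and a known phenotype."""

    records: list[DogRecord]
    concordant: int
    discordant: int

    @property
    def discordant_ids(self) -> list[str]:
        return [r.id for r in self.records if r.concordant is False]

    def to_dict(self) -> dict:
        return {
            "concordant": self.concordant,
            "discordant": self.discordant,
            "discordant_ids": self.discordant_ids,
            "n_evaluated": self.concordant + self.discordant,
        }


def _genotype_class(gt: str) -> str:
    try:
        return _GT_CLASS[gt.strip()]
    except KeyError:
        raise ValueError(f"unrecognized genotype {gt!r}") from None


def concordance_test(cohort: pd.DataFrame, variant_id: str | None = None) -> ConcordanceResult:
    """Test each individual's genotype against its phenotype.

    ``cohort`` needs columns ``dog_id``, ``phenotype`` (affected/
    unaffected/unknown) and ``genotype`` (VCF-style ``0/0``, ``0/1``,
    ``1/1``, ``./.`` or the words hom_ref/het/hom_alt/missing), giving the
    genotype at the candidate variant. Affected individuals are concordant
    iff homozygous-alternate; unaffected iff heterozygous or
    homozygous-reference. Unknown phenotypes and missing genotypes are
    excluded with a warning and do not enter the totals.
    """
    records: list[DogRecord] = []
    concordant = discordant = 0
    for row in cohort.itertuples(index=False):
        gclass = _genotype_class(str(row.genotype))
        phenotype = str(row.phenotype).strip().lower()
        if phenotype not in ("affected", "unaffected") or gclass == "missing":
            if phenotype not in ("affected", "unaffected"):
                warnings.warn(
                    f"{row.dog_id}: unknown phenotype {row.phenotype!r}; excluded",
                    stacklevel=2,
                )
            records.append(DogRecord(str(row.dog_id), phenotype, gclass, None))
            continue
        if phenotype == "affected":
            ok = gclass == "hom_alt"
        else:
            ok = gclass in ("het", "hom_ref")
        records.append(DogRecord(str(row.dog_id), phenotype, gclass, ok))
        if ok:
            concordant += 1
        else:
            discordant += 1
    return ConcordanceResult(records, concordant, discordant)


def load_cohort(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-delimited cohort table (dog_id, phenotype, genotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"dog_id", "phenotype", "genotype"}
    if not required <= set(df.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    return df
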