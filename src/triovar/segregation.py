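"""Trio-based autosomal-recessive filtering cascade.

The discovery cascade mirrors a family-quartet design: two unaffected
parents and two affected offspring define two trios sharing the same sire
and dam. Per trio, a variant is consistent with autosomal-recessive (AR)
inheritance when the affected offspring is homozygous for the alternate
allele and *both* parents are heterozygous — unaffected parents of an
affected child are obligate carriers under full penetrance, so a
homozygous-reference parent is non-Mendelian for a hom-alt offspring and a
homozygous-alternate parent would itself be affected. Variants passing
both trios are then screened against a panel of additional genomes and
kept only if never observed *homozygous* there (heterozygous panel
carriers do not exclude: a recessive allele is expected to segregate in
carriers).

Exonic/nonsynonymous restriction is driven by per-variant annotation flags
supplied on input (annotation itself is upstream of this package).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ConsistencyError
from .variants import MISSING, GenotypeMatrix

#: Contig names treated as autosomes are anything NOT in this set.
DEFAULT_SEX_CONTIGS = frozenset(
    {"X", "Y", "chrX", "chrY", "ChrX", "ChrY", "chrM", "MT"}
)


@dataclass(frozen=True)
class PedigreeSample:
    id: str
    sire: str | None
    dam: str | None
    sex: str
    phenotype: str  # affected / unaffected / unknown
    role: str = ""


@dataclass
class Pedigree:
    samples: list[PedigreeSample]

    def __post_init__(self) -> None:
        ids = {s.id for s in self.samples}
        if len(ids) != len(self.samples):
            raise ConfigurationError("duplicate sample ids in pedigree")
        by_id = {s.id: s for s in self.samples}
        for s in self.samples:
            for parent in (s.sire, s.dam):
                if parent is not None and parent not in ids:
                    raise ConfigurationError(
                        f"{s.id}: parent {parent!r} not in pedigree"
                    )
        for s in self.samples:  # no sample may be its own ancestor
            seen: set[str] = set()
            stack = [p for p in (s.sire, s.dam) if p]
            while stack:
                p = stack.pop()
                if p == s.id:
                    raise ConfigurationError(f"{s.id} is its own ancestor")
                if p in seen:
                    continue
                seen.add(p)
                ps = by_id[p]
                stack.extend(q for q in (ps.sire, ps.dam) if q)

    def __getitem__(self, sample_id: str) -> PedigreeSample:
        for s in self.samples:
            if s.id == sample_id:
                return s
        raise KeyError(sample_id)


@dataclass(frozen=True)
class Trio:
    """A sire/dam/affected-offspring filtering unit."""

    sire: str
    dam: str
    offspring: str

    def __post_init__(self) -> None:
        if len({self.sire, self.dam, self.offspring}) != 3:
            raise ConfigurationError("trio members must be distinct")


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    """Read a 6-column tab-delimited pedigree:
    ``id  sire  dam  sex  phenotype  role`` ('.' or empty = unknown parent).
    """
    samples = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            sid, sire, dam, sex, phenotype = row[:5]
            role = row[5] if len(row) > 5 else ""
            samples.append(
                PedigreeSample(
                    sid,
                    sire if sire not in (".", "", "0") else None,
                    dam if dam not in (".", "", "0") else None,
                    sex,
                    phenotype,
                    role,
                )
            )
    return Pedigree(samples)


def write_pedigree(ped: Pedigree, path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for s in ped.samples:
            writer.writerow(
                [s.id, s.sire or ".", s.dam or ".", s.sex, s.phenotype, s.role]
            )


def trios_from_pedigree(ped: Pedigree) -> list[Trio]:
    """One trio per affected sample with both parents in the pedigree."""
    return [
        Trio(s.sire, s.dam, s.id)
        for s in ped.samples
        if s.phenotype == "affected" and s.sire and s.dam
    ]


# -- filters --------------------------------------------------------------


def autosomal_filter(
    gm: GenotypeMatrix, sex_contigs: frozenset[str] = DEFAULT_SEX_CONTIGS
) -> GenotypeMatrix:
    """Drop variants on sex chromosomes / mitochondria by contig name."""
    return gm.subset(
        i for i, v in enumerate(gm.variants) if v.contig not in sex_contigs
    )


def exonic_filter(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep variants flagged ``exonic`` in their annotations."""
    return gm.subset(i for i in range(gm.n_variants) if gm.info[i].get("exonic"))


def trio_ar_filter(
    gm: GenotypeMatrix, trio: Trio, permissive_missing: bool = False
) -> GenotypeMatrix:
    """Retain variants where the affected offspring is hom-alt and both
    parents are heterozygous.

    With the default ``permissive_missing=False``, any missing call among
    the three samples drops the variant (conservative for discovery); the
    permissive mode lets missing calls pass as compatible.
    """
    try:
        js, jd, jo = (gm.sample_index(s) for s in (trio.sire, trio.dam, trio.offspring))
    except KeyError as exc:
        raise ConfigurationError(f"trio sample not in matrix: {exc}") from exc
    sire, dam, off = gm.calls[:, js], gm.calls[:, jd], gm.calls[:, jo]
    if permissive_missing:
        ok = (
            ((off == 2) | (off == MISSING))
            & ((sire == 1) | (sire == MISSING))
            & ((dam == 1) | (dam == MISSING))
            & ~((off == MISSING) & (sire == MISSING) & (dam == MISSING))
        )
    else:
        ok = (off == 2) & (sire == 1) & (dam == 1)
    return gm.subset(np.flatnonzero(ok))


def intersect_trios(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Variants present in both subsets, in ``a``'s order."""
    keys_b = {v.key for v in b.variants}
    return a.subset(i for i, v in enumerate(a.variants) if v.key in keys_b)


def panel_privacy_filter(
    s: GenotypeMatrix, panel: GenotypeMatrix | list[GenotypeMatrix]
) -> GenotypeMatrix:
    """Drop variants observed homozygous-alternate in any panel genome.

    A variant absent from the panel records counts as not homozygous;
    heterozygous panel carriers never cause exclusion.
    """
    matrices = panel if isinstance(panel, list) else [panel]
    keep = []
    for i, v in enumerate(s.variants):
        hom_somewhere = False
        for pm in matrices:
            j = pm.index_of(v)
            if j is not None and bool((pm.calls[j, :] == 2).any()):
                hom_somewhere = True
                break
        if not hom_somewhere:
            keep.append(i)
    return s.subset(keep)


def class_filter(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Final candidate classes: indels plus nonsynonymous SNVs (synonymous
    SNVs are not disease candidates under a protein-altering model)."""
    return gm.subset(
        i
        for i, v in enumerate(gm.variants)
        if v.is_indel or gm.info[i].get("nonsynonymous")
    )


# -- cascade summary ------------------------------------------------------

#: Canonical stage order; each later stage must be a subset of `exonic`
#: (the two trio stages are parallel branches from `exonic`).
STAGE_ORDER = ["total", "exonic", "ar_trio1", "ar_trio2", "shared", "private", "candidates"]


@dataclass
class FilterSummary:
    """Per-stage variant counts of the discovery cascade, split by class."""

    stages: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        return [
            {"stage": name, **counts} for name, counts in self.stages.items()
        ]

    def write_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["stage", "total", "snv", "indel", "nonsynonymous_snv"])
            for name, c in self.stages.items():
                writer.writerow(
                    [name, c["total"], c["snv"], c["indel"], c["nonsynonymous_snv"]]
                )


def _stage_counts(gm: GenotypeMatrix) -> dict[str, int]:
    snv = sum(v.is_snv for v in gm.variants)
    indel = sum(v.is_indel for v in gm.variants)
    nonsyn = sum(
        1
        for i, v in enumerate(gm.variants)
        if v.is_snv and gm.info[i].get("nonsynonymous")
    )
    return {
        "total": gm.n_variants,
        "snv": snv,
        "indel": indel,
        "nonsynonymous_snv": nonsyn,
    }


def summarize_cascade(stages: list[tuple[str, GenotypeMatrix]]) -> FilterSummary:
    """Tabulate stage counts and enforce cascade monotonicity.

    ``stages`` is an ordered list of (stage name, matrix). The chain
    total >= exonic >= each trio >= shared >= private >= candidates must be
    non-increasing in every class; a violation raises
    :class:`~triovar.errors.ConsistencyError`.
    """
    summary = FilterSummary({name: _stage_counts(gm) for name, gm in stages})
    counts = summary.stages
    chain_parent = {
        "exonic": "total",
        "ar_trio1": "exonic",
        "ar_trio2": "exonic",
        "shared": "ar_trio1",
        "private": "shared",
        "candidates": "private",
    }
    for stage, parent in chain_parent.items():
        if stage in counts and parent in counts:
            for cls in ("total", "snv", "indel", "nonsynonymous_snv"):
                if counts[stage][cls] > counts[parent][cls]:
                    raise ConsistencyError(
                        f"non-monotone cascade: {stage}.{cls} "
                        f"({counts[stage][cls]}) > {parent}.{cls} "
                        f"({counts[parent][cls]})"
                    )
    if "shared" in counts and "ar_trio2" in counts:
        if counts["shared"]["total"] > counts["ar_trio2"]["total"]:
            raise ConsistencyError("shared stage exceeds ar_trio2")
    return summary
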