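"""End-to-end discovery pipeline: generate -> filter -> annotate ->
prioritize -> report.

:func:`run_discovery` chains the module operations exactly as they exist
in the library (the pipeline adds orchestration and provenance, never its
own filtering logic), producing a :class:`RunReport` that is byte-for-byte
reproducible given the same inputs and configuration (timestamps are
excluded from the payload hash).
"""

from __future__ import annotations

import dataclasses
import glob as _glob
import hashlib
import json
import os
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError
from .prioritize import (
    PP2_BENIGN,
    PP2_DAMAGING,
    PROVEAN_CUTOFF,
    EffectScores,
    classify_effect,
    concordance_test,
    intersect_disease_genes,
    load_cohort,
    read_gene_list,
    read_scores,
)
from .segregation import (
    autosomal_filter,
    class_filter,
    exonic_filter,
    intersect_trios,
    panel_privacy_filter,
    read_pedigree,
    summarize_cascade,
    trio_ar_filter,
    trios_from_pedigree,
)
from .simulate import SimulationConfig, write_bundle
from .transcripts import call_consequence, project_to_cds, read_transcripts
from .variants import normalize_variant, parse_vcf, read_fasta


@dataclass
class PipelineConfig:
    """Inputs, toggles and thresholds of one discovery run."""

    vcf: str
    pedigree: str
    transcripts: str | None = None
    reference: str | None = None
    panel: list[str] = field(default_factory=list)
    scores: str | None = None
    disease_genes: str | None = None
    cohort: str | None = None
    out_dir: str | None = None
    # cascade toggles
    autosomes_only: bool = True
    exonic_filter: bool = True
    panel_filter: bool = True
    class_filter: bool = True
    # thresholds
    provean_cutoff: float = PROVEAN_CUTOFF
    pp2_damaging: float = PP2_DAMAGING
    pp2_benign: float = PP2_BENIGN

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")

        def resolve(p):
            return str(base / p) if p and not os.path.isabs(p) else p

        panel = raw.get("panel", [])
        if isinstance(panel, str):
            panel = sorted(_glob.glob(resolve(panel)))
        else:
            panel = [resolve(p) for p in panel]
        kwargs = dict(raw)
        for key in ("vcf", "pedigree", "transcripts", "reference", "scores",
                    "disease_genes", "cohort", "out_dir"):
            if kwargs.get(key):
                kwargs[key] = resolve(kwargs[key])
        kwargs["panel"] = panel
        return cls(**kwargs)

    def canonical(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Machine-readable result of a discovery run."""

    summary: dict
    candidates: list[dict]
    concordance: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "summary": self.summary,
            "candidates": self.candidates,
            "concordance": self.concordance,
            "provenance": self.provenance,
        }

    def payload_hash(self) -> str:
        payload = self.to_dict()
        payload["provenance"] = {
            k: v for k, v in payload["provenance"].items() if k != "created"
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def write_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.canonical(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_discovery(cfg: PipelineConfig) -> RunReport:
    """Execute the full filtering cascade and prioritization.

    Cascade: parse quartet VCF -> (autosomes) -> exonic flag -> AR filter
    per trio -> intersection of trios -> panel privacy -> candidate classes
    (indels + nonsynonymous SNVs) -> consequence annotation, effect-score
    classification, disease-gene intersection, and (optionally) cohort
    concordance.
    """
    gm = parse_vcf(cfg.vcf)
    pedigree = read_pedigree(cfg.pedigree)
    trios = sorted(trios_from_pedigree(pedigree), key=lambda t: t.offspring)
    if not trios:
        raise ConfigurationError("pedigree defines no affected-offspring trio")

    stages = [("total", gm)]
    current = autosomal_filter(gm) if cfg.autosomes_only else gm
    if cfg.exonic_filter:
        current = exonic_filter(current)
    stages.append(("exonic", current))

    trio_subsets = []
    for i, trio in enumerate(trios, start=1):
        sub = trio_ar_filter(current, trio)
        trio_subsets.append(sub)
        stages.append((f"ar_trio{i}", sub))
    shared = trio_subsets[0]
    for sub in trio_subsets[1:]:
        shared = intersect_trios(shared, sub)
    stages.append(("shared", shared))

    if cfg.panel_filter and cfg.panel:
        panel = [parse_vcf(p) for p in cfg.panel]
        private = panel_privacy_filter(shared, panel)
    else:
        private = shared
    stages.append(("private", private))

    candidates_gm = class_filter(private) if cfg.class_filter else private
    stages.append(("candidates", candidates_gm))
    summary = summarize_cascade(stages)

    genome = read_fasta(cfg.reference) if cfg.reference else None
    models = read_transcripts(cfg.transcripts) if cfg.transcripts else []
    scores = read_scores(cfg.scores) if cfg.scores else {}
    disease = read_gene_list(cfg.disease_genes) if cfg.disease_genes else []

    candidates = []
    for i, v in enumerate(candidates_gm.variants):
        info = candidates_gm.info[i]
        entry: dict = {
            "variant": {"contig": v.contig, "pos": v.pos, "ref": v.ref,
                        "alt": v.alt, "id": v.id},
            "gene": info.get("gene"),
            "vclass": v.vclass,
        }
        consequence = None
        if genome is not None:
            vn = normalize_variant(v, genome[v.contig]) if v.contig in genome else v
            entry["variant_normalized"] = {
                "contig": vn.contig, "pos": vn.pos, "ref": vn.ref, "alt": vn.alt
            }
            for tm in models:
                cv = project_to_cds(vn, tm, genome)
                if cv is not None:
                    consequence = call_consequence(cv, tm, genome)
                    entry["gene"] = tm.gene
                    entry["c_name"] = cv.c_name
                    entry["p_name"] = consequence.p_name
                    entry["consequence"] = dataclasses.asdict(consequence)
                    break
        kind = consequence.kind if consequence else None
        s = scores.get(v.id or "", None)
        eff = EffectScores(
            v.id or str(v),
            s.polyphen2 if s else None,
            s.provean if s else None,
            kind or (s.kind if s else None),
        )
        if eff.polyphen2 is None and eff.provean is None and eff.kind not in (
            "frameshift", "stop_gained", "start_lost"
        ):
            entry["effect_label"] = "indeterminate"
        else:
            entry["effect_label"] = classify_effect(
                eff, cfg.provean_cutoff, cfg.pp2_damaging, cfg.pp2_benign
            )
        candidates.append(entry)

    if disease:
        genes = [c["gene"] for c in candidates if c.get("gene")]
        listed = set(g.upper() for g in intersect_disease_genes(genes, disease))
        for c in candidates:
            c["in_disease_list"] = bool(c.get("gene") and c["gene"].upper() in listed)

    concordance = None
    if cfg.cohort:
        concordance = concordance_test(load_cohort(cfg.cohort)).to_dict()

    report = RunReport(
        summary={"stages": summary.stages},
        candidates=candidates,
        concordance=concordance,
        provenance={
            "config": cfg.canonical(),
            "config_sha256": _config_hash(cfg),
            "triovar_version": __version__,
            "created": datetime.now(timezone.utc).isoformat(),
        },
    )
    if cfg.out_dir:
        outdir = Path(cfg.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.write_json(outdir / "report.json")
        summary.write_tsv(outdir / "cascade.tsv")
    return report


def run_generate(
    cfg: SimulationConfig, outdir: str | os.PathLike, force: bool = False
) -> dict:
    """Write the synthetic bundle plus a ready-to-run discover config."""
    manifest = write_bundle(cfg, outdir, force=force)
    files = manifest["files"]
    discover_cfg = {
        "vcf": files["quartet_vcf"],
        "pedigree": files["pedigree"],
        "transcripts": files["transcripts"],
        "reference": files["reference"],
        "panel": files["panel_vcfs"],
        "scores": files["scores"],
        "disease_genes": files["disease_genes"],
        "cohort": files["cohort"],
    }
    with open(Path(outdir) / "config.yaml", "w") as fh:
        yaml.safe_dump(discover_cfg, fh, sort_keys=True)
    return manifest
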