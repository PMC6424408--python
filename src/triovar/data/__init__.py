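"""Packaged fixture tables.

``s4_cohort_synthetic.tsv`` is a *synthetic* reconstruction of the
22-dog validation cohort: the published result reports only the summary
(eight clinically affected dogs, all homozygous for the candidate
insertion; fourteen unaffected dogs, each heterozygous or homozygous
wild type) plus a handful of named individuals, so per-dog genotypes here
are filled in consistently with that summary rather than copied from the
original supplementary table.
"""

from importlib import resources
from pathlib import Path


def s4_cohort_path() -> Path:
    """Path to the synthetic validation-cohort genotype/phenotype table."""
    return Path(resources.files(__package__) / "s4_cohort_synthetic.tsv")
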