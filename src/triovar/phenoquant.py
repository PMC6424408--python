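"""Molecular and cellular quantification formulas.

Small, exact formula layer for the phenotype read-outs that accompany a
loss-of-function retinal variant: relative expression by the delta-delta-Ct
(2^-ddCt) method with GAPDH-style reference normalization, rod-photoreceptor
inference by subtracting PNA-identified cones from outer-nuclear-layer
(ONL) nuclei, background-corrected autofluorescence intensity, and
percent-reduction summaries between genotype groups. Amplification
efficiency is fixed at the ideal 2.0 per cycle; inferential statistics on
the group summaries are left to standard routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError


@dataclass(frozen=True)
class QpcrRecord:
    sample: str
    gene: str  # 'target' or 'reference'
    amplicon: str
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("Ct must be positive")


@dataclass(frozen=True)
class FieldCounts:
    image_id: str
    onl_nuclei: int
    inl_nuclei: int
    cone_count: int
    region_width_um: float = 67.0

    def __post_init__(self) -> None:
        if min(self.onl_nuclei, self.inl_nuclei, self.cone_count) < 0:
            raise ValueError("counts must be non-negative")
        if self.cone_count > self.onl_nuclei:
            raise ConsistencyError(
                f"{self.image_id}: cone count {self.cone_count} exceeds ONL "
                f"nuclei {self.onl_nuclei}"
            )


@dataclass(frozen=True)
class FluorescenceMeasure:
    image_id: str
    region_mean: float
    background_mean: float

    def __post_init__(self) -> None:
        if self.region_mean < 0 or self.background_mean < 0:
            raise ValueError("intensities must be non-negative")


def relative_expression(
    target_ct: float,
    reference_ct: float,
    calibrator_target_ct: float,
    calibrator_reference_ct: float,
) -> float:
    """Fold expression by 2^-ddCt.

    dCt = Ct_target - Ct_reference per sample; ddCt = dCt_sample -
    dCt_calibrator; the calibrator sample therefore returns exactly 1.0 and
    each extra cycle of ddCt halves the fold.
    """
    dct_sample = target_ct - reference_ct
    dct_cal = calibrator_target_ct - calibrator_reference_ct
    return float(2.0 ** -(dct_sample - dct_cal))


def infer_rod_count(fc: FieldCounts) -> int:
    """Rods = ONL nuclei minus PNA-identified cones (in a degenerate
    retina where cones are absent, all ONL nuclei are rods)."""
    return fc.onl_nuclei - fc.cone_count


def corrected_autofluorescence(m: FluorescenceMeasure) -> float:
    """Region mean intensity minus adjacent-background mean. May be
    negative when the region is dimmer than background."""
    return m.region_mean - m.background_mean


def percent_reduction(mean_a: float, mean_b: float) -> float:
    """Percent reduction of ``mean_a`` relative to reference ``mean_b``:
    ``100 * (mean_b - mean_a) / mean_b``."""
    if mean_b == 0:
        raise ZeroDivisionError("reference group mean is zero")
    return 100.0 * (mean_b - mean_a) / mean_b


def percent_remaining(mean_a: float, mean_b: float) -> float:
    """``100 * mean_a / mean_b``; complements :func:`percent_reduction`."""
    if mean_b == 0:
        raise ZeroDivisionError("reference group mean is zero")
    return 100.0 * mean_a / mean_b


# -- table-level summaries ------------------------------------------------


def expression_table(ct: pd.DataFrame, calibrator_group: str = "wild_type") -> pd.DataFrame:
    """Per-sample 2^-ddCt folds from a replicate Ct table.

    Expects columns ``sample, group, gene (target/reference), amplicon,
    replicate, ct``. Replicate Cts are averaged per (sample, gene,
    amplicon); the calibrator dCt per amplicon is the mean dCt of samples
    in ``calibrator_group``.
    """
    ref = ct[ct["gene"] == "reference"].groupby("sample")["ct"].mean()
    tgt = (
        ct[ct["gene"] == "target"]
        .groupby(["sample", "group", "amplicon"])["ct"]
        .mean()
        .reset_index()
    )
    if ref.empty or tgt.empty:
        raise ValueError("ct table must contain 'target' and 'reference' genes")
    tgt["dct"] = tgt["ct"] - tgt["sample"].map(ref)
    cal = tgt[tgt["group"] == calibrator_group].groupby("amplicon")["dct"].mean()
    if cal.empty:
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    tgt["fold"] = 2.0 ** -(tgt["dct"] - tgt["amplicon"].map(cal))
    return tgt[["sample", "group", "amplicon", "fold"]]


def group_mean_sd(values: pd.Series) -> tuple[float, float]:
    """Mean and SD over technical replicates (ddof=1; SD 0 for n=1)."""
    v = np.asarray(values, dtype=float)
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    return float(v.mean()), sd


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Group means/SD of ONL, INL, cone and inferred rod counts.

    Expects columns ``image_id, group, onl_nuclei, inl_nuclei, cone_count``.
    """
    df = counts.copy()
    df["rod_count"] = [
        infer_rod_count(
            FieldCounts(str(r.image_id), int(r.onl_nuclei), int(r.inl_nuclei), int(r.cone_count))
        )
        for r in df.itertuples(index=False)
    ]
    return df.groupby("group")[["onl_nuclei", "inl_nuclei", "cone_count", "rod_count"]].agg(
        ["mean", "std"]
    )


def summarize_fluorescence(fluor: pd.DataFrame) -> pd.DataFrame:
    """Group mean/SD of background-corrected intensity.

    Expects columns ``image_id, group, region_mean, background_mean``.
    """
    df = fluor.copy()
    df["corrected"] = df["region_mean"] - df["background_mean"]
    return df.groupby("group")["corrected"].agg(["mean", "std"])
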