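"""Marker and sample retention filters with an auditable stage report.

Stages run in a fixed order: (1) markers with too much missing data,
(2) samples with too much missing data (recomputed on the surviving
markers), (3) monomorphic markers, (4) markers below the minor-allele-
frequency floor (computed on the surviving samples, missing calls
excluded).  Both missing-rate filters drop at ``>= threshold``
("10% or more").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PanelError

__all__ = ["QCReport", "filter_panel", "missing_summary"]


@dataclass
class QCReport:
    """Stage-by-stage audit of panel filtering."""

    stage_names: list = field(default_factory=list)
    markers_in: list = field(default_factory=list)
    markers_out: list = field(default_factory=list)
    samples_in: list = field(default_factory=list)
    samples_out: list = field(default_factory=list)
    monomorphic_removed: int = 0
    thresholds: dict = field(default_factory=dict)

    def record(self, name, m_in, m_out, s_in, s_out):
        self.stage_names.append(name)
        self.markers_in.append(m_in)
        self.markers_out.append(m_out)
        self.samples_in.append(s_in)
        self.samples_out.append(s_out)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": self.stage_names,
                "markers_in": self.markers_in,
                "markers_out": self.markers_out,
                "samples_in": self.samples_in,
                "samples_out": self.samples_out,
            }
        )

    def to_dict(self) -> dict:
        d = self.as_frame().to_dict(orient="list")
        d["monomorphic_removed"] = self.monomorphic_removed
        d["thresholds"] = self.thresholds
        return d


def _maf(gm: GenotypeMatrix) -> np.ndarray:
    called = (~gm.missing).sum(axis=0)
    alt = np.where(gm.missing, 0, gm.calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * called)
    p = np.where(called == 0, np.nan, p)
    return np.minimum(p, 1.0 - p)


def filter_panel(
    gm: GenotypeMatrix,
    max_marker_missing: float = 0.10,
    max_sample_missing: float = 0.10,
    min_maf: float = 0.05,
):
    """Apply the retention rules; return ``(filtered_matrix, QCReport)``.

    Raises
    ------
    PanelError
        If any stage empties the panel (the offending stage is named).
    """
    for name, value in (
        ("max_marker_missing", max_marker_missing),
        ("max_sample_missing", max_sample_missing),
        ("min_maf", min_maf),
    ):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    report = QCReport(
        thresholds={
            "max_marker_missing": max_marker_missing,
            "max_sample_missing": max_sample_missing,
            "min_maf": min_maf,
        }
    )

    def check(g, stage):
        if g.n_loci == 0 or g.n_samples == 0:
            raise PanelError(f"panel empty after stage {stage!r}")

    # 1: marker missing rate
    frac = gm.missing.mean(axis=0)
    keep = frac < max_marker_missing
    out = gm.subset(loci=keep)
    report.record("marker_missing", gm.n_loci, out.n_loci, gm.n_samples, out.n_samples)
    check(out, "marker_missing")

    # 2: sample missing rate on surviving markers
    frac = out.missing.mean(axis=1)
    keep = frac < max_sample_missing
    nxt = out.subset(samples=keep)
    report.record("sample_missing", out.n_loci, nxt.n_loci, out.n_samples, nxt.n_samples)
    check(nxt, "sample_missing")
    out = nxt

    # 3: monomorphic markers
    maf = _maf(out)
    keep = maf > 0
    keep &= ~np.isnan(maf)
    nxt = out.subset(loci=keep)
    report.monomorphic_removed = out.n_loci - nxt.n_loci
    report.record("monomorphic", out.n_loci, nxt.n_loci, out.n_samples, nxt.n_samples)
    check(nxt, "monomorphic")
    out = nxt

    # 4: MAF floor
    maf = _maf(out)
    keep = maf >= min_maf
    nxt = out.subset(loci=keep)
    report.record("maf", out.n_loci, nxt.n_loci, out.n_samples, nxt.n_samples)
    check(nxt, "maf")
    return nxt, report


def missing_summary(gm: GenotypeMatrix) -> dict:
    """Per-marker and per-sample missing fractions with mean/min/max."""
    if gm.n_loci == 0 or gm.n_samples == 0:
        raise PanelError("empty matrix")
    per_marker = pd.Series(gm.missing.mean(axis=0), index=gm.locus_ids)
    per_sample = pd.Series(gm.missing.mean(axis=1), index=gm.sample_ids)
    return {
        "per_marker": per_marker,
        "per_sample": per_sample,
        "mean": float(gm.missing.mean()),
        "marker_range": (float(per_marker.min()), float(per_marker.max())),
        "sample_range": (float(per_sample.min()), float(per_sample.max())),
    }
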