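"""Per-locus marker statistics and probability-of-identity power curves.

The headline identity statistic is PIDsib: the probability that two full
siblings drawn at random from a population share a multilocus genotype.
It is the conservative choice for duplicate detection in germplasm,
where close relatives are common.  Per locus (biallelic, frequencies
p and q = 1 - p):

    PIDsib = 0.25 + 0.5 * (p^2 + q^2) + 0.5 * (p^2 + q^2)^2
             - 0.25 * (p^4 + q^4)

Multilocus PIDsib is the product over loci; the cumulative curve orders
loci most-informative-first (ascending per-locus PIDsib) so the value at
rank k is the power of the best k-locus sub-panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

__all__ = [
    "AlleleFrequencies",
    "PidCurve",
    "allele_frequencies",
    "marker_stats",
    "pid_sib_locus",
    "pid_unrelated_locus",
    "cumulative_pid",
]


@dataclass
class AlleleFrequencies:
    """Alternate-allele frequencies per locus, optionally per population."""

    locus_ids: list
    p_alt: np.ndarray                 # pooled frequencies, shape (L,)
    n_called: np.ndarray              # samples contributing per locus
    by_population: dict = field(default_factory=dict)  # label -> (L,) array

    def __post_init__(self):
        self.p_alt = np.asarray(self.p_alt, dtype=float)
        self.n_called = np.asarray(self.n_called)

    @property
    def populations(self) -> list:
        return list(self.by_population)


@dataclass
class PidCurve:
    """Cumulative probability-of-identity power curve."""

    locus_order: list        # locus ids, most informative first
    per_locus: np.ndarray    # per-locus PIDsib in that order
    cumulative: np.ndarray   # running product
    population: str = None


def _freq(calls: np.ndarray, missing: np.ndarray):
    called = (~missing).sum(axis=0)
    alt = np.where(missing, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * called)
    return np.where(called == 0, np.nan, p), called


def allele_frequencies(gm: GenotypeMatrix, pops=None) -> AlleleFrequencies:
    """Alternate-allele frequency per locus: (n_het + 2 n_homalt) / (2 n_called).

    ``pops`` is an optional per-sample label sequence; per-population
    frequencies are then reported alongside the pooled ones.
    """
    p, called = _freq(gm.calls, gm.missing)
    out = AlleleFrequencies(list(gm.locus_ids), p, called)
    if pops is not None:
        pops = np.asarray(list(pops))
        if len(pops) != gm.n_samples:
            raise ValueError("pops must label every sample")
        for label in pd.unique(pops):
            rows = pops == label
            if not rows.any():
                raise ValueError(f"population {label!r} has no members")
            pk, _ = _freq(gm.calls[rows], gm.missing[rows])
            out.by_population[label] = pk
    return out


def marker_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus MAF, Nei gene diversity H_exp, observed heterozygosity H_obs.

    H_exp is the uncorrected Nei diversity ``1 - p^2 - q^2`` (ceiling 0.5
    for a biallelic locus); H_obs is the fraction of non-missing calls
    that are heterozygous.
    """
    p, called = _freq(gm.calls, gm.missing)
    q = 1.0 - p
    het = ((gm.calls == 1) & ~gm.missing).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_obs = np.where(called > 0, het / called, np.nan)
    return pd.DataFrame(
        {
            "maf": np.minimum(p, q),
            "h_exp": 1.0 - p**2 - q**2,
            "h_obs": h_obs,
            "missing_fraction": gm.missing.mean(axis=0),
        },
        index=pd.Index(gm.locus_ids, name="locus_id"),
    )


def pid_sib_locus(p_alt) -> np.ndarray:
    """Per-locus sibling probability of identity (biallelic)."""
    p = np.asarray(p_alt, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    q = 1.0 - p
    s2 = p**2 + q**2
    s4 = p**4 + q**4
    out = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
    return out if out.ndim else float(out)


def pid_unrelated_locus(p_alt) -> np.ndarray:
    """Per-locus probability of identity for unrelated individuals under HWE."""
    p = np.asarray(p_alt, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    q = 1.0 - p
    out = p**4 + q**4 + (2.0 * p * q) ** 2
    return out if out.ndim else float(out)


def cumulative_pid(
    freqs: AlleleFrequencies, n_loci: int = None, statistic: str = "sib"
):
    """Cumulative PID curve(s), most informative loci first.

    Returns a single :class:`PidCurve` for pooled frequencies, or a dict
    of per-population curves when the input carries population labels.
    """
    fn = pid_sib_locus if statistic == "sib" else pid_unrelated_locus

    def one(p, label=None):
        ok = ~np.isnan(p)
        per = fn(p[ok])
        ids = [lid for lid, k in zip(freqs.locus_ids, ok) if k]
        order = np.argsort(per, kind="stable")
        if n_loci is not None:
            order = order[:n_loci]
        per_sorted = per[order]
        return PidCurve(
            [ids[i] for i in order],
            per_sorted,
            np.cumprod(per_sorted),
            population=label,
        )

    if freqs.by_population:
        return {lab: one(pk, lab) for lab, pk in freqs.by_population.items()}
    return one(freqs.p_alt)
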