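"""Depletion-of-homozygotes test for recessive lethal haplotypes.

A haplotype linked to a recessive lethal allele is never seen homozygous in
live genotyped animals even though its frequency predicts homozygotes. Two
expectations are computed for every zero-homozygote haplotype:

* simple method — random mating: E[hom] = N * C^2 / 4 = N * f^2, with C the
  carrier frequency (carriers / N) and f = C/2 the haplotype frequency;
  the probability of observing zero homozygotes is Phh = (1 - f^2/4)^N under
  the haplotype-frequency convention (the default; see ``phh_simple``), or
  (1 - C^2/4)^N under the carrier-frequency convention.
* mating method — realized matings: each genotyped animal whose sire and
  maternal grandsire are both carriers has probability 1/4 of being a lethal
  homozygote (the maternal grandsire proxies the ungenotyped dam, granddam
  and grandsire allele frequencies taken as equal), so with n such animals
  E[hom] = n/4 and the zero-homozygote probability is 0.75^n.

Candidates must show zero homozygotes, haplotype percentage above 2%, simple
expectation above 1, and both probabilities below 0.6.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .haploscan import (
    HaplotypeCatalog,
    PhasedPanel,
    enumerate_haplotypes,
    plan_segments,
)
from .pedigree import Pedigree

LOG_3_4 = np.log(0.75)


def expected_hom_simple(n_carriers: int, n_genotyped: int) -> float:
    """Random-mating expected homozygote count, N*(C^2)/4 = N*f^2."""
    if n_genotyped <= 0:
        raise ValueError("n_genotyped must be positive")
    if not 0 <= n_carriers <= n_genotyped:
        raise ValueError("n_carriers must lie in [0, n_genotyped]")
    c = n_carriers / n_genotyped
    return n_genotyped * c * c / 4.0


def phh_simple(freq: float, n_genotyped: int, convention: str = "haplotype") -> float:
    """Probability of zero homozygotes among N animals, (1 - freq^2/4)^N.

    The formula is always (1 - freq^2/4)^N, evaluated in log space; the
    ``convention`` flag only records which frequency the caller inserted.
    Published screens insert the haplotype frequency f = carriers/2N (the
    default used by :func:`depletion_report`); the formula's verbal statement
    names the carrier frequency C = 2f, which gives much smaller
    probabilities and is available as convention='carrier' metadata.
    """
    if not 0.0 <= freq <= 1.0:
        raise ValueError("freq must be in [0, 1]")
    if n_genotyped < 0:
        raise ValueError("n_genotyped must be >= 0")
    if convention not in ("haplotype", "carrier"):
        raise ValueError("convention must be 'haplotype' or 'carrier'")
    x2 = freq * freq / 4.0
    if x2 >= 1.0:
        return 0.0
    return float(np.exp(n_genotyped * np.log1p(-x2)))


def phh_mating(n_matings: int) -> float:
    """Zero-homozygote probability under realized carrier matings, 0.75^n."""
    if n_matings < 0:
        raise ValueError("n_matings must be >= 0")
    return float(np.exp(n_matings * LOG_3_4))


def count_carrier_matings(
    ped: Pedigree, carriers, genotyped
) -> int:
    """Number of genotyped animals with carrier sire AND carrier maternal
    grandsire (one unit per progeny); unknown sire or MGS never counts."""
    carrier_set = {str(c) for c in carriers}
    if not carrier_set:
        return 0
    mgs_idx = ped.maternal_grandsire_indices()
    ids = np.asarray(ped.ids)
    count = 0
    for a in genotyped:
        a = str(a)
        if a not in ped:
            continue
        i = ped.index_of(a)
        s = ped.sire_idx[i]
        g = mgs_idx[i]
        if s >= 0 and g >= 0 and ids[s] in carrier_set and ids[g] in carrier_set:
            count += 1
    return count


@dataclass
class DepletionRecord:
    """One zero-homozygote candidate haplotype with both tests applied."""

    haplotype: str
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    n_genotyped: int
    n_carriers: int
    n_homozygotes: int
    n_carrier_matings: int
    phh_simple: float
    phh_mating: float
    passes_filter: bool = False

    @property
    def hap_freq(self) -> float:
        """Haplotype frequency f = carriers / 2N (homozygotes absent)."""
        return self.n_carriers / (2 * self.n_genotyped)

    @property
    def carrier_freq(self) -> float:
        return self.n_carriers / self.n_genotyped

    @property
    def hap_pct(self) -> float:
        return 100.0 * self.hap_freq

    @property
    def exp_hom_simple(self) -> float:
        return expected_hom_simple(self.n_carriers, self.n_genotyped)

    @property
    def exp_hom_mating(self) -> float:
        return self.n_carrier_matings / 4.0


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "haplotype": [r.haplotype for r in records],
            "chrom": [r.chrom for r in records],
            "start_bp": [r.start_bp for r in records],
            "end_bp": [r.end_bp for r in records],
            "length_mb": [(r.end_bp - r.start_bp) / 1e6 for r in records],
            "n_markers": [r.n_markers for r in records],
            "n_carriers": [r.n_carriers for r in records],
            "hap_pct": [r.hap_pct for r in records],
            "exp_hom_simple": [r.exp_hom_simple for r in records],
            "phh_simple": [r.phh_simple for r in records],
            "n_carrier_matings": [r.n_carrier_matings for r in records],
            "exp_hom_mating": [r.exp_hom_mating for r in records],
            "phh_mating": [r.phh_mating for r in records],
            "passes_filter": [r.passes_filter for r in records],
        }
    )


def filter_candidates(
    records,
    min_hap_pct: float = 2.0,
    min_exp_hom: float = 1.0,
    max_phh: float = 0.6,
) -> list:
    """Apply the three-condition candidate filter.

    Keeps records with zero homozygotes, haplotype percentage strictly above
    ``min_hap_pct``, simple expected homozygotes strictly above
    ``min_exp_hom``, and BOTH zero-homozygote probabilities strictly below
    ``max_phh``. Sets ``passes_filter`` on every input record and returns the
    passers sorted by chromosome then start position.
    """
    for r in records:
        r.passes_filter = (
            r.n_homozygotes == 0
            and r.hap_pct > min_hap_pct
            and r.exp_hom_simple > min_exp_hom
            and r.phh_simple < max_phh
            and r.phh_mating < max_phh
        )
    kept = [r for r in records if r.passes_filter]

    def chrom_key(c):
        return (0, int(c)) if str(c).isdigit() else (1, str(c))

    return sorted(kept, key=lambda r: (chrom_key(r.chrom), r.start_bp))


def depletion_report(
    catalog: HaplotypeCatalog,
    ped: Pedigree,
    min_hap_pct: float = 2.0,
    convention: str = "haplotype",
) -> list:
    """Build DepletionRecords for every zero-homozygote haplotype at or above
    the frequency floor. Catalog animals absent from the pedigree are skipped
    by the mating method (their matings cannot be resolved)."""
    n = catalog.n_genotyped
    genotyped_in_ped = [a for a in catalog.animals if a in ped]
    n_missing = len(catalog.animals) - len(genotyped_in_ped)
    if n_missing:
        import logging

        logging.getLogger(__name__).warning(
            "%d genotyped animals absent from pedigree; skipped by mating method",
            n_missing,
        )
    records = []
    for hap in catalog:
        if hap.n_homozygotes > 0:
            continue
        f = hap.n_carriers / (2 * n)
        if 100.0 * f <= min_hap_pct:
            continue
        carriers = {c for c in hap.carrier_ids if c in ped}
        n_matings = count_carrier_matings(ped, carriers, genotyped_in_ped)
        records.append(
            DepletionRecord(
                haplotype=hap.name,
                chrom=hap.chrom,
                start_bp=hap.start_bp,
                end_bp=hap.end_bp,
                n_markers=hap.n_markers,
                n_genotyped=n,
                n_carriers=hap.n_carriers,
                n_homozygotes=0,
                n_carrier_matings=n_matings,
                phh_simple=phh_simple(f, n, convention="haplotype")
                if convention == "haplotype"
                else phh_simple(hap.n_carriers / n, n, convention="carrier"),
                phh_mating=phh_mating(n_matings),
            )
        )
    return records


class DepletionScreen(BaseEstimator):
    """Genome screen for recessive lethal haplotypes.

    Segments the phased panel, enumerates haplotypes, applies the simple and
    mating depletion tests and the three-condition filter.

    Parameters
    ----------
    max_markers : largest marker count per segment (sliding-window width).
    min_hap_pct : haplotype-percentage floor (100*f must exceed it).
    min_exp_hom : floor on the simple expected homozygote count.
    max_phh : ceiling both zero-homozygote probabilities must stay below.
    phh_convention : 'haplotype' (reproduces published screens) or 'carrier'
        (the formula's literal reading with C).

    Attributes (after fit)
    ----------------------
    plan_ : SegmentPlan. catalog_ : HaplotypeCatalog.
    records_ : all zero-homozygote DepletionRecords above the floor.
    candidates_ : records passing the filter, sorted by position.
    report_ : DataFrame of records_ (one row per tested haplotype).
    """

    def __init__(
        self,
        max_markers: int = 200,
        min_hap_pct: float = 2.0,
        min_exp_hom: float = 1.0,
        max_phh: float = 0.6,
        phh_convention: str = "haplotype",
    ):
        self.max_markers = max_markers
        self.min_hap_pct = min_hap_pct
        self.min_exp_hom = min_exp_hom
        self.max_phh = max_phh
        self.phh_convention = phh_convention

    def fit(self, panel: PhasedPanel, pedigree: Pedigree) -> "DepletionScreen":
        if self.phh_convention not in ("haplotype", "carrier"):
            raise ValueError("phh_convention must be 'haplotype' or 'carrier'")
        self.plan_ = plan_segments(panel.marker_map, self.max_markers)
        self.catalog_ = enumerate_haplotypes(panel, self.plan_)
        self.records_ = depletion_report(
            self.catalog_,
            pedigree,
            min_hap_pct=self.min_hap_pct,
            convention=self.phh_convention,
        )
        self.candidates_ = filter_candidates(
            self.records_,
            min_hap_pct=self.min_hap_pct,
            min_exp_hom=self.min_exp_hom,
            max_phh=self.max_phh,
        )
        self.report_ = records_to_frame(self.records_)
        return self


def load_published_screen_counts() -> pd.DataFrame:
    """Published zero-homozygote haplotype counts from a 62,022-animal Nellore
    screen: per haplotype the carrier count and the carrier-sire x
    carrier-maternal-grandsire pair count, with the printed expectations and
    probabilities for cross-checking the arithmetic."""
    with resources.files("lethascan.data").joinpath(
        "nellore_screen_counts.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype={"haplotype": str, "chrom": str})
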