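"""Sliding-window segmentation of phased genotypes and haplotype enumeration.

Chromosomes are partitioned into contiguous marker blocks of at most
``max_len`` markers (default 200), as equal in size as possible, and every
distinct allele string within a block is catalogued with its copy count,
carriers (one copy) and homozygotes (two copies). Segment ids are numbered
consecutively across chromosomes in map order; haplotypes within a segment by
descending copy count (ties: lexicographic allele string), so a candidate is
addressed as ``<segment>.<haplotype>``.

Exact string identity defines a haplotype; the panel must be completely
phased (no missing alleles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class PhasingError(ValueError):
    """Raised when the panel is not fully phased / contains missing alleles."""


@dataclass
class PhasedPanel:
    """Phased biallelic haplotypes for a set of genotyped animals.

    Attributes
    ----------
    marker_map : DataFrame with columns chrom, pos (1-based bp), id; markers
        sorted by position within chromosome, chromosomes in file order.
    haplotypes : uint8 array of shape (n_animals, 2, n_markers), alleles 0/1.
    animals : list of animal ids, row order of ``haplotypes``.
    """

    marker_map: pd.DataFrame
    haplotypes: np.ndarray
    animals: list

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_animals, 2, n_markers)")
        if self.haplotypes.shape[2] != len(self.marker_map):
            raise ValueError("marker count mismatch between map and haplotypes")
        if self.haplotypes.shape[0] != len(self.animals):
            raise ValueError("animal count mismatch")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise PhasingError(
                "panel contains alleles outside {0,1}; input must be "
                "complete phased biallelic data"
            )
        self.animals = [str(a) for a in self.animals]

    @property
    def n_animals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[2]

    def chromosomes(self) -> list:
        return list(pd.unique(self.marker_map["chrom"]))

    def subset_markers(self, keep: np.ndarray) -> "PhasedPanel":
        keep = np.asarray(keep)
        return PhasedPanel(
            self.marker_map.iloc[keep].reset_index(drop=True),
            self.haplotypes[:, :, keep],
            list(self.animals),
        )


@dataclass(frozen=True)
class Segment:
    """One half-open marker-index block [start, stop) on a chromosome."""

    segment_id: int  # 1-based, consecutive across chromosomes
    chrom: str
    start: int  # global marker index, inclusive
    stop: int  # global marker index, exclusive

    @property
    def n_markers(self) -> int:
        return self.stop - self.start


@dataclass
class SegmentPlan:
    segments: list

    def __iter__(self):
        return iter(self.segments)

    def __len__(self):
        return len(self.segments)

    def to_frame(self, marker_map: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for seg in self.segments:
            rows.append(
                {
                    "segment": seg.segment_id,
                    "chrom": seg.chrom,
                    "start_idx": seg.start,
                    "stop_idx": seg.stop,
                    "n_markers": seg.n_markers,
                    "start_bp": int(marker_map["pos"].iloc[seg.start]),
                    "end_bp": int(marker_map["pos"].iloc[seg.stop - 1]),
                }
            )
        return pd.DataFrame(rows)


def plan_segments(marker_map: pd.DataFrame, max_len: int = 200) -> SegmentPlan:
    """Partition each chromosome into ceil(M/max_len) near-equal blocks.

    Within a chromosome with M markers the n_seg = ceil(M/max_len) block sizes
    are floor(M/n_seg) or ceil(M/n_seg), larger blocks first, so sizes within
    a chromosome differ by at most one and never exceed ``max_len``.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    pos = marker_map["pos"].to_numpy()
    chroms = marker_map["chrom"].to_numpy()
    segments = []
    seg_id = 0
    offset = 0
    for chrom in pd.unique(marker_map["chrom"]):
        mask = chroms == chrom
        m = int(mask.sum())
        idx = np.flatnonzero(mask)
        if not np.array_equal(idx, np.arange(idx[0], idx[0] + m)):
            raise ValueError(f"markers of chromosome {chrom} are not contiguous")
        p = pos[idx]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"markers of chromosome {chrom} not sorted by position")
        if m == 0:  # pragma: no cover - pd.unique cannot yield an empty group
            warnings.warn(f"chromosome {chrom} has no markers; skipped")
            continue
        n_seg = -(-m // max_len)
        base, extra = divmod(m, n_seg)
        start = idx[0]
        for k in range(n_seg):
            size = base + (1 if k < extra else 0)
            seg_id += 1
            segments.append(Segment(seg_id, str(chrom), start, start + size))
            start += size
        offset += m
    return SegmentPlan(segments)


@dataclass
class HaplotypeRecord:
    """One distinct allele string within a segment."""

    segment_id: int
    haplotype_no: int  # 1-based rank by descending copy count within segment
    chrom: str
    start_bp: int
    end_bp: int
    n_markers: int
    allele_string: str
    copies: int
    carrier_ids: list
    homozygote_ids: list

    @property
    def name(self) -> str:
        return f"{self.segment_id}.{self.haplotype_no}"

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_ids)

    @property
    def n_homozygotes(self) -> int:
        return len(self.homozygote_ids)


@dataclass
class HaplotypeCatalog:
    """All haplotypes of all segments, plus the panel bookkeeping."""

    records: list
    n_genotyped: int
    animals: list

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    def by_segment(self, segment_id: int) -> list:
        return [r for r in self.records if r.segment_id == segment_id]

    def get(self, name: str) -> HaplotypeRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": [r.name for r in self.records],
                "segment": [r.segment_id for r in self.records],
                "haplotype_no": [r.haplotype_no for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "start_bp": [r.start_bp for r in self.records],
                "end_bp": [r.end_bp for r in self.records],
                "n_markers": [r.n_markers for r in self.records],
                "copies": [r.copies for r in self.records],
                "n_carriers": [r.n_carriers for r in self.records],
                "n_homozygotes": [r.n_homozygotes for r in self.records],
                "allele_string": [r.allele_string for r in self.records],
            }
        )


def enumerate_haplotypes(panel: PhasedPanel, plan: SegmentPlan) -> HaplotypeCatalog:
    """Catalogue every distinct allele string per segment with carrier sets.

    Each animal contributes its two allele strings; per haplotype,
    2*|homozygotes| + |carriers| = copy count and the copy counts over a
    segment sum to 2N.
    """
    if panel.n_markers == 0 or len(plan) == 0:
        return HaplotypeCatalog([], panel.n_animals, list(panel.animals))
    last = max(seg.stop for seg in plan)
    if last > panel.n_markers:
        raise ValueError("segment plan extends beyond the panel's markers")
    records = []
    animals = np.asarray(panel.animals)
    pos = panel.marker_map["pos"].to_numpy()
    for seg in plan:
        block = panel.haplotypes[:, :, seg.start : seg.stop]
        n, _, m = block.shape
        flat = np.ascontiguousarray(block.reshape(2 * n, m))
        # group identical rows: view as void for lexicographic uniqueness
        uniq, inverse, counts = np.unique(
            flat.view([("", flat.dtype)] * m).ravel(),
            return_inverse=True,
            return_counts=True,
        )
        inverse = inverse.reshape(n, 2)
        strings = ["".join(map(str, np.array(u.tolist(), dtype=int))) for u in uniq]
        # rank: descending copies, ties lexicographic by allele string
        order = sorted(range(len(uniq)), key=lambda k: (-counts[k], strings[k]))
        rank = {k: r + 1 for r, k in enumerate(order)}
        hom = inverse[:, 0] == inverse[:, 1]
        for k in order:
            in_a = inverse[:, 0] == k
            in_b = inverse[:, 1] == k
            hom_mask = in_a & in_b
            car_mask = (in_a | in_b) & ~hom_mask
            records.append(
                HaplotypeRecord(
                    segment_id=seg.segment_id,
                    haplotype_no=rank[k],
                    chrom=seg.chrom,
                    start_bp=int(pos[seg.start]),
                    end_bp=int(pos[seg.stop - 1]),
                    n_markers=m,
                    allele_string=strings[k],
                    copies=int(counts[k]),
                    carrier_ids=list(animals[car_mask]),
                    homozygote_ids=list(animals[hom_mask]),
                )
            )
    return HaplotypeCatalog(records, panel.n_animals, list(panel.animals))
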