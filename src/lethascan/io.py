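"""Readers and writers for the external formats, plus marker QC.

Phased VCF 4.2 is the canonical genotype interchange (read through cyvcf2);
a plain haplotype-matrix TSV is accepted for dependency-light fixtures.
Chromosome names are harmonised by stripping an optional "chr"/"BTA" prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .haploscan import PhasedPanel, PhasingError
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

DEFAULT_AUTOSOMES = [str(c) for c in range(1, 30)]  # BTA1..BTA29


def norm_chrom(c) -> str:
    s = str(c).strip()
    for prefix in ("chr", "Chr", "CHR", "BTA", "bta"):
        if s.startswith(prefix):
            return s[len(prefix):]
    return s


# ---------------------------------------------------------------------------
# phased VCF

def write_phased_vcf(panel: PhasedPanel, path) -> None:
    """Write the panel as minimal phased VCF 4.2 (GT with '|' separator)."""
    mm = panel.marker_map
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(mm["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.animals)
            + "\n"
        )
        h = panel.haplotypes
        for j in range(panel.n_markers):
            row = mm.iloc[j]
            gts = "\t".join(f"{h[i, 0, j]}|{h[i, 1, j]}" for i in range(panel.n_animals))
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_phased_vcf(path) -> PhasedPanel:
    """Read a fully phased biallelic VCF into a PhasedPanel (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animals = list(vcf.samples)
    chroms, pos, ids, rows = [], [], [], []
    for i, var in enumerate(vcf):
        gt = np.asarray(var.genotype.array())
        if gt.shape[1] < 3 or np.any(gt[:, 2] == 0):
            raise PhasingError(
                f"unphased genotype at {var.CHROM}:{var.POS} (record {i + 1}); "
                "this pipeline requires completely phased input"
            )
        alleles = gt[:, :2]
        if np.any(alleles < 0) or np.any(alleles > 1):
            raise PhasingError(
                f"missing or multiallelic genotype at {var.CHROM}:{var.POS} "
                f"(record {i + 1})"
            )
        chroms.append(norm_chrom(var.CHROM))
        pos.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        rows.append(alleles.astype(np.uint8))
    vcf.close()
    if not rows:
        return PhasedPanel(
            pd.DataFrame({"chrom": [], "pos": [], "id": []}),
            np.empty((len(animals), 2, 0), dtype=np.uint8),
            animals,
        )
    haps = np.stack(rows, axis=2)  # (n_animals, 2, n_markers)
    mm = pd.DataFrame({"chrom": chroms, "pos": pos, "id": ids})
    return PhasedPanel(mm, haps, animals)


# ---------------------------------------------------------------------------
# haplotype-matrix TSV (fixture format): one row per haplotype copy

def write_haplotype_matrix(panel: PhasedPanel, path) -> None:
    m = panel.n_markers
    with open(path, "w") as fh:
        fh.write("animal\tcopy\t" + "\t".join(panel.marker_map["id"]) + "\n")
        for i, a in enumerate(panel.animals):
            for c in range(2):
                fh.write(a + f"\t{c + 1}\t" + "\t".join(map(str, panel.haplotypes[i, c])) + "\n")


def read_haplotype_matrix(path, marker_map: pd.DataFrame) -> PhasedPanel:
    df = pd.read_csv(path, sep="\t", dtype={"animal": str})
    marker_cols = [c for c in df.columns if c not in ("animal", "copy")]
    if list(marker_cols) != list(marker_map["id"]):
        raise ValueError("haplotype matrix columns do not match the marker map")
    animals = list(dict.fromkeys(df["animal"]))
    n, m = len(animals), len(marker_cols)
    haps = np.zeros((n, 2, m), dtype=np.uint8)
    idx = {a: i for i, a in enumerate(animals)}
    for _, row in df.iterrows():
        haps[idx[row["animal"]], int(row["copy"]) - 1] = row[marker_cols].to_numpy(
            dtype=np.uint8
        )
    return PhasedPanel(marker_map.reset_index(drop=True), haps, animals)


# ---------------------------------------------------------------------------
# pedigree / traits

def write_pedigree_csv(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and not set(c.lower() for c in df.columns) >= {"animal", "sire", "dam"}:
        raise ValueError(f"{path}: not a pedigree CSV (need animal,sire,dam columns)")
    return Pedigree.from_frame(df)


def read_traits_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"animal": str, "trait": str, "cg": str})
    missing = {"animal", "trait", "value", "cg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: traits CSV lacks columns {sorted(missing)}")
    bad = ~df["value"].isin([0, 1])
    if bad.any():
        lineno = int(df.index[bad][0]) + 2  # header + 1-based
        raise ValueError(f"{path}:{lineno}: trait values must be strictly 0/1")
    return df


def read_marker_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    missing = {"chrom", "pos", "id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: marker map lacks columns {sorted(missing)}")
    df["chrom"] = df["chrom"].map(norm_chrom)
    return df


# ---------------------------------------------------------------------------
# gene spans (BED6 / GFF3)

def read_gene_spans(path) -> pd.DataFrame:
    """Gene spans as a DataFrame (chrom, start, end, gene) from BED6 or GFF3.

    BED intervals are half-open 0-based and converted to 1-based inclusive;
    GFF3 is already 1-based inclusive and only 'gene' features are kept.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3", ".gtf"):
        rows = []
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}:{i}: malformed GFF3 line")
                if parts[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("ID") or f"gene_{i}"
                rows.append(
                    {
                        "chrom": norm_chrom(parts[0]),
                        "start": int(parts[3]),
                        "end": int(parts[4]),
                        "gene": name,
                    }
                )
        genes = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    else:  # BED
        genes = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "gene"],
            dtype={0: str, 3: str},
        )
        genes["chrom"] = genes["chrom"].map(norm_chrom)
        genes["start"] = genes["start"] + 1  # BED 0-based half-open -> 1-based
    return genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# marker QC

@dataclass
class QcReport:
    n_input: int
    n_non_autosomal: int
    n_low_gencall: int
    n_duplicate_position: int
    n_monomorphic: int
    n_retained: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def qc_markers(
    panel: PhasedPanel,
    gencall: np.ndarray | None = None,
    min_gencall: float = 0.90,
    autosomes: list | None = None,
):
    """Marker QC: drop non-autosomal markers, markers with GenCall score below
    ``min_gencall`` (when scores are supplied; the cutoff itself is retained),
    duplicate-position markers (first by input order kept), and monomorphic
    markers. Returns (filtered panel, QcReport)."""
    autosomes = set(DEFAULT_AUTOSOMES if autosomes is None else map(str, autosomes))
    mm = panel.marker_map
    n = len(mm)
    keep = np.ones(n, dtype=bool)

    autosomal = mm["chrom"].map(norm_chrom).isin(autosomes).to_numpy()
    n_nonauto = int((~autosomal).sum())
    keep &= autosomal

    n_low = 0
    if gencall is not None:
        gencall = np.asarray(gencall, dtype=float)
        if len(gencall) != n:
            raise ValueError("gencall scores must match the marker count")
        low = gencall < min_gencall
        n_low = int((low & keep).sum())
        keep &= ~low

    dup = mm.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
    n_dup = int((dup & keep).sum())
    if n_dup:
        logger.info("dropping %d duplicate-position markers", n_dup)
    keep &= ~dup

    flat = panel.haplotypes.reshape(-1, n)
    mono = (flat == flat[0]).all(axis=0) if flat.shape[0] else np.zeros(n, dtype=bool)
    n_mono = int((mono & keep).sum())
    keep &= ~mono

    if not keep.any():
        raise ValueError("marker QC removed every marker")
    report = QcReport(
        n_input=n,
        n_non_autosomal=n_nonauto,
        n_low_gencall=n_low,
        n_duplicate_position=n_dup,
        n_monomorphic=n_mono,
        n_retained=int(keep.sum()),
    )
    return panel.subset_markers(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# tabular outputs

def write_tsv(df: pd.DataFrame, path, comment: dict | None = None) -> None:
    """TSV with a '#' comment block (version, config hash, seed ...)."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# lethascan {__version__}\n")
        for k, v in (comment or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
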