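"""End-to-end pipeline: simulate -> qc -> scan -> depletion -> ebv ->
deregress -> gwas -> annotate, driven by a RunConfig.

Every stage writes its artifacts under the run directory and never mutates
its inputs; re-running with the same config and seed reproduces every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .depletion import DepletionScreen, records_to_frame
from .gwas import (
    annotate_windows,
    cross_trait_overlap,
    dosage_matrix,
    haplotype_association,
    snp_association,
)
from .liability import GibbsThresholdModel, deregress, prepare_traits
from .simdata import SimConfig, simulate_population, write_population

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "qc", "scan", "depletion", "ebv", "deregress", "gwas", "annotate")


@dataclass
class RunConfig:
    """Paths, thresholds and toggles for one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(_STAGES))
    # inputs (ignored by stages that regenerate them)
    vcf: str | None = None
    pedigree: str | None = None
    traits: str | None = None
    genes: str | None = None
    gencall: str | None = None
    regions_bed: str | None = None
    # simulate
    simulate: dict = field(default_factory=dict)
    # scan / depletion
    max_markers: int = 200
    min_hap_pct: float = 2.0
    min_exp_hom: float = 1.0
    max_phh: float = 0.6
    phh_convention: str = "haplotype"
    # ebv / deregress
    min_cg: int = 5
    n_iter: int = 6000
    burn_in: int = 1500
    thin: int = 5
    min_accuracy: float = 0.40
    garrick_c: float = 0.5
    # gwas
    significance: float = 6.0
    tail: str = "t"
    gene_window: int = 100_000
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if not 0 < self.max_phh <= 1:
            raise ValueError("max_phh must be in (0,1]")
        if not 0 <= self.min_accuracy <= 1:
            raise ValueError("min_accuracy must be in [0,1]")
        if self.gene_window < 0 or self.significance < 0 or self.min_hap_pct < 0:
            raise ValueError("thresholds must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analysis parameters (paths excluded, so runs of the
        same analysis in different directories share a digest)."""
        d = dataclasses.asdict(self)
        for path_field in ("out_dir", "vcf", "pedigree", "traits", "genes",
                           "gencall", "regions_bed"):
            d.pop(path_field, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns a path map of artifacts.

    A failing stage raises with the stage name in the message.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comment = {"config": config.digest(), "seed": config.seed}
    artifacts: dict = {}
    panel = pedigree = traits = None
    candidates = None
    debv_by_trait: dict = {}
    h2_by_trait: dict = {}

    def _load_inputs(need_panel=True, need_ped=False, need_traits=False):
        nonlocal panel, pedigree, traits
        if need_panel and panel is None:
            if not config.vcf:
                raise RuntimeError("no VCF available; run simulate or set vcf")
            panel = lio.read_phased_vcf(config.vcf)
        if need_ped and pedigree is None:
            if not config.pedigree:
                raise RuntimeError("no pedigree available; run simulate or set pedigree")
            pedigree = lio.read_pedigree_csv(config.pedigree)
        if need_traits and traits is None:
            if not config.traits:
                raise RuntimeError("no traits available; run simulate or set traits")
            traits = lio.read_traits_csv(config.traits)

    for stage in [s for s in _STAGES if s in config.stages]:
        try:
            if stage == "simulate":
                sim_kwargs = dict(config.simulate)
                sim_kwargs.setdefault("seed", config.seed)
                pop = simulate_population(SimConfig(**sim_kwargs))
                paths = write_population(pop, out / "sim")
                artifacts.update({f"sim_{k}": str(v) for k, v in paths.items()})
                config.vcf = str(paths["vcf"])
                config.pedigree = str(paths["pedigree"])
                config.traits = str(paths["traits"])
                panel, pedigree, traits = pop.panel, pop.pedigree, pop.traits
                logger.info("simulate: %d animals, %d markers", panel.n_animals, panel.n_markers)

            elif stage == "qc":
                _load_inputs()
                scores = None
                if config.gencall:
                    scores = pd.read_csv(config.gencall, sep="\t")["score"].to_numpy()
                panel, report = lio.qc_markers(panel, gencall=scores)
                p = out / "qc_report.json"
                p.write_text(json.dumps(report.to_dict(), indent=1))
                artifacts["qc_report"] = str(p)
                logger.info("qc: retained %d/%d markers", report.n_retained, report.n_input)

            elif stage == "scan":
                _load_inputs()
                from .haploscan import enumerate_haplotypes, plan_segments

                plan = plan_segments(panel.marker_map, config.max_markers)
                catalog = enumerate_haplotypes(panel, plan)
                p = out / "catalog.tsv"
                lio.write_tsv(catalog.to_frame(), p, comment)
                artifacts["catalog"] = str(p)
                logger.info("scan: %d segments, %d haplotypes", len(plan), len(catalog))

            elif stage == "depletion":
                _load_inputs(need_ped=True)
                screen = DepletionScreen(
                    max_markers=config.max_markers,
                    min_hap_pct=config.min_hap_pct,
                    min_exp_hom=config.min_exp_hom,
                    max_phh=config.max_phh,
                    phh_convention=config.phh_convention,
                ).fit(panel, pedigree)
                lio.write_tsv(screen.report_, out / "depletion.tsv", comment)
                cand = records_to_frame(screen.candidates_)
                lio.write_tsv(cand, out / "candidates.tsv", comment)
                string_by_name = {
                    r.haplotype: screen.catalog_.get(r.haplotype) for r in screen.candidates_
                }
                candidates = [
                    {
                        "haplotype": r.haplotype,
                        "chrom": r.chrom,
                        "start_bp": r.start_bp,
                        "end_bp": r.end_bp,
                        "carrier_ids": list(string_by_name[r.haplotype].carrier_ids),
                    }
                    for r in screen.candidates_
                ]
                artifacts["depletion"] = str(out / "depletion.tsv")
                artifacts["candidates"] = str(out / "candidates.tsv")
                logger.info(
                    "depletion: %d tested, %d candidates pass (min_hap_pct=%.2f, "
                    "min_exp_hom=%.2f, max_phh=%.2f)",
                    len(screen.records_), len(screen.candidates_),
                    config.min_hap_pct, config.min_exp_hom, config.max_phh,
                )

            elif stage == "ebv":
                _load_inputs(need_panel=False, need_ped=True, need_traits=True)
                summaries = {}
                for trait, sub in traits.groupby("trait"):
                    prepared = prepare_traits(sub[["animal", "value", "cg"]], config.min_cg)
                    model = GibbsThresholdModel(
                        n_iter=config.n_iter, burn_in=config.burn_in, thin=config.thin,
                        seed=config.seed,
                    ).fit(prepared, pedigree)
                    res = model.result_
                    lio.write_tsv(res.to_frame(), out / f"ebv_{trait}.tsv", comment)
                    h2_by_trait[trait] = res.h2
                    summaries[trait] = {
                        "sigma2_a": res.sigma2_a, "sigma2_a_sd": res.sigma2_a_sd,
                        "h2": res.h2, "h2_sd": res.h2_sd, "n_records": int(len(prepared)),
                        "diverged": res.diverged,
                    }
                    artifacts[f"ebv_{trait}"] = str(out / f"ebv_{trait}.tsv")
                    logger.info("ebv[%s]: h2=%.3f (sd %.3f)", trait, res.h2, res.h2_sd)
                (out / "variance_components.json").write_text(json.dumps(summaries, indent=1))
                artifacts["variance_components"] = str(out / "variance_components.json")

            elif stage == "deregress":
                _load_inputs(need_panel=False, need_ped=True)
                for trait in sorted(h2_by_trait):
                    ebv_path = artifacts.get(f"ebv_{trait}")
                    res_df = lio.read_tsv(ebv_path)
                    from .liability import GibbsResult

                    res = GibbsResult(
                        ids=list(res_df["animal"].astype(str)),
                        ebv=res_df["ebv"].to_numpy(),
                        ebv_sd=res_df["ebv_sd"].to_numpy(),
                        pev=res_df["pev"].to_numpy(),
                        reliability=res_df["reliability"].to_numpy(),
                        sigma2_a=np.nan, sigma2_a_sd=np.nan,
                        h2=h2_by_trait[trait], h2_sd=np.nan,
                        h2_samples=np.empty(0), diverged=False,
                    )
                    d = deregress(
                        res, pedigree, h2=h2_by_trait[trait],
                        min_acc=config.min_accuracy, c=config.garrick_c,
                    )
                    lio.write_tsv(d, out / f"debv_{trait}.tsv", comment)
                    debv_by_trait[trait] = d
                    artifacts[f"debv_{trait}"] = str(out / f"debv_{trait}.tsv")
                    logger.info("deregress[%s]: %d animals above accuracy %.2f",
                                trait, len(d), config.min_accuracy)

            elif stage == "gwas":
                _load_inputs()
                if not debv_by_trait:
                    raise RuntimeError("gwas needs the deregress stage in the same run")
                mask = None
                if config.regions_bed:
                    mask = lio.read_gene_spans(config.regions_bed)
                elif candidates:
                    mask = pd.DataFrame(
                        [
                            {"chrom": c["chrom"], "start": c["start_bp"], "end": c["end_bp"]}
                            for c in candidates
                        ]
                    )
                mm = panel.marker_map
                keep_markers = list(mm["id"])
                if mask is not None and len(mask):
                    sel = np.zeros(len(mm), dtype=bool)
                    for _, reg in mask.iterrows():
                        sel |= (
                            (mm["chrom"].astype(str) == str(reg["chrom"]))
                            & (mm["pos"] >= int(reg["start"]))
                            & (mm["pos"] <= int(reg["end"]))
                        ).to_numpy()
                    keep_markers = list(mm.loc[sel, "id"])
                dos = dosage_matrix(panel, keep_markers)
                per_trait = {}
                for trait, d in sorted(debv_by_trait.items()):
                    assoc = snp_association(
                        d, dos, mm, threshold=config.significance, tail=config.tail
                    )
                    per_trait[trait] = assoc
                    lio.write_tsv(assoc, out / f"assoc_{trait}.tsv", comment)
                    lio.write_tsv(
                        assoc[["chrom", "pos", "minus_log10_p"]],
                        out / f"manhattan_{trait}.tsv", comment,
                    )
                    artifacts[f"assoc_{trait}"] = str(out / f"assoc_{trait}.tsv")
                    if candidates:
                        hap_rows = []
                        for c in candidates:
                            r = haplotype_association(
                                d, c["carrier_ids"], name=c["haplotype"],
                                chrom=c["chrom"], pos=c["start_bp"],
                                threshold=config.significance, tail=config.tail,
                            )
                            hap_rows.append(r)
                        from .gwas import _assoc_frame

                        lio.write_tsv(
                            _assoc_frame(hap_rows), out / f"hap_assoc_{trait}.tsv", comment
                        )
                        artifacts[f"hap_assoc_{trait}"] = str(out / f"hap_assoc_{trait}.tsv")
                    n_sig = int(per_trait[trait]["significant"].sum())
                    logger.info("gwas[%s]: %d markers tested, %d significant at "
                                "-log10(p)>%.1f", trait, len(dos.columns), n_sig,
                                config.significance)
                if len(per_trait) >= 2:
                    ov = cross_trait_overlap(per_trait)
                    (out / "overlap.json").write_text(json.dumps(ov, indent=1))
                    artifacts["overlap"] = str(out / "overlap.json")
                artifacts["_assoc_frames"] = per_trait  # in-memory handoff

            elif stage == "annotate":
                if not config.genes:
                    logger.warning("annotate: no genes file configured; stage skipped")
                    continue
                genes = lio.read_gene_spans(config.genes)
                per_trait = artifacts.get("_assoc_frames", {})
                if not per_trait:
                    raise RuntimeError("annotate needs the gwas stage in the same run")
                for trait, assoc in sorted(per_trait.items()):
                    hits = annotate_windows(assoc, genes, window=config.gene_window)
                    lio.write_tsv(hits, out / f"gene_hits_{trait}.tsv", comment)
                    artifacts[f"gene_hits_{trait}"] = str(out / f"gene_hits_{trait}.tsv")
                    logger.info("annotate[%s]: %d gene hits", trait, len(hits))
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    artifacts.pop("_assoc_frames", None)
    return artifacts
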