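"""End-to-end driver: data (simulated or loaded), ancestry inference, scan,
null calibration and reporting."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import simulate as sim
from .ancestry import HMMParams, estimate_source_freqs, infer_dosage
from .io import GenotypeMatrix, RunConfig, read_genotypes, write_genotypes
from .scan import Region, ScanSummary, call_regions, estimate_fwer, fdr_from_fwer, scan_stats

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    summary: ScanSummary
    regions: list[Region]
    threshold_k: float
    n_snps: int
    stationary_m: float
    fwer: float | None = None
    fdr: float | None = None
    null_region_counts: list[int] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "summary": {
                "mean": self.summary.mean,
                "sd": self.summary.sd,
                "thresholds": {str(k): v for k, v in self.summary.thresholds.items()},
            },
            "threshold_k": self.threshold_k,
            "n_snps": self.n_snps,
            "stationary_m": self.stationary_m,
            "regions": [dataclasses.asdict(r) for r in self.regions],
            "fwer": self.fwer,
            "fdr": self.fdr,
            "null_region_counts": self.null_region_counts,
            "provenance": self.provenance,
        }

    def to_text(self) -> str:
        lines = [
            f"SNPs analysed: {self.n_snps}",
            f"mean ancestry proportion: {self.summary.mean:.4f} "
            f"(SD {self.summary.sd:.4f})",
            f"threshold (mean + {self.threshold_k:g} SD): "
            f"{self.summary.threshold(self.threshold_k):.4f}",
            f"regions called: {len(self.regions)}",
        ]
        for r in self.regions:
            lines.append(f"  {r.chrom}:{r.start}-{r.end} "
                         f"({r.n_snps} SNPs, max {r.max_prop:.3f})")
        if self.fwer is not None:
            lines.append(f"FWER: {self.fwer:.3f}")
        if self.fdr is not None:
            lines.append(f"FDR: {self.fdr:.4f}")
        return "\n".join(lines)


def _validate_report(report: PipelineReport) -> None:
    thr = report.summary.threshold(report.threshold_k)
    for r in report.regions:
        if r.max_prop <= thr:
            raise AssertionError("reported region does not exceed the threshold")


def _load_data(config: RunConfig):
    paths = (config.admixed, config.source_p, config.source_a)
    if all(paths):
        mats = [read_genotypes(p, config.format) for p in paths]
        return mats[0], mats[1], mats[2], None
    if any(paths):
        raise ValueError("admixed, source_p and source_a must all be set")
    demog = sim.DemographyConfig(**config.demography)
    ds = sim.simulate_neutral(demog, config.seed)
    target = config.target_snps or int(round(162_358 * demog.n_segments / 3000))
    ds = sim.ascertain_snps(ds, min(target, ds.n_snps), seed=config.seed + 1)
    return ds.pop_admixed, ds.pop_p, ds.pop_a, ds


def _drop_samples(gm: GenotypeMatrix, exclude: list[str]) -> GenotypeMatrix:
    if not exclude:
        return gm
    keep = [i for i, s in enumerate(gm.sample_ids) if s not in exclude]
    return GenotypeMatrix(
        sample_ids=[gm.sample_ids[i] for i in keep],
        chrom=gm.chrom, pos=gm.pos, ref=gm.ref, alt=gm.alt,
        geno=gm.geno[keep],
    )


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Run the full analysis and write artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    admixed, ref_p, ref_a, ds = _load_data(config)
    admixed = _drop_samples(admixed, config.exclude_samples)

    # call-rate filter; the polymorphic-in-each-population rule applies to
    # loaded (array-style) data — simulated SNPs are ascertained already
    keep = np.ones(admixed.n_snps, dtype=bool)
    for gm in (admixed, ref_p, ref_a):
        keep &= gm.call_rate() >= config.min_call_rate
        if ds is None:
            keep &= gm.is_polymorphic()
    idx = np.where(keep)[0]
    admixed, ref_p, ref_a = (gm.take_snps(idx) for gm in (admixed, ref_p, ref_a))
    logger.info("analysing %d SNPs after filters", admixed.n_snps)

    demog = sim.DemographyConfig(**config.demography) if ds is not None else None
    block_ids = None
    if ds is not None:
        ds = sim.subset_dataset(ds, idx)
        block_ids = sim.segment_ids(ds)

    params = HMMParams(g=config.generations, m=None,
                       rec=config.recombination_rate, eps=config.eps)
    dm = infer_dosage(admixed, estimate_source_freqs(ref_p),
                      estimate_source_freqs(ref_a), params,
                      block_ids=block_ids)
    track = dm.mean_track()
    summary = scan_stats(track)
    regions = call_regions(track, admixed.pos, admixed.chrom,
                           summary.threshold(config.scan_k))

    fwer = fdr = None
    counts: list[int] = []
    if config.n_null_runs > 0:
        if demog is None:
            demog = sim.DemographyConfig(**config.demography)
        fwer, counts = estimate_fwer(
            config.n_null_runs, demog, seed=config.seed + 2,
            target_snps=config.target_snps, eps=config.eps, k=config.scan_k)
        if regions:
            fdr = fdr_from_fwer(fwer, len(regions))

    report = PipelineReport(
        summary=summary, regions=regions, threshold_k=config.scan_k,
        n_snps=admixed.n_snps, stationary_m=float(dm.dosage.mean() / 2),
        fwer=fwer, fdr=fdr, null_region_counts=counts,
        provenance={
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "package": "admixscan",
        },
    )
    _validate_report(report)

    # artifacts
    write_genotypes(admixed, out / "admixed.tsv", "tsv")
    _write_dosage(dm, out / "dosage.tsv")
    _write_regions(regions, out / "regions.tsv")
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    (out / "report.txt").write_text(report.to_text() + "\n")
    return report


def _write_dosage(dm, path) -> None:
    import pandas as pd

    df = pd.DataFrame({"chrom": dm.chrom, "pos": dm.pos})
    for i, s in enumerate(dm.sample_ids):
        df[s] = dm.dosage[i]
    df["mean_prop"] = dm.mean_track()
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _write_regions(regions: list[Region], path) -> None:
    import pandas as pd

    df = pd.DataFrame([dataclasses.asdict(r) for r in regions],
                      columns=["chrom", "start", "end", "n_snps",
                               "max_prop", "mean_prop"])
    df.to_csv(path, sep="\t", index=False)
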