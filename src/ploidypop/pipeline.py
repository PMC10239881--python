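"""End-to-end orchestration of the mixed-ploidy analysis.

Stage order mirrors the study workflow: simulate (or load) data, call
ploidy from fluorescence, genotype dosages from read counts, filter and
thin sites, estimate coancestry and its PCoA, fit admixture over a K
range with Evanno best-K selection, classify introgression at the q
thresholds, infer the tetraploid inheritance mode, and summarize
niche-raster overlap.  A single global seed fans out to independent
per-stage streams so toggling one stage does not perturb the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import admix, cytometry, filters, genolik, inherit, kinship, nicheops, synthio
from .containers import DosageMatrix
from .io import dosage_to_tsv, write_vcf

__all__ = ["PipelineConfig", "run", "report"]

log = logging.getLogger("ploidypop")

STAGES = (
    "simulate",
    "cytometry",
    "genotype",
    "filter",
    "kinship",
    "admixture",
    "introgression",
    "inheritance",
    "niche",
)


@dataclass
class PipelineConfig:
    sim: synthio.SimConfig = field(default_factory=synthio.SimConfig)
    filter: filters.FilterConfig = field(default_factory=filters.FilterConfig)
    q_thresholds: tuple[float, ...] = admix.DEFAULT_THRESHOLDS
    k_range: tuple[int, int] = (1, 10)
    restarts: int = 10
    purity: float = 0.9
    vote_cutoff: float = 0.6
    band_tolerance: float = 0.15
    seed: int = 0
    outdir: str = "ploidypop_out"
    stages: tuple[str, ...] = STAGES
    em_max_iter: int = 2000
    em_tol: float = 1e-8

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synthio.SimConfig(**raw.pop("sim", {}))
        flt = filters.FilterConfig(**raw.pop("filter", {}))
        return cls(sim=sim, filter=flt, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, independent across stages."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the report bundle.

    Every output file is written under ``config.outdir`` together with a
    ``provenance.json`` (config hash, seed, stage seeds).  A stage failure
    raises with the stage name attached; outputs of completed stages are
    retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "stage_seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
    }
    stage = "start"
    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        sim = synthio.SimConfig(**{**asdict(config.sim), "seed": _stage_seed(config.seed, stage)})
        truth, true_dosages, reads = synthio.simulate_dataset(sim)
        bundle["truth"] = truth
        bundle["reads"] = reads
        log.info("simulated %d individuals x %d sites", reads.n_individuals, reads.n_sites)

        # --- cytometry ----------------------------------------------------
        stage = "cytometry"
        if stage in config.stages:
            fluo = synthio.simulate_fluorescence(
                truth.true_ploidy,
                sim.rf_bands,
                seed=_stage_seed(config.seed, stage),
                sample_ids=list(reads.samples),
            )
            known_diploid = fluo[
                fluo["sample_id"].isin(
                    [s for s, v in zip(reads.samples, truth.true_ploidy) if v == 2][:10]
                )
            ]["rf"].to_numpy()
            center = cytometry.calibrate_band(known_diploid)
            calls = cytometry.call_ploidy_table(fluo, center, config.band_tolerance)
            calls.to_csv(out / "ploidy_calls.tsv", sep="\t", index=False)
            bundle["ploidy_calls"] = calls
            bundle["band_center"] = center

        # --- genotype -----------------------------------------------------
        stage = "genotype"
        dosages = genolik.genotype_all(reads, min_depth=config.filter.min_depth)
        bundle["dosages_raw"] = dosages
        write_vcf(dosages, str(out / "genotypes.vcf"), reads)

        # --- filter -------------------------------------------------------
        stage = "filter"
        filtered, flog = filters.filter_sites(dosages, config.filter)
        thinned = filters.thin_one_per_window(filtered, config.filter.window_bp)
        flog.as_frame().to_csv(out / "filter_log.tsv", sep="\t", index=False)
        dosage_to_tsv(thinned, str(out / "dosages_filtered.tsv"))
        bundle["dosages"] = thinned
        bundle["filter_log"] = flog
        log.info("filter cascade: %d -> %d -> %d sites",
                 flog.n_input, flog.n_retained, thinned.n_sites)

        # --- kinship ------------------------------------------------------
        stage = "kinship"
        if stage in config.stages:
            coa = kinship.pairwise_coancestry(filtered)
            pco = kinship.pcoa(coa, n_axes=3)
            coa.as_frame().to_csv(out / "relatedness.tsv", sep="\t")
            np.savetxt(out / "pcoa_coords.tsv", pco.coordinates, delimiter="\t")
            bundle["coancestry"] = coa
            bundle["pcoa"] = pco

        # --- admixture ----------------------------------------------------
        stage = "admixture"
        if stage in config.stages:
            k_lo, k_hi = config.k_range
            if k_hi - k_lo + 1 < 3:
                raise ValueError("k_range must span at least 3 consecutive K values")
            base_seed = _stage_seed(config.seed, stage)
            runs = admix.replicate_likelihoods(
                thinned, range(k_lo, k_hi + 1), n_replicates=config.restarts,
                seed=base_seed, max_iter=config.em_max_iter, tol=config.em_tol,
            )
            ks = admix.select_k(runs)
            bundle["k_selection"] = ks
            chosen = ks.best_k if ks.best_k is not None else k_hi
            best = admix.fit_admixture(
                thinned, chosen, seed=base_seed, restarts=config.restarts,
                max_iter=config.em_max_iter, tol=config.em_tol,
            )
            bundle["admixture_runs"] = runs
            bundle["admixture"] = best
            best.q_frame().to_csv(out / "q_matrix.tsv", sep="\t")

        # --- introgression ------------------------------------------------
        stage = "introgression"
        if stage in config.stages and "admixture" in bundle:
            labels, table = admix.classify_introgression(
                bundle["admixture"].q, config.q_thresholds, list(thinned.samples)
            )
            table.to_csv(out / "introgression.tsv", sep="\t", index=False)
            bundle["introgression_labels"] = labels
            bundle["introgression_table"] = table

        # --- inheritance --------------------------------------------------
        stage = "inheritance"
        if stage in config.stages:
            q = bundle["admixture"].q if "admixture" in bundle else None
            spectrum = inherit.build_spectrum(filtered, q, config.purity)
            call = inherit.classify_mode(spectrum)
            spectrum.as_frame().to_csv(out / "genotype_spectrum.tsv", sep="\t", index=False)
            bundle["spectrum"] = spectrum
            bundle["mode_call"] = call

        # --- niche --------------------------------------------------------
        stage = "niche"
        if stage in config.stages:
            va, vb, ca = synthio.simulate_vote_grids(
                (40, 40), 1.0, "overlap", 0.25, _stage_seed(config.seed, stage)
            )
            ga = nicheops.threshold_votes(nicheops.PresenceGrid(va, ca), config.vote_cutoff)
            gb = nicheops.threshold_votes(nicheops.PresenceGrid(vb, ca), config.vote_cutoff)
            merged = nicheops.merge_models(ga, gb)
            summ = nicheops.area_summary(merged)
            summ.as_frame().to_csv(out / "area_summary.tsv", sep="\t", index=False)
            bundle["area_summary"] = summ

        # --- machine-readable summary ------------------------------------
        summary = {
            "n_individuals": reads.n_individuals,
            "n_sites_input": int(bundle["filter_log"].n_input),
            "n_sites_filtered": int(bundle["filter_log"].n_retained),
            "n_sites_thinned": int(bundle["dosages"].n_sites),
        }
        if "ploidy_calls" in bundle:
            summary["ploidy_counts"] = (
                bundle["ploidy_calls"]["call"].value_counts().to_dict()
            )
        if "k_selection" in bundle:
            summary["best_k"] = bundle["k_selection"].best_k
        if "mode_call" in bundle:
            summary["inheritance_mode"] = bundle["mode_call"].mode
        if "area_summary" in bundle:
            summary["areas_km2"] = bundle["area_summary"].areas
        bundle["summary"] = summary
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
        with open(out / "provenance.json", "w") as fh:
            json.dump(bundle["provenance"], fh, indent=2)
    except Exception as exc:  # annotate with the failing stage, keep partials
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return bundle


def report(bundle: dict) -> str:
    """Render a human-readable multi-section summary of a report bundle."""
    lines: list[str] = ["# ploidypop report", ""]

    def section(title: str) -> None:
        lines.extend(["", f"## {title}", ""])

    section("Ploidy calls (relative fluorescence)")
    if "ploidy_calls" in bundle:
        counts = bundle["ploidy_calls"]["call"].value_counts()
        for k, v in counts.items():
            lines.append(f"  {k}: {v}")
        lines.append(f"  diploid band center: {bundle['band_center']:.3f}")
    else:
        lines.append("  [absent]")

    section("Filter cascade")
    if "filter_log" in bundle:
        lines.append(bundle["filter_log"].as_frame().to_string(index=False))
        lines.append(f"  after thinning: {bundle['dosages'].n_sites} sites")
    else:
        lines.append("  [absent]")

    section("Best-K (Evanno)")
    if "k_selection" in bundle:
        ks = bundle["k_selection"]
        for k, m, s, d in zip(ks.k_values, ks.mean_ll, ks.sd_ll, ks.delta_k):
            lines.append(f"  K={k}: mean LL {m:.1f} (sd {s:.1f}) deltaK {d:.1f}")
        lines.append(f"  chosen K = {ks.best_k}")
    else:
        lines.append("  [absent]")

    section("Introgression percentages per (home, donor) cluster")
    if "introgression_table" in bundle:
        lines.append(bundle["introgression_table"].to_string(index=False))
    else:
        lines.append("  [absent]")

    section("Inheritance mode")
    if "mode_call" in bundle:
        c = bundle["mode_call"]
        lines.append(
            f"  mode={c.mode}  LLR={c.llr:.1f}  loci={c.n_loci}  "
            f"classes at AF~0.5: {c.n_classes_at_half}"
        )
    else:
        lines.append("  [absent]")

    section("Niche-overlap area summary (km^2)")
    if "area_summary" in bundle:
        lines.append(bundle["area_summary"].as_frame().to_string(index=False))
    else:
        lines.append("  [absent]")

    return "\n".join(lines)
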