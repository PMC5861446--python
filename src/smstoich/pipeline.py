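"""End-to-end orchestration: simulate -> detect -> register -> colocalize ->
count steps -> summarize.

A run processes ``n_experiments`` x ``fields_per_experiment`` fields (the
reference protocol is three experiments of ~50 fields each), pools the
step-count histogram by summing counts across experiments, and reports
per-experiment colocalized fractions with their SEM.  A single seed fans
out deterministically to per-field substreams, so changing the number of
fields never reshuffles earlier fields.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .detect import (DetectionParams, EdgeSpotError, detect_spots,
                     extract_trace, max_projection)
from .io import spots_to_frame, traces_to_frame, write_json, write_stack
from .register import (ChromaticMap, colocalize, estimate_coincidence,
                       fit_chromatic_map, summarize_colocalization)
from .simulate import (ComplexPopulationSpec, SimulationConfig,
                       simulate_fiducials, simulate_movie)
from .steps import classify_spot, count_steps
from .stoichiometry import (LabelingModel, StoichiometryMixtureModel,
                            build_histogram, two_step_ratio)

log = logging.getLogger("smstoich")

__all__ = ["RunConfig", "run_pipeline", "analyze_field", "field_rng"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run (simulate mode)."""

    seed: int = 0
    n_experiments: int = 3
    fields_per_experiment: int = 50
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    population: ComplexPopulationSpec = field(
        default_factory=lambda: ComplexPopulationSpec(
            n_complexes=100, stoichiometry_weights={1: 1.0}))
    detection: DetectionParams = field(default_factory=DetectionParams)
    pairing_radius: float = 2.0
    aperture_radius: float = 3.0
    isolation_radius: float = 9.0   # px; spots with a neighbour closer than
                                    # this are excluded from step counting —
                                    # inside it the neighbour's PSF reaches
                                    # into the photometry aperture and mixes
                                    # the traces
    n_fiducials: int = 30
    fiducial_jitter_sd: float = 0.05
    prior_odds: float = 1.0
    min_segment: int = 3
    subtract_coincidence: bool = False   # reported, not subtracted, by default
    fit_mixture: bool = True
    mixture_components: tuple[int, ...] = (1, 2)


def field_rng(seed: int, experiment: int, field_idx: int) -> np.random.Generator:
    """Deterministic per-field random stream."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(experiment, field_idx)))


def analyze_field(red_stack, green_stack, chromatic_map: ChromaticMap,
                  config: RunConfig) -> dict:
    """Detect, pair and step-count one field; returns per-field results.

    Edge spots whose photometry annulus would leave the image are excluded
    and counted in ``n_edge_excluded`` rather than silently dropped.
    """
    red_img = max_projection(red_stack)
    green_img = max_projection(green_stack)
    red_spots = detect_spots(red_img, config.detection, channel="red")
    green_spots = detect_spots(green_img, config.detection, channel="green")
    coloc = colocalize(red_spots, green_spots, chromatic_map,
                       radius=config.pairing_radius)
    area = float(np.prod(green_img.shape))
    coloc.coincidence_estimate = estimate_coincidence(
        red_spots, green_spots, image_area=area, radius=config.pairing_radius)

    green_xy = np.array([[s.x, s.y] for s in green_spots]) if green_spots else np.zeros((0, 2))
    classifications = []
    n_edge = 0
    n_crowded = 0
    steps_rows = []
    for red_id, green_id, dist in coloc.pairs:
        spot = green_spots[green_id]
        if len(green_xy) > 1 and config.isolation_radius > 0:
            d2 = ((green_xy - green_xy[green_id]) ** 2).sum(axis=1)
            d2[green_id] = np.inf
            if d2.min() < config.isolation_radius ** 2:
                n_crowded += 1
                continue
        try:
            trace = extract_trace(green_stack, spot,
                                  aperture_radius=config.aperture_radius)
        except EdgeSpotError:
            n_edge += 1
            continue
        fit = count_steps(trace, prior_odds=config.prior_odds,
                          min_segment=config.min_segment)
        label = classify_spot(fit)
        classifications.append(label)
        steps_rows.append({"red_id": red_id, "green_id": green_id,
                           "distance": dist, "n_down": fit.n_down_steps,
                           "n_up": fit.n_up_steps, "classification": label,
                           "score": fit.score})
    return {
        "red_spots": red_spots,
        "green_spots": green_spots,
        "coloc": coloc,
        "classifications": classifications,
        "n_rna_spots": len(red_spots),
        "n_edge_excluded": n_edge,
        "n_crowded_excluded": n_crowded,
        "coincidence": coloc.coincidence_estimate,
        "steps": pd.DataFrame(steps_rows,
                              columns=["red_id", "green_id", "distance",
                                       "n_down", "n_up", "classification",
                                       "score"]),
    }


def run_pipeline(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the full simulated pipeline and return the report dictionary.

    Pooled histogram = summed class counts over all experiments;
    colocalization = mean and SEM over per-experiment fractions; random
    coincidence is reported per run but not subtracted unless
    ``subtract_coincidence`` is set.
    """
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    all_classifications: list[str] = []
    total_rna = 0
    per_experiment_fraction: list[float] = []
    coincidences: list[float] = []
    n_edge_total = 0

    for e in range(config.n_experiments):
        exp_rng = field_rng(config.seed, e, 10 ** 6)
        fiducials = simulate_fiducials(config.simulation.chromatic_map,
                                       n=config.n_fiducials,
                                       jitter_sd=config.fiducial_jitter_sd,
                                       rng=exp_rng,
                                       image_size=config.simulation.image_size)
        cmap = fit_chromatic_map(fiducials)
        exp_pairs = 0
        exp_rna = 0
        for f in range(config.fields_per_experiment):
            rng = field_rng(config.seed, e, f)
            red_stack, green_stack, truth = simulate_movie(
                config.population, config.simulation, rng=rng)
            res = analyze_field(red_stack, green_stack, cmap, config)
            all_classifications.extend(res["classifications"])
            total_rna += res["n_rna_spots"]
            exp_rna += res["n_rna_spots"]
            exp_pairs += res["coloc"].n_pairs
            coincidences.append(res["coincidence"])
            n_edge_total += res["n_edge_excluded"]
            if out is not None:
                tag = f"e{e}_f{f}"
                spots_to_frame(res["red_spots"], field_id=f).to_csv(
                    out / f"spots_red_{tag}.csv", index=False)
                spots_to_frame(res["green_spots"], field_id=f).to_csv(
                    out / f"spots_green_{tag}.csv", index=False)
                res["steps"].to_csv(out / f"steps_{tag}.csv", index=False)
            log.info("experiment %d field %d: %d RNA spots, %d pairs",
                     e, f, res["n_rna_spots"], res["coloc"].n_pairs)
        frac = 100.0 * exp_pairs / exp_rna if exp_rna else 0.0
        if config.subtract_coincidence and coincidences:
            frac -= 100.0 * float(np.mean(coincidences))
        per_experiment_fraction.append(frac)

    coloc_summary = summarize_colocalization(per_experiment_fraction)
    hist = (build_histogram(all_classifications, total_rna)
            if total_rna else None)

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_experiments": config.n_experiments,
        "fields_per_experiment": config.fields_per_experiment,
        "total_rna_spots": total_rna,
        "n_edge_excluded": n_edge_total,
        "colocalization": coloc_summary.to_dict(),
        "mean_coincidence_fraction": float(np.mean(coincidences)) if coincidences else 0.0,
        "coincidence_subtracted": config.subtract_coincidence,
        "histogram": hist.to_dict() if hist else None,
    }
    if hist is not None and hist.counts["1"] > 0:
        report["two_step_one_step_ratio_percent"] = two_step_ratio(hist)
    if hist is not None and config.fit_mixture and hist.n_classified > 0:
        model = LabelingModel(p_label=config.population.p_label,
                              d=config.population.dimer_fraction)
        results = StoichiometryMixtureModel(
            hist, model, components=config.mixture_components).fit()
        report["mixture"] = results.to_dict()
    if out is not None:
        write_json(report, out / "report.json")
    return report
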