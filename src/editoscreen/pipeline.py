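"""End-to-end orchestration: simulate -> screen -> control -> quantify ->
stats -> report.

Each stage writes plain files before the next stage reads them, so any
stage can be re-run in isolation.  All floating-point output is serialized
at fixed precision and every random draw flows from the configured seed,
so re-running a configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import editing_quant, evolutionary_stats, synthetic_data
from .conservation_screen import (
    ScreenResult,
    control_signal_to_noise,
    extract_windows,
    run_screen,
)
from .io_formats import (
    GenomeAssembly,
    SiteRecord,
    read_mpileup,
    read_site_table,
    write_genome,
    write_json,
    write_site_table,
    write_tsv,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "measurements_to_frame", "frame_to_measurements"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-data run."""

    outdir: str
    simulation: synthetic_data.SimulationConfig = dataclasses.field(
        default_factory=synthetic_data.SimulationConfig
    )
    motif_halfwidth: int = 10
    run_reversion: bool = True
    run_control: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | None = None,
                  seed: int | None = None) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        sim = data.pop("simulation", {})
        for key in ("conserved_level_beta", "noncons_level_beta"):
            if key in sim:
                sim[key] = tuple(sim[key])
        if seed is not None:
            sim["seed"] = seed
        if outdir is not None:
            data["outdir"] = outdir
        data.setdefault("outdir", "editoscreen_run")
        return cls(simulation=synthetic_data.SimulationConfig(**sim), **data)


def measurements_to_frame(
    measurements: list[editing_quant.EditingMeasurement],
) -> pd.DataFrame:
    rows = []
    for m in measurements:
        rows.append(
            {
                "species": m.site.species,
                "chrom": m.site.chrom,
                "pos": m.site.pos1,
                "strand": m.site.strand,
                "sample": m.sample,
                "a_reads": m.a_reads,
                "g_reads": m.g_reads,
                "other_reads": m.other_reads,
                "total": m.total,
                "level": float("nan") if m.level is None else m.level,
                "state": m.state,
            }
        )
    return pd.DataFrame(rows)


def frame_to_measurements(df: pd.DataFrame) -> list[editing_quant.EditingMeasurement]:
    out = []
    for row in df.itertuples(index=False):
        site = SiteRecord(species=row.species, chrom=row.chrom,
                          pos1=int(row.pos), strand=row.strand)
        out.append(
            editing_quant.EditingMeasurement(
                site=site, sample=row.sample, a_reads=int(row.a_reads),
                g_reads=int(row.g_reads), other_reads=int(row.other_reads),
                state=row.state,
            )
        )
    return out


def pairs_to_frame(screen: ScreenResult) -> pd.DataFrame:
    rows = []
    for wa in screen.conserved_pairs:
        rows.append(
            {
                "query_chrom": wa.query_site.chrom,
                "query_pos": wa.query_site.pos1,
                "query_strand": wa.query_site.strand,
                "subject_chrom": wa.subject_site.chrom,
                "subject_pos": wa.subject_site.pos1,
                "subject_strand": wa.subject_site.strand,
                "identical": wa.identical,
                "aligned_length": wa.aligned_length,
                "gaps": wa.gaps,
                "score": wa.score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["query_chrom", "query_pos", "query_strand", "subject_chrom",
                 "subject_pos", "subject_strand", "identical",
                 "aligned_length", "gaps", "score"],
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the JSON-ready summary dict.

    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = cfg.simulation
    summary: dict = {"parameters": dataclasses.asdict(sim)}

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        qg, sg, truth = synthetic_data.simulate_ortholog_pair(sim)
        write_genome(qg, outdir / "query_genome.fa")
        write_genome(sg, outdir / "subject_genome.fa")
        write_site_table(truth.query_sites, outdir / "query_sites.tsv")
        write_site_table(truth.subject_sites, outdir / "subject_sites.tsv")
        write_site_table(truth.query_snps, outdir / "query_snps.tsv")
        write_site_table(truth.subject_snps, outdir / "subject_snps.tsv")
        truth.to_json(outdir / "truth.json")
        pileup_dir = outdir / "pileups"
        pileup_dir.mkdir(exist_ok=True)
        pileups = synthetic_data.simulate_pileups(truth, sim, qg, pileup_dir)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(exc)) from exc

    # --- screen -----------------------------------------------------------
    stage = "screen"
    try:
        query_sites = read_site_table(outdir / "query_sites.tsv")
        subject_sites = read_site_table(outdir / "subject_sites.tsv")
        if not query_sites or not subject_sites:
            raise ValueError("empty site table")
        screen = run_screen(query_sites, subject_sites, qg, sg,
                            flank=sim.flank, min_identical=sim.min_identical)
        write_tsv(pairs_to_frame(screen), outdir / "screen_pairs.tsv")
        write_site_table(screen.conserved_query_sites,
                         outdir / "conserved_sites.tsv")
        summary["screen"] = {
            "n_query": screen.n_query,
            "n_subject": screen.n_subject,
            "conserved_found": screen.n_conserved,
            "planted_conserved": len(truth.conserved_pairs),
        }
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- control ----------------------------------------------------------
    if cfg.run_control:
        stage = "control"
        try:
            report = control_signal_to_noise(
                screen, truth.query_snps, truth.subject_snps, qg, sg
            )
            payload = dataclasses.asdict(report)
            if report.ratio_is_infinite:
                payload["ratio"] = None
            write_json(payload, outdir / "control.json")
            summary["signal_to_noise"] = payload
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    # --- quantify ---------------------------------------------------------
    stage = "quantify"
    try:
        meas_dir = outdir / "measurements"
        meas_dir.mkdir(exist_ok=True)
        all_measurements = []
        for strain in truth.strains:
            cols = read_mpileup(pileups[strain])
            ms = editing_quant.quantify_sites(cols, query_sites,
                                              sample=strain)
            all_measurements.extend(ms)
            write_tsv(measurements_to_frame(ms), meas_dir / f"{strain}.tsv")
        matrix = editing_quant.build_matrix(all_measurements)
        matrix.levels().to_csv(outdir / "matrix_levels.tsv", sep="\t",
                               float_format="%.6f")
        matrix.states().to_csv(outdir / "matrix_states.tsv", sep="\t")
        matrix.coverage().to_csv(outdir / "matrix_coverage.tsv", sep="\t")
        groups = {
            s.key: ("conserved" if s.key in truth.conserved_query_keys
                    else "other")
            for s in query_sites
        }
        levels = editing_quant.summarize_levels(matrix, groups)
        summary["levels"] = {
            "group_mean_level": {k: round(v, 6)
                                 for k, v in levels.group_means.items()},
            "group_mean_sd": {k: round(v, 6)
                              for k, v in levels.group_mean_sd.items()},
            "expression_sample": levels.expression_sample,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- accumulation -----------------------------------------------------
    stage = "accumulate"
    try:
        states = matrix.states()
        panel = {
            strain: set(states.index[states[strain] == editing_quant.EDITED])
            for strain in states.columns
        }
        curve = evolutionary_stats.accumulation_curve(panel)
        write_tsv(
            pd.DataFrame(
                {
                    "k": range(1, len(curve.ordered_samples) + 1),
                    "sample": curve.ordered_samples,
                    "cumulative": curve.cumulative_counts,
                    "fraction": curve.fraction_at_k,
                }
            ),
            outdir / "accumulation.tsv",
        )
        summary["accumulation"] = {
            "total_sites": curve.total,
            "samples": len(curve.ordered_samples),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- motif ------------------------------------------------------------
    stage = "motif"
    try:
        conserved_windows = extract_windows(
            qg, screen.conserved_query_sites, sim.flank
        )
        motif = evolutionary_stats.motif_matrix(
            conserved_windows, halfwidth=cfg.motif_halfwidth
        )
        motif.frequencies.to_csv(outdir / "motif.tsv", sep="\t",
                                 float_format="%.6f")
        summary["motif"] = {
            "upstream_g": round(float(motif.frequencies.loc[-1, "G"]), 6),
            "downstream_g": round(float(motif.frequencies.loc[1, "G"]), 6),
            "n_windows": motif.n_windows,
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- regions ----------------------------------------------------------
    stage = "regions"
    try:
        report = evolutionary_stats.classify_regions(query_sites)
        payload = dataclasses.asdict(report)
        payload["nonsynonymous_fraction"] = (
            None if report.annotated_cds == 0
            else round(report.nonsynonymous_fraction, 6)
        )
        write_json(payload, outdir / "regions.json")
        summary["regions"] = {"counts": report.region_counts}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- reversion --------------------------------------------------------
    if cfg.run_reversion:
        stage = "reversion"
        try:
            rev = evolutionary_stats.reversion_analysis(
                query_sites, subject_sites, qg, sg,
                flank=sim.flank, min_identical=sim.min_identical,
            )
            payload = {
                "forward": {
                    "direction": rev.forward.direction,
                    "matched": rev.forward.matched_sites,
                    "fraction_g": rev.forward.fraction_g,
                    "control_fraction_g": rev.forward.control_fraction_g,
                    "counterpart_base_counts":
                        rev.forward.counterpart_base_counts,
                },
                "backward": {
                    "direction": rev.backward.direction,
                    "matched": rev.backward.matched_sites,
                    "fraction_g": rev.backward.fraction_g,
                    "control_fraction_g": rev.backward.control_fraction_g,
                    "counterpart_base_counts":
                        rev.backward.counterpart_base_counts,
                },
                "contingency": rev.contingency,
                "odds_ratio": None if rev.odds_ratio != rev.odds_ratio
                or rev.odds_ratio == float("inf") else rev.odds_ratio,
                "fisher_p": rev.fisher_p,
            }
            write_json(payload, outdir / "reversion.json")
            summary["reversion"] = payload
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    write_json(summary, outdir / "summary.json")
    # deterministic run log: parameters only, no timestamps
    log_lines = ["editoscreen pipeline run"]
    for key, val in sorted(dataclasses.asdict(sim).items()):
        log_lines.append(f"param {key}={val}")
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return summary
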