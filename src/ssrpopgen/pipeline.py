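"""End-to-end analysis pipeline: genotypes in, shaped reports out.

Runs the full stack — allele frequencies, per-marker diversity, allelic
patterns, F-statistics and gene flow, pairwise distances, AMOVA, PCoA,
UPGMA tree, admixture grid with ΔK selection — and writes each stage's
report plus a machine-readable summary of the headline numbers.  All
randomness flows from one root seed, split per stage, so re-running a
config reproduces every output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .admixture import align_labels, evanno, run_admixture
from .amova import individual_squared_distances, run_amova
from .fstatistics import gene_flow, nei_distance, pairwise_fst, per_locus_fstats
from .genotypes import BinningSpec, GenotypeMatrix, bin_alleles, read_genotypes
from .locus_stats import allele_frequencies, locus_summary
from .ordination import pcoa, shared_allele_distance, upgma
from .population_diversity import allelic_patterns

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs."""

    input_path: str | Path | None = None
    dialect: str = "long-table"
    missing_code: str = "0"
    binning: BinningSpec = field(default_factory=BinningSpec)
    amova_permutations: int = 999
    k_range: tuple[int, ...] = tuple(range(1, 9))
    runs_per_k: int = 8
    burnin: int = 30000
    reps: int = 15000
    seed: int = 0
    output_dir: str | Path = "ssrpopgen_out"
    run_admixture_stage: bool = True

    def __post_init__(self) -> None:
        if not self.k_range:
            raise ValueError("K range must be nonempty")


def _write(df, path: Path) -> None:
    df.to_csv(path)


def run_pipeline(
    config: PipelineConfig, matrix: GenotypeMatrix | None = None
) -> dict:
    """Execute every stage and write reports under ``config.output_dir``.

    Either ``matrix`` is given directly or ``config.input_path`` is read.
    Returns the headline summary (also written as ``summary.json``).
    Stages that need >= 2 populations are skipped with a notice on
    single-population input.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(rng.integers(2**31 - 1))
        for name in ("amova", "admixture")
    }
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
    }
    stage = "read"
    try:
        if matrix is None:
            matrix = read_genotypes(
                config.input_path, config.dialect, config.missing_code
            )
        matrix = bin_alleles(matrix, config.binning)
        summary["n_individuals"] = matrix.n_individuals
        summary["n_loci"] = matrix.n_loci
        summary["populations"] = matrix.population_names()

        stage = "locus_stats"
        freqs = allele_frequencies(matrix)
        table2 = locus_summary(freqs, matrix)
        _write(table2, out / "locus_summary.csv")
        body = table2.loc[matrix.loci]
        summary["total_alleles"] = int(body["Allele No"].sum())
        summary["mean_maf"] = float(body["Major Allele Frequency"].mean())
        summary["mean_pic"] = float(body["PIC"].mean())
        summary["mean_ho"] = float(body["Observed Heterozygosity"].mean())

        multi_pop = len(matrix.population_names()) >= 2
        if multi_pop:
            stage = "population_diversity"
            patterns = allelic_patterns(freqs, matrix)
            _write(patterns, out / "allelic_patterns.csv")

            stage = "f_statistics"
            fstats = per_locus_fstats(freqs)
            _write(fstats, out / "fstats.csv")
            mean_row = fstats.loc["Mean"]
            for key, col in (
                ("mean_ht", "Ht"),
                ("mean_fis", "Fis"),
                ("mean_fit", "Fit"),
                ("mean_fst", "Fst"),
                ("mean_nm", "Nm"),
            ):
                summary[key] = float(mean_row[col])
            pw_fst = pairwise_fst(freqs)
            nei = nei_distance(freqs)
            combined = np.triu(nei.values, 1) + np.tril(pw_fst.values, -1)
            import pandas as pd

            _write(
                pd.DataFrame(combined, index=pw_fst.labels, columns=pw_fst.labels),
                out / "pairwise_fst_nei.csv",
            )
            nm = gene_flow(pw_fst)
            _write(
                nm.to_frame().where(np.tril(np.ones(nm.values.shape, bool))),
                out / "pairwise_gene_flow.csv",
            )

            stage = "amova"
            d2 = individual_squared_distances(matrix)
            am = run_amova(
                d2,
                matrix.pop_of,
                n_permutations=config.amova_permutations,
                seed=stage_seeds["amova"],
            )
            _write(am.table, out / "amova.csv")
            summary["amova_percent_among"] = am.percent_among
            summary["amova_percent_within"] = am.percent_within
            summary["amova_p_value"] = am.p_value
        else:
            logger.warning("single population: F-statistics and AMOVA skipped")
            summary["notices"] = [
                "single population: F-statistics and AMOVA skipped"
            ]

        stage = "ordination"
        sad = shared_allele_distance(matrix)
        ord_res = pcoa(sad)
        ord_res.coordinates.to_csv(out / "pcoa_coordinates.csv")
        import pandas as pd

        axes = pd.DataFrame(
            {
                "%": ord_res.percent_variation[:3],
                "Cumulative %": ord_res.cumulative_percent[:3],
            },
            index=pd.Index(range(1, min(3, len(ord_res.percent_variation)) + 1), name="Axis"),
        )
        _write(axes, out / "pcoa_axes.csv")
        summary["pcoa_axis_percent"] = [
            float(x) for x in ord_res.percent_variation[:3]
        ]
        tree = upgma(sad)
        (out / "upgma.nwk").write_text(tree.to_newick() + "\n")

        if config.run_admixture_stage:
            stage = "admixture"
            runs_by_k: dict[int, list] = {}
            sub_rng = np.random.default_rng(stage_seeds["admixture"])
            for k in config.k_range:
                runs = []
                for _ in range(config.runs_per_k):
                    run = run_admixture(
                        matrix,
                        k,
                        burnin=config.burnin,
                        reps=config.reps,
                        seed=int(sub_rng.integers(2**31 - 1)),
                    )
                    runs.append(run)
                runs = align_labels(runs)
                runs_by_k[k] = runs
                runs[0].q_frame().to_csv(out / f"structure_q_K{k}.csv")
            all_runs = [r for rs in runs_by_k.values() for r in rs]
            if len(runs_by_k) >= 3 and config.runs_per_k >= 2:
                stage = "evanno"
                ev = evanno(all_runs)
                _write(ev.table, out / "evanno.csv")
                summary["selected_k"] = ev.selected_k
            else:
                logger.warning("K grid too small for ΔK; selection skipped")
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        summary["failed_stage"] = stage
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        raise

    summary["runtime_seconds"] = round(time.time() - t0, 3)
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline finished in %.1fs", summary["runtime_seconds"])
    return summary
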