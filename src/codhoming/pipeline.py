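"""Config-driven end-to-end run.

Stage order: load/simulate → per-allele HWE screen (advisory warnings) →
diversity table → pairwise θ + permutation p + MDS → pool references →
LOO self-assignment → exclusion test → assignment of tagged fish →
behaviour classification → group summaries → contingency + Fisher +
Boschloo → reference-subsampling robustness.  Every stage writes its table
under the output directory; optional stages degrade gracefully with a
warning recorded in the run report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assignment import (
    assign_individuals,
    build_pool,
    exclusion_test,
    self_assign_loo,
    subsample_robustness,
    summarize,
)
from .behaviour import Boundary, classify_cohort
from .genotypes import (
    GenotypeDataset,
    attach_metadata,
    pool_samples,
    read_genepop,
    read_track_table,
    subset_loci,
)
from .philopatry import boschloo_test, build_contingency, fisher_exact
from .popgen import (
    classical_mds,
    diversity_stats,
    fst_permutation_test,
    pairwise_fst_matrix,
    per_allele_hwe,
    write_diversity_table,
    write_fst_matrix,
    write_mds_coordinates,
)
from .simulate import SyntheticConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "codhoming_out"
    seed: int = 0
    # exactly one of (references path, synthetic) must be set
    references: str | None = None
    tagged: str | None = None
    tracks: str | None = None
    metadata: str | None = None
    synthetic: SyntheticConfig | None = None
    pooling: dict[str, str] | None = None  # sample label -> pool name
    structure_panel: list[str] | None = None  # default: first 8 loci
    assignment_panel: list[str] | None = None  # default: all loci
    permutation_reps: int = 199
    exclusion_sims: int = 1000
    exclusion_threshold: float = 0.01
    assignment_criterion: str = "bayesian"
    hwe_stat: str = "n_fis2"
    boschloo_sided: str = "one"
    boschloo_grid: int = 1001
    boundary_lat: float = 57.75
    boundary_lon: float = 10.0
    subsample_n: int | None = None
    subsample_reps: int = 10

    def __post_init__(self):
        if (self.references is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'references' and 'synthetic' must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw, synthetic=SyntheticConfig(**syn) if syn is not None else None)
        return cfg


@dataclass
class RunReport:
    version: str
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


class _WarningCollector(logging.Handler):
    def __init__(self, sink: list):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record):
        self.sink.append(f"{record.name}: {record.getMessage()}")


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    report = RunReport(__version__, cfg_dict)
    collector = _WarningCollector(report.warnings)
    logging.getLogger("codhoming").addHandler(collector)
    try:
        _run(config, out, report)
    finally:
        logging.getLogger("codhoming").removeHandler(collector)
    with open(out / "report.json", "w") as fh:
        json.dump(asdict(report), fh, indent=1, default=str)
    return report


def _stage(report: RunReport, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            report.stages.setdefault(name, {})
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            report.stages.setdefault(name, {})["elapsed_s"] = round(time.perf_counter() - self.t0, 3)
            return False

    return _Timer()


def _run(config: RunConfig, out: Path, report: RunReport):
    boundary = Boundary(config.boundary_lat, config.boundary_lon)

    with _stage(report, "load"):
        if config.synthetic is not None:
            refs, fish, truth = simulate_study(config.synthetic)
            truth.to_csv(out / "truth.csv", index=False)
            pooling = {s.label: s.label for s in refs.samples}
        else:
            refs = read_genepop(config.references)
            if config.metadata:
                attach_metadata(refs, config.metadata)
            fish = []
            if config.tagged and config.tracks:
                tagged_ds = read_genepop(config.tagged)
                genos = {
                    ind.individual_id: ind for s in tagged_ds.samples for ind in s.individuals
                }
                fish = read_track_table(config.tracks, genotypes=genos)
            else:
                logger.warning("no tagged fish / tracks supplied; behaviour stages skipped")
            pooling = config.pooling or {s.label: s.label for s in refs.samples}
        report.stages["load"] = {
            "n_samples": len(refs.samples),
            "n_loci": len(refs.loci),
            "n_individuals": int(sum(s.n for s in refs.samples)),
            "n_tagged": len(fish),
        }

    structure_panel = config.structure_panel or refs.locus_names[: min(8, len(refs.loci))]
    assignment_panel = config.assignment_panel or refs.locus_names

    with _stage(report, "hwe_screen"):
        flags = 0
        tests = 0
        for s in refs.samples:
            for name in structure_panel:
                try:
                    results = per_allele_hwe(refs, s.label, name, hwe_stat=config.hwe_stat)
                except ValueError:
                    continue
                tests += len(results)
                for r in results:
                    if r.p < 0.001:
                        flags += 1
                        logger.warning(
                            "HWE flag: %s %s allele %d (p=%.2g)", r.sample_label, r.locus, r.allele, r.p
                        )
        report.stages["hwe_screen"].update(
            {"tests": tests, "flags": flags, "multiple_testing": "none (advisory screen)"}
        )

    with _stage(report, "diversity"):
        stats_rows = []
        for s in refs.samples:
            for panel, label in ((structure_panel, 8), (assignment_panel, 12)):
                try:
                    stats_rows.append(diversity_stats(refs, s.label, panel))
                except ValueError as exc:
                    logger.warning("diversity for %s failed: %s", s.label, exc)
        write_diversity_table(stats_rows, out / "table2_diversity.tsv")
        report.stages["diversity"].update({"rows": len(stats_rows)})

    with _stage(report, "structure"):
        matrix = pairwise_fst_matrix(refs, panel=structure_panel)
        write_fst_matrix(matrix, out / "tableS2_pairwise_fst.tsv")
        global_res = fst_permutation_test(
            refs, panel=structure_panel, reps=config.permutation_reps, seed=config.seed
        )
        if len(matrix.labels) > 2:
            mds = classical_mds(matrix, k=2)
            write_mds_coordinates(mds, out / "fig1_mds.tsv")
        report.stages["structure"].update(
            {"global_theta": global_res.theta, "global_p": global_res.p}
        )

    with _stage(report, "pool_references"):
        pooled = pool_samples(refs, pooling)
        pools = [
            build_pool([s], s.label, assignment_panel)
            for s in subset_loci(pooled, assignment_panel).samples
        ]
        pooled_theta = None
        if len(pooled.samples) >= 2:
            pooled_theta = wc = fst_permutation_test(
                pooled, panel=assignment_panel, reps=config.permutation_reps, seed=config.seed + 1
            )
        report.stages["pool_references"].update(
            {
                "pools": {p.name: p.n for p in pools},
                "pooled_theta": pooled_theta.theta if pooled_theta else None,
                "pooled_p": pooled_theta.p if pooled_theta else None,
            }
        )

    with _stage(report, "self_assignment"):
        if len(pools) >= 2:
            _, summaries = self_assign_loo(pools, criterion=config.assignment_criterion)
        else:
            summaries = []
            logger.warning("fewer than two pools: self-assignment skipped")
        report.stages["self_assignment"].update(
            {s.group: s.proportions for s in summaries}
        )

    pool_names = [p.name for p in pools]
    panel_fish = fish
    idx = [refs.locus_index(n) for n in assignment_panel]
    if fish and idx != list(range(len(refs.loci))):
        from dataclasses import replace as _dc_replace
        from .genotypes import IndividualGenotype as _IG

        panel_fish = [
            _dc_replace(
                f,
                genotype=_IG(f.genotype.individual_id, f.genotype.calls[idx])
                if f.genotype is not None
                else None,
            )
            for f in fish
        ]
    if fish:
        with _stage(report, "exclusion"):
            records = {}
            for f in panel_fish:
                if f.genotype is None:
                    continue
                rec = exclusion_test(
                    f,
                    pools,
                    n_sim=config.exclusion_sims,
                    seed=config.seed,
                    threshold=config.exclusion_threshold,
                    criterion=config.assignment_criterion,
                )
                records[f.fish_id] = rec
            max_ps = [max(r.exclusion_p.values()) for r in records.values() if r.exclusion_p]
            report.stages["exclusion"].update(
                {
                    "n": len(max_ps),
                    "min_max_p": float(np.min(max_ps)) if max_ps else None,
                    "median_max_p": float(np.median(max_ps)) if max_ps else None,
                }
            )

        with _stage(report, "assignment"):
            assign_records = assign_individuals(
                panel_fish, pools, criterion=config.assignment_criterion
            )
            assigned_of = {r.individual_id: r.assigned for r in assign_records}
            with open(out / "assignments.jsonl", "w") as fh:
                for r in assign_records:
                    fh.write(json.dumps(asdict(r), default=str) + "\n")
            report.stages["assignment"].update(
                {"assigned": sum(1 for r in assign_records if r.assigned), "errors": sum(1 for r in assign_records if r.error)}
            )

        with _stage(report, "behaviour"):
            classifications = classify_cohort(panel_fish, boundary=boundary)
            cls_df = pd.DataFrame(
                [
                    {
                        "fish_id": c.fish_id,
                        "category": c.category.value,
                        "days_at_liberty": c.days_at_liberty,
                        "min_validated_longitude": round(c.min_validated_longitude, 4),
                        "reason": c.reason or "",
                        "assigned": assigned_of.get(c.fish_id) or "",
                    }
                    for c in classifications
                ]
            )
            cls_df.to_csv(out / "classification.tsv", sep="\t", index=False)
            group_rows = []
            for cat in sorted({c.category for c in classifications}, key=lambda c: c.value):
                members = [c.fish_id for c in classifications if c.category == cat]
                recs = [r for r in assign_records if r.individual_id in members and r.assigned]
                summ = summarize(cat.value, recs, pool_names)
                group_rows.append(
                    {"group": cat.value, "n": len(members), **summ.counts,
                     **{f"prop_{k}": v for k, v in summ.proportions.items()}}
                )
            pd.DataFrame(group_rows).to_csv(out / "table1a_assignment.tsv", sep="\t", index=False, float_format="%.4f")
            report.stages["behaviour"].update(
                {"groups": {row["group"]: row["n"] for row in group_rows}}
            )

        with _stage(report, "philopatry"):
            cat_of = {c.fish_id: c.category for c in classifications}
            pairs = [
                (cat_of[r.individual_id], r.assigned)
                for r in assign_records
                if r.assigned is not None and r.individual_id in cat_of
            ]
            try:
                table = build_contingency(pairs)
                fisher = fisher_exact(table, sided=config.boschloo_sided)
                boschloo = boschloo_test(
                    table, sided=config.boschloo_sided, grid_size=config.boschloo_grid
                )
                pd.DataFrame(
                    table.as_array(), index=table.row_labels, columns=table.col_labels
                ).to_csv(out / "table1b_contingency.tsv", sep="\t")
                report.stages["philopatry"].update(
                    {
                        "table": table.as_array().tolist(),
                        "fisher_p": fisher.p,
                        "boschloo_p": boschloo.p,
                        "pi_argmax": boschloo.pi_argmax,
                        "sided": config.boschloo_sided,
                    }
                )
            except ValueError as exc:
                logger.warning("philopatry test skipped: %s", exc)

        with _stage(report, "subsampling"):
            groups = {c.fish_id: c.category.value for c in classifications}
            n_target = config.subsample_n or min(p.n for p in pools)
            try:
                df = subsample_robustness(
                    panel_fish,
                    pools,
                    groups,
                    n_target=n_target,
                    reps=config.subsample_reps,
                    seed=config.seed,
                    criterion=config.assignment_criterion,
                )
                df.to_csv(out / "tableS4_subsample.tsv", sep="\t", index=False, float_format="%.4f")
                report.stages["subsampling"].update({"n_target": n_target, "reps": config.subsample_reps})
            except ValueError as exc:
                logger.warning("subsampling skipped: %s", exc)
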