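"""End-to-end orchestration: simulate/load → primary → filter → classify.

`run_pipeline` executes the multi-phase hit-calling computation in order —
plate Z-scores and threshold hit calling on the inducible reporter,
exclusion-list filtering, dual-reporter percent-inhibition classification
into strong (group A) and moderate (group B) hits, and final
positive/negative classification of the tertiary candidate set — writing
per-stage TSVs, a JSON run report, and structured progress to stderr.

The tertiary candidate set is all group-A genes plus an explicit,
user-supplied selection of group-B genes. That selection was expert
judgement in the screen this models (functional relatedness to group A), so
it is configuration, never inferred.

When the pipeline runs on a simulation, one dual-reporter dataset is the
measurement basis for every phase (the primary stage reads its firefly
channel only); with real data, separate per-stage datasets can be supplied.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .filtering import apply_exclusions, read_exclusion_list
from .model import ScreenDataset, read_plate_table, read_reagent_table, write_plate_table
from .primary import PlateZScorer, call_primary_hits, gene_ztable
from .reporter import InhibitionClassifier, ReporterNormalizer, amplicon_summaries
from .simulate import SimulationConfig, reagent_table, simulate_screen

logger = logging.getLogger("hifscreen.pipeline")


@dataclass
class PipelineConfig:
    """Everything a full run needs; build directly or via :meth:`from_yaml`."""

    simulation: SimulationConfig | None = None
    wells_path: str | None = None
    reagents_path: str | None = None
    #: Optional separate dual-reporter datasets for phases II/III.
    secondary_wells_path: str | None = None
    tertiary_wells_path: str | None = None
    cutoff: float = -2.5
    rule: str = "any"
    include_controls: bool = True
    ddof: int = 1
    hit_threshold: float = 50.0
    strong_threshold: float = 75.0
    #: Ordered (name, genes-or-path) exclusion lists.
    exclusions: list[tuple[str, object]] = field(default_factory=list)
    #: Explicit group-B genes to carry into the tertiary stage.
    group_b_selection: list[str] = field(default_factory=list)
    seed: int | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.cutoff < 0:
            raise ValueError(f"Z cutoff must be negative, got {self.cutoff}")
        for name in ("hit_threshold", "strong_threshold"):
            v = getattr(self, name)
            if not 0 < v < 100:
                raise ValueError(f"{name} must lie in (0, 100), got {v}")
        if self.simulation is None and self.wells_path is None:
            raise ValueError("config needs either a simulation or a wells_path")
        if self.simulation is not None and self.seed is not None:
            self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        exclusions = [(d["name"], d["genes"] if "genes" in d else d["path"])
                      for d in raw.pop("exclusions", [])]
        return cls(simulation=sim, exclusions=exclusions, **raw)


@dataclass
class RunReport:
    """Machine-readable per-stage accounting of one pipeline run."""

    seed: int | None
    version: str
    parameters: dict
    n_genes_input: int = 0
    primary_hits: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    filtered: int = 0
    secondary: dict[str, int] = field(default_factory=dict)
    tertiary_candidates: int = 0
    tertiary: dict[str, int] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("tables")
        return d


def _load_exclusions(cfg: PipelineConfig) -> list[tuple[str, list[str]]]:
    out = []
    for name, src in cfg.exclusions:
        genes = read_exclusion_list(src) if isinstance(src, (str, Path)) else list(src)
        out.append((name, genes))
    return out


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order; identical config+seed ⇒ identical report."""
    cfg = config
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s: %(message)s")
    truth = None
    if cfg.simulation is not None:
        ds, truth = simulate_screen(cfg.simulation)
        reagents = reagent_table(cfg.simulation)
    else:
        ds = read_plate_table(cfg.wells_path)
        reagents = read_reagent_table(cfg.reagents_path)
    report = RunReport(
        seed=cfg.simulation.seed if cfg.simulation else cfg.seed,
        version=__version__,
        parameters={
            "cutoff": cfg.cutoff, "rule": cfg.rule,
            "include_controls": cfg.include_controls, "ddof": cfg.ddof,
            "hit_threshold": cfg.hit_threshold,
            "strong_threshold": cfg.strong_threshold,
        },
    )
    sample_genes = reagents[reagents["reagent_id"].isin(ds.sample_wells()["reagent_id"])]
    report.n_genes_input = sample_genes["target_gene_id"].nunique()

    # phase I: plate Z-scores on the inducible reporter, threshold calling
    scorer = PlateZScorer(include_controls=cfg.include_controls, ddof=cfg.ddof)
    zwells = scorer.fit(ds).transform(ds)
    ztable = gene_ztable(zwells, reagents)
    calls = call_primary_hits(ztable, cutoff=cfg.cutoff, rule=cfg.rule)
    hits = calls.loc[calls["label"] == "hit", "gene_id"].tolist()
    report.primary_hits = len(hits)
    report.tables["primary_calls"] = calls
    logger.info("primary: %d/%d genes below Z cutoff %.2f (rule=%s)",
                len(hits), report.n_genes_input, cfg.cutoff, cfg.rule)

    # phase I filtering: sequential exclusion lists
    excl = apply_exclusions(hits, _load_exclusions(cfg))
    report.removed = dict(excl.removed)
    report.filtered = excl.surviving_count
    report.tables["filtered"] = pd.DataFrame({"gene_id": excl.survivors})
    logger.info("filter: %d hits -> %d survivors (removed %s)",
                excl.input_count, excl.surviving_count, excl.removed)

    # phases II/III need the constitutive reporter
    sec_ds = (read_plate_table(cfg.secondary_wells_path, stage="secondary")
              if cfg.secondary_wells_path else ds)
    if sec_ds.wells["renilla"].notna().any():
        norm = ReporterNormalizer().fit(sec_ds)
        summaries = amplicon_summaries(norm.transform(sec_ds), reagents)
        surviving = summaries[summaries["gene_id"].isin(excl.survivors)]
        if surviving.empty:
            logger.info("no phase-I survivors: nothing to classify downstream")
            return report
        sec = InhibitionClassifier(
            stage="secondary", hit_threshold=cfg.hit_threshold,
            strong_threshold=cfg.strong_threshold,
        ).fit(surviving)
        sec_calls = sec.calls_
        report.secondary = sec_calls["label"].value_counts().to_dict()
        report.tables["secondary_calls"] = sec_calls
        group_a = sec_calls.loc[sec_calls["label"] == "group_A", "gene_id"].tolist()
        group_b = set(sec_calls.loc[sec_calls["label"] == "group_B", "gene_id"])
        selected_b = [g for g in cfg.group_b_selection if g in group_b]
        candidates = group_a + selected_b
        report.tertiary_candidates = len(candidates)
        logger.info("secondary: %s; tertiary candidates = %d group_A + %d "
                    "selected group_B", report.secondary, len(group_a),
                    len(selected_b))

        ter_ds = (read_plate_table(cfg.tertiary_wells_path, stage="tertiary")
                  if cfg.tertiary_wells_path else sec_ds)
        if ter_ds is not sec_ds:
            norm = ReporterNormalizer().fit(ter_ds)
            ter_summaries = amplicon_summaries(norm.transform(ter_ds), reagents)
        else:
            ter_summaries = summaries
        cand_sum = ter_summaries[ter_summaries["gene_id"].isin(candidates)]
        if not cand_sum.empty:
            ter = InhibitionClassifier(
                stage="tertiary", hit_threshold=cfg.hit_threshold,
            ).fit(cand_sum)
            report.tertiary = ter.calls_["label"].value_counts().to_dict()
            report.tables["tertiary_calls"] = ter.calls_
            logger.info("tertiary: %s", report.tertiary)
    else:
        logger.info("no Renilla channel: stopping after phase-I filtering")

    if truth is not None:
        report.tables["ground_truth"] = truth.genes
    if cfg.out_dir is not None:
        _write_outputs(cfg, ds, report)
    return report


def _write_outputs(cfg: PipelineConfig, ds: ScreenDataset, report: RunReport) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.simulation is not None:
        write_plate_table(ds, out / "wells.csv")
        reagent_table(cfg.simulation).to_csv(out / "reagents.csv", index=False)
    for name, table in report.tables.items():
        table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
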