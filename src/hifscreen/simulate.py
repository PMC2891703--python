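"""Synthetic reporter screens with known ground truth.

The generator emulates a duplicate, multi-plate dsRNA knockdown screen read
out by an inducible firefly-luciferase reporter and (optionally) a
constitutive Renilla reporter. For a sample well *w* on plate *p* carrying a
reagent against gene *g*::

    firefly(w) = P_p * F0 * I * (1 - e_g) * v_g * eps_w
    renilla(w) = P_p * R0 * v_g * eps'_w

where ``P_p = exp(N(0, plate_effect_sd))`` is a multiplicative plate factor
shared by every well of plate *p*, ``F0``/``R0`` are channel baselines, ``I``
is the fold-induction of the inducible reporter by the stimulus, ``e_g`` is
the reporter-specific knockdown fraction (nonzero only for planted regulator
genes and the positive control), ``v_g`` is a viability factor (< 1 only for
planted viability genes, depressing both channels), and ``eps`` are
independent mean-one log-normal noise terms with a given coefficient of
variation. Replicates redraw plate factors and well noise only; gene effects
are fixed, so the planted biology is identical across replicates.

Multiplicative (log-normal) noise and plate factors are deliberate:
luminescence is positive with fold-change-like variability, and the
firefly/Renilla ratio then cancels ``P_p`` exactly, which is the point of a
dual-reporter design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import ceil, log, sqrt

import numpy as np
import pandas as pd

from .model import PLATE_FORMATS, ScreenDataset, _row_letters

NEGATIVE_CONTROL_REAGENT = "ctrl_GFP"
POSITIVE_CONTROL_REAGENT = "ctrl_sima"
#: Knockdown of the positive-control dsRNA, matching the ~90% inhibition the
#: HIF-alpha control shows in a well-behaved screen.
POSITIVE_CONTROL_KNOCKDOWN = 0.9


@dataclass
class SimulationConfig:
    """Parameters of the synthetic screen.

    Defaults describe a plausible well-behaved genome-scale screen: 2
    replicates, 5% of genes true positive regulators with knockdown drawn
    uniformly from [0.5, 0.95], 5% viability genes, 10-fold reporter
    induction, 20% well-level CV, and ~15% plate-to-plate scale variation.
    """

    n_genes: int = 300
    amplicons_per_gene: int = 1
    plate_format: int = 384
    n_replicates: int = 2
    fraction_true_hits: float = 0.05
    #: Either a (low, high) uniform range or a single fixed knockdown fraction.
    hit_effect: tuple[float, float] | float = (0.5, 0.95)
    fraction_viability: float = 0.05
    baseline_firefly: float = 1000.0
    baseline_renilla: float = 500.0
    induction_fold: float = 10.0
    noise_cv: float = 0.2
    plate_effect_sd: float = 0.15
    controls_per_plate: int = 4
    with_renilla: bool = False
    stage: str = "primary"
    condition: str = "DFO"
    #: Pin the number of plates per replicate; None = computed from capacity.
    n_plates: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_true_hits", "fraction_viability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_true_hits + self.fraction_viability > 1.0:
            raise ValueError("fraction_true_hits + fraction_viability > 1")
        for name in ("baseline_firefly", "baseline_renilla", "induction_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_cv < 0 or self.plate_effect_sd < 0:
            raise ValueError("noise_cv and plate_effect_sd must be >= 0")
        if self.plate_format not in PLATE_FORMATS:
            raise ValueError(f"unsupported plate format {self.plate_format}")
        lo, hi = self._effect_range()
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"hit_effect must lie within [0, 1], got {self.hit_effect}")

    def _effect_range(self) -> tuple[float, float]:
        if isinstance(self.hit_effect, (int, float)):
            return float(self.hit_effect), float(self.hit_effect)
        lo, hi = self.hit_effect
        return float(lo), float(hi)


@dataclass
class GroundTruth:
    """Planted truth of a simulated screen, one row per gene.

    ``genes`` has columns ``gene_id``, ``true_class`` (``neutral`` |
    ``hif_regulator`` | ``viability``) and ``knockdown`` (reporter knockdown
    for regulators, viability factor complement for viability genes, 0 for
    neutrals).
    """

    genes: pd.DataFrame
    config: SimulationConfig = field(repr=False, default=None)

    def of_class(self, true_class: str) -> list[str]:
        g = self.genes
        return g.loc[g["true_class"] == true_class, "gene_id"].tolist()


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = log(1.0 + cv * cv)
    sigma = sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def _plan_layout(cfg: SimulationConfig) -> tuple[pd.DataFrame, int]:
    """Assign reagents and controls to plate positions for one replicate.

    Returns the per-replicate layout (plate index, row, col, reagent_id,
    role) and the number of plates. The same layout is reused for every
    replicate, as in a real screen where replicate plates share the library
    plate map. Controls are spread evenly through each plate.
    """
    n_rows, n_cols = PLATE_FORMATS[cfg.plate_format]
    wells_per_plate = n_rows * n_cols
    n_controls = 2 * cfg.controls_per_plate
    capacity = wells_per_plate - n_controls
    if capacity <= 0:
        raise ValueError("controls_per_plate leaves no room for samples")
    n_sample_wells = cfg.n_genes * cfg.amplicons_per_gene
    n_plates = ceil(n_sample_wells / capacity)
    if cfg.n_plates is not None:
        if cfg.n_plates < n_plates:
            raise ValueError(
                f"{n_sample_wells} sample wells plus {n_controls} controls per "
                f"plate exceed {cfg.n_plates} x {cfg.plate_format}-well plates; "
                f"need at least {n_plates} plates"
            )
        n_plates = cfg.n_plates

    letters = _row_letters(cfg.plate_format)
    reagents = [
        (f"amp_{g:05d}_{a}", f"g{g:05d}", a)
        for g in range(1, cfg.n_genes + 1)
        for a in range(1, cfg.amplicons_per_gene + 1)
    ]
    rows = []
    it = iter(reagents)
    exhausted = False
    for p in range(n_plates):
        # controls interleaved at evenly spaced positions within the plate
        step = wells_per_plate // max(n_controls, 1)
        control_pos = set(range(0, n_controls * step, step)[:n_controls])
        ctrl_roles = (["negative_control", "positive_control"]
                      * cfg.controls_per_plate)
        ctrl_iter = iter(ctrl_roles)
        for idx in range(wells_per_plate):
            r, c = letters[idx // n_cols], idx % n_cols + 1
            if idx in control_pos:
                role = next(ctrl_iter)
                rid = (NEGATIVE_CONTROL_REAGENT if role == "negative_control"
                       else POSITIVE_CONTROL_REAGENT)
                rows.append((p, r, c, rid, role))
            elif not exhausted:
                try:
                    rid, _, _ = next(it)
                except StopIteration:
                    exhausted = True
                    rows.append((p, r, c, None, "empty"))
                else:
                    rows.append((p, r, c, rid, "sample"))
            else:
                rows.append((p, r, c, None, "empty"))
    layout = pd.DataFrame(rows, columns=["plate", "row", "col", "reagent_id", "role"])
    return layout, n_plates


def simulate_screen(config: SimulationConfig) -> tuple[ScreenDataset, GroundTruth]:
    """Draw one synthetic screen and its planted ground truth.

    The random stream is hierarchical (gene effects, then plate factors,
    then well noise, each from an independent child of the config seed), so
    the planted biology for a given seed is stable under changes to the
    noise settings. The same seed yields a bit-identical dataset.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    ss_genes, ss_plates, ss_noise = root.spawn(3)
    rng_genes = np.random.default_rng(ss_genes)
    rng_plates = np.random.default_rng(ss_plates)
    rng_noise = np.random.default_rng(ss_noise)

    gene_ids = [f"g{g:05d}" for g in range(1, cfg.n_genes + 1)]
    n_hits = round(cfg.fraction_true_hits * cfg.n_genes)
    n_via = round(cfg.fraction_viability * cfg.n_genes)
    perm = rng_genes.permutation(cfg.n_genes)
    classes = np.array(["neutral"] * cfg.n_genes, dtype=object)
    classes[perm[:n_hits]] = "hif_regulator"
    classes[perm[n_hits:n_hits + n_via]] = "viability"
    lo, hi = cfg._effect_range()
    effects = rng_genes.uniform(lo, hi, size=cfg.n_genes)
    knockdown = np.where(classes == "neutral", 0.0, effects)
    truth = GroundTruth(
        genes=pd.DataFrame(
            {"gene_id": gene_ids, "true_class": classes, "knockdown": knockdown}
        ),
        config=cfg,
    )
    e_g = dict(zip(gene_ids, np.where(classes == "hif_regulator", knockdown, 0.0)))
    v_g = dict(zip(gene_ids, np.where(classes == "viability", 1.0 - knockdown, 1.0)))
    gene_of = {f"amp_{g:05d}_{a}": f"g{g:05d}"
               for g in range(1, cfg.n_genes + 1)
               for a in range(1, cfg.amplicons_per_gene + 1)}
    e_g[NEGATIVE_CONTROL_REAGENT] = 0.0
    v_g[NEGATIVE_CONTROL_REAGENT] = 1.0
    e_g[POSITIVE_CONTROL_REAGENT] = POSITIVE_CONTROL_KNOCKDOWN
    v_g[POSITIVE_CONTROL_REAGENT] = 1.0

    layout, n_plates = _plan_layout(cfg)
    frames = []
    replicate_map: dict[str, int] = {}
    for rep in range(1, cfg.n_replicates + 1):
        for p in range(n_plates):
            plate_id = f"r{rep}_p{p + 1:02d}"
            replicate_map[plate_id] = rep
            sub = layout[layout["plate"] == p].copy()
            pf = (np.exp(rng_plates.normal(0.0, cfg.plate_effect_sd))
                  if cfg.plate_effect_sd > 0 else 1.0)
            n = len(sub)
            eps_f = _lognormal_noise(rng_noise, cfg.noise_cv, n)
            eps_r = _lognormal_noise(rng_noise, cfg.noise_cv, n)
            gene = sub["reagent_id"].map(lambda r: gene_of.get(r, r))
            kd = gene.map(lambda g: e_g.get(g, 0.0)).to_numpy(float)
            via = gene.map(lambda g: v_g.get(g, 1.0)).to_numpy(float)
            firefly = (pf * cfg.baseline_firefly * cfg.induction_fold
                       * (1.0 - kd) * via * eps_f)
            renilla = pf * cfg.baseline_renilla * via * eps_r
            empty = (sub["role"] == "empty").to_numpy()
            firefly[empty] = 0.0
            renilla[empty] = 0.0
            sub["plate_id"] = plate_id
            sub["firefly"] = firefly
            sub["renilla"] = renilla if cfg.with_renilla else np.nan
            frames.append(sub.drop(columns=["plate"]))
    wells = pd.concat(frames, ignore_index=True)
    ds = ScreenDataset(
        wells=wells, stage=cfg.stage, condition=cfg.condition,
        replicate_map=replicate_map, plate_format=cfg.plate_format,
    )
    return ds, truth


def reagent_table(config: SimulationConfig) -> pd.DataFrame:
    """Reagent → gene annotation matching :func:`simulate_screen` layouts."""
    rows = [
        (f"amp_{g:05d}_{a}", f"g{g:05d}", a)
        for g in range(1, config.n_genes + 1)
        for a in range(1, config.amplicons_per_gene + 1)
    ]
    rows.append((NEGATIVE_CONTROL_REAGENT, "GFP", 1))
    rows.append((POSITIVE_CONTROL_REAGENT, "sima_control", 1))
    return pd.DataFrame(rows, columns=["reagent_id", "target_gene_id", "amplicon_index"])


def make_table1_fixture() -> pd.DataFrame:
    """The packaged 35-gene per-amplicon percent-inhibition table.

    Mean and SD percent inhibition of the hypoxia-inducible reporter for one
    or two dsRNA amplicons per gene, measured in hypoxia against GFP-dsRNA
    control wells. Genes with a single tested amplicon have NA in the
    ``inhibition_amp2_*`` columns. Suitable as direct input to
    :func:`hifscreen.reporter.classify_tertiary`.
    """
    with resources.files("hifscreen.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
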